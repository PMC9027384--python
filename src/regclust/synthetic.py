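"""Ground-truth synthetic data: planted time profiles, network and GO tables.

The generator emulates the structure of a pulse-response transcriptome
study: genes fall into clusters with archetypal time profiles (immediate
down then recovery, delayed persistent up, ...), a TF/SF interaction table
wires *planted* regulator combinations to genes concentrated in one target
cluster each (plus a small leak outside), decoy combinations are wired
uniformly at random, and GO categories follow the same planted/decoy
scheme. Additive Gaussian noise on the log2 fold changes completes the
model. Everything is deterministic given the seed, down to byte-identical
fixture files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .expression import TimeCourseMatrix, write_expression
from .regnet import ACTIVATION, REPRESSION, Combo, Interaction, write_network

__all__ = [
    "PlantedCombo",
    "PlantedGO",
    "SyntheticTruth",
    "DEFAULT_TIMES",
    "DEFAULT_ARCHETYPES",
    "make_truth",
    "simulate_expression",
    "simulate_network",
    "write_fixtures",
]

#: Default sampling grid, hours after the perturbation.
DEFAULT_TIMES = (0.5, 1.0, 2.5, 4.0, 6.0, 9.0, 12.0, 15.0, 20.0, 25.0)

#: Anchor-value archetype profiles (time, log2FC); linearly interpolated.
DEFAULT_ARCHETYPES: dict[str, tuple[tuple[float, float], ...]] = {
    "imm_down_recover": ((0.5, -2.5), (6.0, -2.2), (12.0, -0.8), (15.0, -0.2), (25.0, 0.0)),
    "imm_down_persistent": ((0.5, -2.0), (25.0, -2.0)),
    "delayed_down_persistent": ((0.5, 0.0), (4.0, -0.2), (9.0, -2.0), (25.0, -2.0)),
    "delayed_up_transient": ((0.5, 0.0), (2.5, 0.3), (4.0, 2.2), (6.0, 2.0),
                             (9.0, 0.3), (15.0, 0.0), (25.0, 0.0)),
    "delayed_up_persistent": ((0.5, 0.0), (4.0, 0.2), (9.0, 2.0), (25.0, 2.2)),
    "delayed_up_recover": ((0.5, 0.2), (2.5, 2.0), (6.0, 2.2), (15.0, 1.0), (25.0, 0.3)),
    "imm_up_persistent": ((0.5, 2.2), (25.0, 2.0)),
}

_DEFAULT_PLANTED_COMBOS = (
    (("CRP-cAMP", "RpoD", ACTIVATION), "imm_down_recover", 40),
    (("CRP-cAMP", "RpoS", ACTIVATION), "imm_down_persistent", 25),
    (("FlhDC", "RpoF", ACTIVATION), "delayed_down_persistent", 20),
    (("FNR", "RpoD", REPRESSION), "delayed_up_transient", 19),
    (("ArcA", "RpoD", REPRESSION), "delayed_up_persistent", 18),
    (("GadE", "RpoS", ACTIVATION), "imm_up_persistent", 25),
)

_DEFAULT_PLANTED_GO = (
    ("GO:0006099", "imm_down_recover", 30),
    ("GO:0015980", "imm_down_persistent", 24),
    ("GO:0071973", "delayed_down_persistent", 20),
    ("GO:0009061", "delayed_up_transient", 20),
    ("GO:0006006", "delayed_up_persistent", 22),
    ("GO:0010447", "imm_up_persistent", 24),
)


@dataclass(frozen=True)
class PlantedCombo:
    """A regulator combination planted to control one cluster."""

    combo: Combo
    cluster: str
    n_controlled: int


@dataclass(frozen=True)
class PlantedGO:
    """A GO category planted to concentrate in one cluster."""

    go_id: str
    cluster: str
    n_members: int


@dataclass(frozen=True)
class SyntheticTruth:
    """Complete ground truth of one synthetic study."""

    n_genes: int
    times: tuple[float, ...]
    archetypes: dict[str, tuple[tuple[float, float], ...]]
    cluster_sizes: dict[str, int]
    gene_cluster: dict[str, str]
    planted_combos: tuple[PlantedCombo, ...]
    planted_go: tuple[PlantedGO, ...]
    n_decoy_combos: int
    n_decoy_go: int
    decoy_size: int
    leak_fraction: float
    noise_sd: float
    seed: int

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_cluster, key=lambda g: int(g[1:]))

    def cluster_members(self, name: str) -> list[str]:
        return [g for g in self.gene_ids if self.gene_cluster[g] == name]

    @property
    def n_planted_clusters(self) -> int:
        """Number of differential-expression clusters (background excluded)."""
        return len(self.archetypes)


def make_truth(
    n_genes: int = 1200,
    noise_sd: float = 0.2,
    seed: int = 42,
    cluster_size: int = 150,
    leak_fraction: float = 0.10,
    n_decoy_combos: int = 20,
    n_decoy_go: int = 15,
    decoy_size: int = 3,
) -> SyntheticTruth:
    """Build the deterministic ground truth of a synthetic study.

    Seven differential-expression archetypes plus one flat background
    cluster; six planted TF/SF combinations and six planted GO categories,
    one per DE archetype cluster. Genes are assigned to clusters in blocks,
    ``cluster_size`` per archetype, remainder to background.
    """
    names = list(DEFAULT_ARCHETYPES)
    if cluster_size * len(names) > n_genes:
        raise ValueError(
            f"cluster sizes ({len(names)} x {cluster_size}) exceed n_genes={n_genes}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    sizes = {name: cluster_size for name in names}
    sizes["background"] = n_genes - cluster_size * len(names)
    width = len(str(n_genes))
    gene_cluster: dict[str, str] = {}
    i = 1
    for name in names + ["background"]:
        for _ in range(sizes[name]):
            gene_cluster[f"g{i:0{width}d}"] = name
            i += 1
    combos = tuple(
        PlantedCombo(Combo(*c), cl, n) for c, cl, n in _DEFAULT_PLANTED_COMBOS
    )
    gos = tuple(PlantedGO(g, cl, n) for g, cl, n in _DEFAULT_PLANTED_GO)
    for pc in combos:
        n_inside = pc.n_controlled - int(leak_fraction * pc.n_controlled)
        if n_inside < 15:
            raise ValueError(
                f"planted combo {pc.combo.label()} controls only {n_inside} genes "
                "inside its target cluster; selection would be unachievable"
            )
    return SyntheticTruth(
        n_genes=n_genes,
        times=DEFAULT_TIMES,
        archetypes={k: tuple(v) for k, v in DEFAULT_ARCHETYPES.items()},
        cluster_sizes=sizes,
        gene_cluster=gene_cluster,
        planted_combos=combos,
        planted_go=gos,
        n_decoy_combos=n_decoy_combos,
        n_decoy_go=n_decoy_go,
        decoy_size=decoy_size,
        leak_fraction=leak_fraction,
        noise_sd=noise_sd,
        seed=seed,
    )


def archetype_profile(truth: SyntheticTruth, name: str) -> np.ndarray:
    """Noise-free profile of an archetype on the truth's time grid."""
    if name == "background":
        return np.zeros(len(truth.times))
    anchors = truth.archetypes[name]
    at = np.array([a[0] for a in anchors])
    av = np.array([a[1] for a in anchors])
    return np.interp(np.array(truth.times), at, av)


def simulate_expression(
    truth: SyntheticTruth,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> TimeCourseMatrix:
    """Archetype profiles plus iid Gaussian noise per cell.

    Background genes get pure noise. ``noise_sd``/``seed`` default to the
    truth's own; the expression seed is derived from the truth seed so the
    matrix and the network draw independent randomness.
    """
    sd = truth.noise_sd if noise_sd is None else noise_sd
    if sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 1])
    )
    profiles = {name: archetype_profile(truth, name)
                for name in list(truth.archetypes) + ["background"]}
    genes = truth.gene_ids
    values = np.empty((len(genes), len(truth.times)))
    for i, g in enumerate(genes):
        values[i] = profiles[truth.gene_cluster[g]]
    values += rng.normal(0.0, sd, size=values.shape) if sd > 0 else 0.0
    return TimeCourseMatrix(genes, truth.times, values)


def simulate_network(
    truth: SyntheticTruth, seed: int | None = None
) -> tuple[list[Interaction], dict[str, frozenset[str]]]:
    """Wire planted and decoy combinations and GO categories to genes.

    Each planted combination's targets are drawn from its target cluster,
    with a ``leak_fraction`` share drawn from outside it; decoy units are
    wired uniformly at random over all genes. Deterministic given the seed
    (derived from the truth seed by default).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 2])
    )
    genes = np.array(truth.gene_ids)
    cluster_of = truth.gene_cluster

    def draw_planted(target_cluster: str, n_total: int) -> list[str]:
        # leak models regulon members that do not respond to the perturbation:
        # drawn from the flat background, i.e. outside the target cluster
        inside = np.array([g for g in genes if cluster_of[g] == target_cluster])
        outside = np.array([g for g in genes if cluster_of[g] == "background"])
        if outside.size == 0:
            outside = np.array([g for g in genes if cluster_of[g] != target_cluster])
        n_out = int(truth.leak_fraction * n_total)
        n_in = n_total - n_out
        chosen = list(rng.choice(inside, size=n_in, replace=False))
        if n_out:
            chosen += list(rng.choice(outside, size=n_out, replace=False))
        return chosen

    interactions: list[Interaction] = []
    for pc in truth.planted_combos:
        for g in draw_planted(pc.cluster, pc.n_controlled):
            interactions.append(Interaction(pc.combo.tf, pc.combo.sf, g, pc.combo.mode))
    # decoy regulons: small, wired like real regulons (co-expressed targets,
    # i.e. concentrated in one cluster drawn at random) but far below the
    # selection rule's minimum gene count
    cluster_names = list(truth.archetypes)
    for d in range(truth.n_decoy_combos):
        tf = f"DecoyTF{d:02d}"
        mode = ACTIVATION if d % 2 == 0 else REPRESSION
        sf = "RpoD" if d % 3 else "RpoS"
        home = cluster_names[int(rng.integers(len(cluster_names)))]
        for g in draw_planted(home, truth.decoy_size):
            interactions.append(Interaction(tf, sf, str(g), mode))

    go_map: dict[str, frozenset[str]] = {}
    for pg in truth.planted_go:
        go_map[pg.go_id] = frozenset(draw_planted(pg.cluster, pg.n_members))
    for d in range(truth.n_decoy_go):
        go_id = f"GO:99000{d:02d}"
        go_map[go_id] = frozenset(
            str(g) for g in rng.choice(genes, size=truth.decoy_size, replace=False)
        )
    return interactions, go_map


def write_fixtures(truth: SyntheticTruth, outdir: str | Path) -> dict[str, Path]:
    """Write expression.tsv, network.tsv, go.tsv and truth.json.

    Byte-identical across runs for the same truth (all randomness derives
    from the truth seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = simulate_expression(truth)
    interactions, go_map = simulate_network(truth)
    paths = {
        "expression": outdir / "expression.tsv",
        "network": outdir / "network.tsv",
        "go": outdir / "go.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression(matrix, paths["expression"])
    write_network(interactions, paths["network"])
    with open(paths["go"], "w", encoding="utf-8") as fh:
        fh.write("gene\tgo_id\n")
        for go_id in sorted(go_map):
            for g in sorted(go_map[go_id]):
                fh.write(f"{g}\t{go_id}\n")
    doc = asdict(truth)
    doc["planted_combos"] = [
        {"tf": p.combo.tf, "sf": p.combo.sf, "mode": p.combo.mode,
         "cluster": p.cluster, "n_controlled": p.n_controlled}
        for p in truth.planted_combos
    ]
    doc["planted_go"] = [asdict(p) for p in truth.planted_go]
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
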