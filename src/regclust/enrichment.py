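"""Over-representation analysis of clusters: GO categories and TF/SF combos.

For every (cluster, unit) pair — a unit being either a GO biological-process
category or a (TF, SF, mode) regulator combination — a one-sided Fisher's
exact test asks whether the unit's genes are over-represented among the
cluster's DEGs relative to the gene universe. Three counts parameterise the
test: the number of DEGs in the cluster, the number of those belonging to
the unit, and the number of universe ("whole genome") genes in the unit; the
universe size closes the 2x2 table. Raw p-values are corrected per stage
with the Holm–Bonferroni step-down method, and a unit is *selected* in a
cluster when it has at least ``min_genes`` member DEGs there (default 9) at
a corrected p below ``alpha_enrich`` (default 0.0025).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import Config
from .regnet import Combo

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "fisher_right_tail",
    "holm_bonferroni",
    "enrich",
    "select_important",
    "read_go_annotation",
    "export_revigo",
    "records_to_frame",
]


def fisher_right_tail(n_hit: int, n_cluster: int, n_unit_genome: int, n_genome: int) -> float:
    """Right-tail Fisher's exact p: P(X >= n_hit), X ~ Hypergeom.

    X counts unit genes in a draw of ``n_cluster`` from a universe of
    ``n_genome`` genes of which ``n_unit_genome`` belong to the unit.
    Computed by exact hypergeometric tail summation.
    """
    for name, v in (("n_hit", n_hit), ("n_cluster", n_cluster),
                    ("n_unit_genome", n_unit_genome), ("n_genome", n_genome)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name}={v} must be a non-negative integer")
    if n_cluster > n_genome:
        raise ValueError(f"n_cluster={n_cluster} exceeds n_genome={n_genome}")
    if n_unit_genome > n_genome:
        raise ValueError(f"n_unit_genome={n_unit_genome} exceeds n_genome={n_genome}")
    if n_hit > min(n_cluster, n_unit_genome):
        raise ValueError(
            f"n_hit={n_hit} exceeds min(n_cluster={n_cluster}, "
            f"n_unit_genome={n_unit_genome})"
        )
    if n_hit < n_cluster + n_unit_genome - n_genome:
        raise ValueError(f"n_hit={n_hit} below the hypergeometric support minimum")
    return float(hypergeom.sf(n_hit - 1, n_genome, n_unit_genome, n_cluster))


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values, in input order.

    The i-th smallest p is multiplied by (m - i + 1), a running maximum
    enforces monotonicity, and values are capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One Fisher test of a unit (GO category or TF/SF combo) in a cluster."""

    cluster: int
    unit: Hashable
    n_cluster: int
    n_hit: int
    n_unit_genome: int
    n_genome: int
    p_raw: float
    p_adj: float
    selected: bool


def enrich(
    assignments: Mapping[str, int],
    units: Mapping[Hashable, frozenset[str] | set[str]],
    universe: Iterable[str],
    config: Config,
) -> list[EnrichmentRecord]:
    """Fisher over-representation of every unit in every cluster.

    One record is emitted per (cluster, unit) pair with at least one member
    DEG in the cluster; the Holm correction family is all emitted tests of
    the stage. ``assignments`` maps clustered DEGs to labels; ``units`` maps
    a unit id to its target-gene set; ``universe`` is the background.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    n_genome = len(universe)
    clusters: dict[int, set[str]] = {}
    for gene, label in assignments.items():
        if gene in universe:
            clusters.setdefault(label, set()).add(gene)
    unit_sets = {u: frozenset(genes) & universe for u, genes in units.items()}

    rows: list[tuple[int, Hashable, int, int, int, float]] = []
    for label in sorted(clusters):
        members = clusters[label]
        for unit in sorted(unit_sets, key=str):
            targets = unit_sets[unit]
            n_hit = len(members & targets)
            if n_hit == 0:
                continue
            p = fisher_right_tail(n_hit, len(members), len(targets), n_genome)
            rows.append((label, unit, len(members), n_hit, len(targets), p))
    if not rows:
        return []
    p_adj = holm_bonferroni([r[5] for r in rows])
    records = []
    for (label, unit, n_cluster, n_hit, n_unit, p), pa in zip(rows, p_adj):
        records.append(EnrichmentRecord(
            cluster=label, unit=unit, n_cluster=n_cluster, n_hit=n_hit,
            n_unit_genome=n_unit, n_genome=n_genome, p_raw=p, p_adj=float(pa),
            selected=bool(n_hit >= config.min_genes and pa < config.alpha_enrich),
        ))
    return records


def select_important(records: Iterable[EnrichmentRecord]) -> frozenset[Combo]:
    """TF/SF combinations selected in at least one cluster."""
    return frozenset(r.unit for r in records if r.selected)


def read_go_annotation(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column gene -> GO id table into GO id -> gene-set form."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                     comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gene, GO id)")
    first_gene = str(df.iloc[0, 0]).lower()
    first_term = str(df.iloc[0, 1]).lower()
    if first_gene in ("gene", "gene_id") or first_term in ("go", "go_id", "term", "category"):
        df = df.iloc[1:]
    mapping: dict[str, set[str]] = {}
    for gene, go in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(str(go), set()).add(str(gene))
    return {go: frozenset(genes) for go, genes in mapping.items()}


def export_revigo(records: Iterable[EnrichmentRecord], path: str | Path) -> None:
    """Write GO-stage results in the two-column term/p format REVIGO accepts."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tp_adj\n")
        for r in records:
            fh.write(f"{r.unit}\t{r.p_adj:.6e}\n")


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    cols = ["cluster", "unit", "n_cluster", "n_hit", "n_unit_genome",
            "n_genome", "p_raw", "p_adj", "selected"]
    data = [[getattr(r, c) if c != "unit" else
             (r.unit.label() if isinstance(r.unit, Combo) else r.unit)
             for c in cols] for r in records]
    return pd.DataFrame(data, columns=cols)
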