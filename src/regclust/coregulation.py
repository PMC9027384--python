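"""Co-regulation level analysis of important TF/SF combinations.

After the enrichment stage has identified the *important* regulator
combinations, each DEG is mapped to the exact subset of important
combinations controlling it. Genes sharing the same exact subset form a
group; the group's *level* is the subset's cardinality (Level 1 = one
combination acting alone, Level 2 = two combinations in cooperative
control, ...). Two tests score each group:

* a right-tail Fisher's exact test asking whether the group is enriched in
  DEGs shifted in the group's own direction (down or up), and
* per sampling time, a one-sided two-sample t-test of the group's log2 fold
  changes against all other genes, in the group's direction.

Both p-value families are Holm–Bonferroni corrected within each level, and a
group is *decisive* only when both corrected p-values drop below
``alpha_level`` (default 0.05) — the Fisher one and the best timepoint one.
The per-timepoint results export as a signed -log10 p heat-map (negative =
down-regulation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .expression import Config, TimeCourseMatrix
from .enrichment import fisher_right_tail, holm_bonferroni
from .regnet import Combo

logger = logging.getLogger(__name__)

__all__ = [
    "LevelGroup",
    "TimepointTest",
    "assign_levels",
    "group_fisher",
    "timepoint_ttests",
    "decisive_flags",
    "export_heatmap",
    "run_level_analysis",
]


@dataclass(frozen=True)
class LevelGroup:
    """Genes controlled by exactly one subset of important combinations.

    ``direction`` is the sign of the group's mean log2 fold change over the
    whole time course ("down" or "up"); ``testable`` requires at least two
    member genes (and two complement genes) for the t-test.
    """

    combos: frozenset[Combo]
    level: int
    genes: tuple[str, ...]
    direction: str
    testable: bool = True
    fisher_p_raw: float = float("nan")
    fisher_p_adj: float = float("nan")
    decisive: bool = False

    def label(self) -> str:
        return " & ".join(sorted(c.label() for c in self.combos))


@dataclass(frozen=True)
class TimepointTest:
    """One-sided two-sample t-test of a group vs all other genes at one time."""

    group_label: str
    level: int
    time: float
    t_stat: float
    p_one_sided: float
    p_adj: float
    direction_tested: str  # "less" (down) or "greater" (up)


def assign_levels(
    deg_genes: Iterable[str],
    important: Iterable[Combo],
    signatures: Mapping[str, frozenset[Combo]],
    matrix: TimeCourseMatrix,
) -> list[LevelGroup]:
    """Partition DEGs by the exact subset of important combos controlling them.

    A gene's key is signature(g) restricted to the important set; genes with
    an empty key are excluded. The group's level is the key's cardinality.
    Groups with fewer than two genes are retained but marked untestable.
    Returned sorted by (level, label) for stable reporting.
    """
    important = frozenset(important)
    if not important:
        raise ValueError("important combination set is empty")
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    buckets: dict[frozenset[Combo], list[str]] = {}
    for gene in sorted(deg_genes):
        key = signatures.get(gene, frozenset()) & important
        if key:
            buckets.setdefault(key, []).append(gene)
    groups: list[LevelGroup] = []
    for key, members in buckets.items():
        rows = [pos[g] for g in members if g in pos]
        mean_fc = float(matrix.values[rows].mean()) if rows else 0.0
        groups.append(LevelGroup(
            combos=key,
            level=len(key),
            genes=tuple(members),
            direction="down" if mean_fc < 0 else "up",
            testable=len(rows) >= 2 and matrix.n_genes - len(rows) >= 2,
        ))
    return sorted(groups, key=lambda g: (g.level, g.label()))


def _direction_deg_sets(
    matrix: TimeCourseMatrix, deg_genes: Iterable[str]
) -> dict[str, frozenset[str]]:
    """DEGs classified by direction: sign of the mean log2FC over time."""
    degs = set(deg_genes)
    down, up = set(), set()
    for gene, row in zip(matrix.gene_ids, matrix.values):
        if gene in degs:
            (down if row.mean() < 0 else up).add(gene)
    return {"down": frozenset(down), "up": frozenset(up)}


def group_fisher(
    group: LevelGroup,
    direction_degs: Mapping[str, frozenset[str]],
    universe: Iterable[str],
) -> float:
    """Right-tail Fisher p for enrichment of direction-matched DEGs in a group.

    2x2 table over the universe: membership in the group vs membership in
    the set of DEGs shifted in the group's direction. Degenerate margins
    (no direction-DEGs, or the group covering the whole universe) give p = 1
    with a warning.
    """
    universe = frozenset(universe)
    members = frozenset(group.genes) & universe
    hits = direction_degs[group.direction] & universe
    if not members:
        raise ValueError("group has no genes inside the universe")
    if not hits or len(members) == len(universe):
        warnings.warn(
            f"degenerate Fisher margins for group {group.label()!r}; p = 1",
            stacklevel=2,
        )
        return 1.0
    return fisher_right_tail(
        n_hit=len(members & hits),
        n_cluster=len(members),
        n_unit_genome=len(hits),
        n_genome=len(universe),
    )


def timepoint_ttests(
    groups: Sequence[LevelGroup],
    matrix: TimeCourseMatrix,
    config: Config,
) -> list[TimepointTest]:
    """Pooled-variance one-sided t-tests of each group vs all other genes.

    Direction follows the group's own sign (down -> lower tail, up -> upper
    tail). The Holm correction family is all (group x time) tests within
    the same level. Untestable groups are passed over; a zero-pooled-
    variance time point yields p = NaN and is excluded from the correction
    family with a warning.
    """
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    raw: list[TimepointTest] = []
    for group in groups:
        if not group.testable:
            continue
        rows = np.array([pos[g] for g in group.genes if g in pos])
        mask = np.zeros(matrix.n_genes, dtype=bool)
        mask[rows] = True
        alternative = "less" if group.direction == "down" else "greater"
        for j, t in enumerate(matrix.times):
            x = matrix.values[mask, j]
            y = matrix.values[~mask, j]
            if np.ptp(x) == 0 and np.ptp(y) == 0:
                warnings.warn(
                    f"zero pooled variance for {group.label()!r} at t={t}",
                    stacklevel=2,
                )
                raw.append(TimepointTest(group.label(), group.level, float(t),
                                         float("nan"), float("nan"), float("nan"),
                                         alternative))
                continue
            res = stats.ttest_ind(x, y, equal_var=True, alternative=alternative)
            raw.append(TimepointTest(group.label(), group.level, float(t),
                                     float(res.statistic), float(res.pvalue),
                                     float("nan"), alternative))
    # Holm within each level over the valid tests
    out: list[TimepointTest] = []
    for level in sorted({t.level for t in raw}):
        level_tests = [t for t in raw if t.level == level]
        valid = [t for t in level_tests if np.isfinite(t.p_one_sided)]
        adj = holm_bonferroni([t.p_one_sided for t in valid]) if valid else []
        adj_iter = iter(adj)
        for t in level_tests:
            if np.isfinite(t.p_one_sided):
                out.append(replace(t, p_adj=float(next(adj_iter))))
            else:
                out.append(t)
    return out


def decisive_flags(
    groups: Sequence[LevelGroup],
    fisher_p_adj: Mapping[str, float],
    ttests: Sequence[TimepointTest],
    alpha_level: float = 0.05,
) -> list[LevelGroup]:
    """Mark groups decisive when both corrected tests clear ``alpha_level``.

    Decisive = Fisher p_adj < alpha AND the smallest timepoint t-test p_adj
    of the group < alpha. Untestable groups are never decisive.
    """
    best_t: dict[str, float] = {}
    for t in ttests:
        if np.isfinite(t.p_adj):
            best_t[t.group_label] = min(best_t.get(t.group_label, np.inf), t.p_adj)
    out = []
    for g in groups:
        pf = fisher_p_adj.get(g.label(), float("nan"))
        decisive = (
            g.testable
            and np.isfinite(pf)
            and pf < alpha_level
            and best_t.get(g.label(), np.inf) < alpha_level
        )
        out.append(replace(g, fisher_p_adj=float(pf), decisive=bool(decisive)))
    return out


def run_level_analysis(
    deg_genes: Iterable[str],
    important: Iterable[Combo],
    signatures: Mapping[str, frozenset[Combo]],
    matrix: TimeCourseMatrix,
    config: Config,
) -> tuple[list[LevelGroup], list[TimepointTest]]:
    """Full level stage: grouping, both tests, Holm per level, decisive flags."""
    groups = assign_levels(deg_genes, important, signatures, matrix)
    direction_degs = _direction_deg_sets(matrix, deg_genes)
    universe = list(matrix.gene_ids)
    # Fisher p per group, Holm-corrected within each level
    raw_by_level: dict[int, list[tuple[str, float]]] = {}
    for g in groups:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = group_fisher(g, direction_degs, universe)
        raw_by_level.setdefault(g.level, []).append((g.label(), p))
    fisher_adj: dict[str, float] = {}
    fisher_raw: dict[str, float] = {}
    for level, pairs in raw_by_level.items():
        adj = holm_bonferroni([p for _, p in pairs])
        for (label, p_raw), pa in zip(pairs, adj):
            fisher_raw[label] = p_raw
            fisher_adj[label] = float(pa)
    groups = [replace(g, fisher_p_raw=fisher_raw[g.label()]) for g in groups]
    tests = timepoint_ttests(groups, matrix, config)
    groups = decisive_flags(groups, fisher_adj, tests, config.alpha_level)
    return groups, tests


def export_heatmap(
    tests: Sequence[TimepointTest],
    path: str | Path,
) -> None:
    """Write the per-timepoint significance heat-map as TSV.

    Rows are groups (label plus level), columns sampling times, cells the
    signed -log10 corrected p (negative for down-regulated groups; NaN for
    untested cells).
    """
    times = sorted({t.time for t in tests})
    by_group: dict[tuple[str, int], dict[float, float]] = {}
    for t in tests:
        sign = -1.0 if t.direction_tested == "less" else 1.0
        val = sign * (-np.log10(t.p_adj)) if np.isfinite(t.p_adj) and t.p_adj > 0 else np.nan
        by_group.setdefault((t.group_label, t.level), {})[t.time] = val
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\tlevel\t" + "\t".join(repr(float(t)) for t in times) + "\n")
        for (label, level) in sorted(by_group):
            cells = by_group[(label, level)]
            row = "\t".join(
                repr(float(cells[t])) if t in cells and np.isfinite(cells[t]) else "nan"
                for t in times
            )
            fh.write(f"{label}\t{level}\t{row}\n")
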