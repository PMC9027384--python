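"""Time-course expression matrices: I/O, DEG filtering and profile scaling.

The central container is :class:`TimeCourseMatrix`, a gene x time matrix of
log2 fold changes relative to a pre-perturbation reference (time zero = the
perturbation, e.g. a glucose pulse on a carbon-limited chemostat culture).
Differentially expressed genes (DEGs) are those whose absolute log2 fold
change reaches a threshold (default 1.5) at one or more sampling points.
Before clustering, each DEG profile is scaled to unit maximum absolute value
so that cluster membership reflects the *shape* of the response rather than
its amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

logger = logging.getLogger(__name__)

__all__ = [
    "TimeCourseMatrix",
    "DEGSet",
    "Config",
    "ProfileMaxAbsScaler",
    "read_expression",
    "write_expression",
    "filter_degs",
    "scale_profiles",
]


class ExpressionError(ValueError):
    """Raised on malformed expression input."""


@dataclass(frozen=True)
class TimeCourseMatrix:
    """Gene x time log2 fold-change matrix.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene identifiers, one per row.
    times : sequence of float
        Strictly increasing sampling times in hours after the perturbation.
    values : ndarray of shape (n_genes, n_times)
        log2 fold change versus the pre-perturbation reference.
    """

    gene_ids: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray

    def __init__(self, gene_ids: Sequence[str], times: Sequence[float], values) -> None:
        gene_ids = tuple(str(g) for g in gene_ids)
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if len(set(gene_ids)) != len(gene_ids):
            seen: set[str] = set()
            for g in gene_ids:
                if g in seen:
                    raise ExpressionError(f"duplicate gene id: {g!r}")
                seen.add(g)
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ExpressionError("sampling times must be strictly increasing")
        if values.ndim != 2 or values.shape != (len(gene_ids), len(times)):
            raise ExpressionError(
                f"values shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(times)} times"
            )
        if np.isnan(values).any():
            raise ExpressionError("matrix contains missing values after validation")
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    def subset(self, genes: Iterable[str]) -> "TimeCourseMatrix":
        """Row subset in matrix order; unknown genes raise."""
        wanted = set(genes)
        unknown = wanted - set(self.gene_ids)
        if unknown:
            raise ExpressionError(f"unknown gene ids: {sorted(unknown)[:5]}")
        idx = [i for i, g in enumerate(self.gene_ids) if g in wanted]
        return TimeCourseMatrix(
            [self.gene_ids[i] for i in idx], self.times, self.values[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.times)
        )


@dataclass(frozen=True)
class DEGSet:
    """Differentially expressed genes at a given |log2FC| threshold."""

    gene_ids: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.gene_ids)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.gene_ids)


@dataclass
class Config:
    """Pipeline thresholds and search settings.

    Defaults follow the published analysis: DEG cutoff 1.5 (absolute log2
    fold change), selection of an enriched unit requires at least 9 member
    DEGs in a cluster at corrected p < 0.0025, and the level-stage dual
    significance rule uses corrected p < 0.05 for both tests.
    """

    deg_threshold: float = 1.5
    min_genes: int = 9
    alpha_enrich: float = 0.0025
    alpha_level: float = 0.05
    k_range: tuple[int, int] = (2, 30)
    repeats_per_k: int = 20
    seed: int = 0
    max_mustlink_pairs: int = 100_000

    def __post_init__(self) -> None:
        if self.deg_threshold <= 0:
            raise ValueError("deg_threshold must be positive")
        if self.min_genes < 1:
            raise ValueError("min_genes must be a positive integer")
        for name in ("alpha_enrich", "alpha_level"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError("k_range must be an interval with lower bound >= 2")
        if self.repeats_per_k < 1:
            raise ValueError("repeats_per_k must be positive")


def read_expression(path: str | Path, missing_policy: str = "drop_gene") -> TimeCourseMatrix:
    """Read a delimited gene x time log2 fold-change table.

    The file has a header row of numeric time labels (hours after the
    perturbation) and gene identifiers in the first column. Tab- and
    comma-delimited files are both accepted.

    Parameters
    ----------
    path : path-like
    missing_policy : {"drop_gene", "error"}
        "drop_gene" removes genes with any missing/non-numeric value (with a
        logged warning); "error" raises on the first offending cell.
    """
    if missing_policy not in ("drop_gene", "error"):
        raise ValueError(f"unknown missing_policy: {missing_policy!r}")
    path = Path(path)
    sep = "\t"
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if "\t" not in first and "," in first:
        sep = ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ExpressionError(f"{path}: no time columns found")
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise ExpressionError(f"{path}: non-numeric time label in header: {exc}") from None
    if np.any(np.diff(times) <= 0):
        raise ExpressionError(f"{path}: sampling times are not strictly increasing")
    gene_ids = [str(g) for g in df.index]
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise ExpressionError(f"{path}: duplicate gene id: {g!r}")
        seen.add(g)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(values).any(axis=1)
    if bad.any():
        if missing_policy == "error":
            i = int(np.argmax(bad))
            j = int(np.argmax(np.isnan(values[i])))
            raise ExpressionError(
                f"{path}: non-numeric or missing value for gene {gene_ids[i]!r} "
                f"at time column {df.columns[j]!r}"
            )
        dropped = [g for g, b in zip(gene_ids, bad) if b]
        logger.warning(
            "%s: dropped %d gene(s) with missing values (e.g. %s)",
            path, len(dropped), dropped[:3],
        )
        gene_ids = [g for g, b in zip(gene_ids, bad) if not b]
        values = values[~bad]
    return TimeCourseMatrix(gene_ids, times, values)


def write_expression(matrix: TimeCourseMatrix, path: str | Path) -> None:
    """Write the native tab-delimited dialect (round-trips bit-exactly)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(repr(float(t)) for t in matrix.times) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def filter_degs(matrix: TimeCourseMatrix, threshold: float = 1.5) -> DEGSet:
    """Select genes with max-over-time |log2FC| >= threshold (inclusive).

    A gene qualifies as differentially expressed if its absolute log2 fold
    change reaches the threshold at one or more sampling points.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if matrix.n_genes == 0:
        raise ExpressionError("cannot filter an empty matrix")
    keep = np.max(np.abs(matrix.values), axis=1) >= threshold
    genes = tuple(g for g, k in zip(matrix.gene_ids, keep) if k)
    return DEGSet(genes, threshold)


class ProfileMaxAbsScaler(TransformerMixin, BaseEstimator):
    """Scale each *row* (gene profile) to unit maximum absolute value.

    Unlike feature-wise scalers this operates per sample, so the transform
    is stateless: ``fit`` only validates. Signs are preserved, and every
    scaled profile satisfies ``max |x| == 1`` exactly. All-zero rows cannot
    be scaled and raise.
    """

    def fit(self, X, y=None):  # noqa: D102 - sklearn API
        check_array(X, ensure_min_features=1)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X) -> np.ndarray:  # noqa: D102 - sklearn API
        X = check_array(X, ensure_min_features=1, copy=True)
        maxabs = np.max(np.abs(X), axis=1)
        if np.any(maxabs == 0):
            i = int(np.argmax(maxabs == 0))
            raise ValueError(f"cannot scale all-zero profile at row {i}")
        return X / maxabs[:, None]


def scale_profiles(matrix: TimeCourseMatrix, genes: DEGSet | None = None) -> TimeCourseMatrix:
    """Per-gene unit max-abs scaling of (optionally a DEG subset of) profiles.

    Each row is divided by its own maximum absolute log2 fold change so
    profiles of different amplitude but similar shape become comparable.
    Idempotent: scaling a scaled matrix is a no-op.
    """
    sub = matrix if genes is None else matrix.subset(genes.gene_ids)
    scaled = ProfileMaxAbsScaler().fit_transform(sub.values)
    return TimeCourseMatrix(sub.gene_ids, sub.times, scaled)
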