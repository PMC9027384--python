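"""Constrained k-means on scaled expression profiles, silhouette model selection.

The clustering core is COP-kmeans: Lloyd's algorithm in Euclidean space with
background-knowledge constraints. Must-link pairs are closed transitively
into blocks that are assigned atomically (each block moves to the centroid
nearest its member mean), so must-link-only problems are always feasible.
Cannot-links are honoured greedily during assignment with seeded restarts.

The number of clusters is chosen by repeated computation of the silhouette
validity index over a k range: for every k several seeded restarts are run,
the mean silhouette per k is recorded, and the k with the highest mean wins
(ties break toward the smaller, more parsimonious k).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_random_state

from .expression import Config, TimeCourseMatrix
from .regnet import ConstraintSet

__all__ = [
    "ConstrainedKMeans",
    "ClusterResult",
    "InfeasibleConstraintsError",
    "cop_kmeans",
    "mean_silhouette",
    "select_k",
]


class InfeasibleConstraintsError(RuntimeError):
    """Cannot-link constraints could not be satisfied after restarts."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        super().__init__(
            f"constraints infeasible; violating pairs (sample): {self.pairs[:5]}"
        )


def _union_find_blocks(n: int, must_links: Sequence[tuple[int, int]]) -> np.ndarray:
    """Transitive closure of must-links -> block id per point (0..n_blocks-1)."""
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in must_links:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(n)])
    _, block_of = np.unique(roots, return_inverse=True)
    return block_of


class ConstrainedKMeans(ClusterMixin, BaseEstimator):
    """K-means clustering with must-link / cannot-link constraints.

    Parameters
    ----------
    n_clusters : int, default=8
        Number of clusters k (k = 1 is allowed and trivial).
    must_links : sequence of (int, int), default=()
        Row-index pairs that must share a cluster. Closed transitively into
        blocks assigned as units at the centroid of their members.
    cannot_links : sequence of (int, int), default=()
        Row-index pairs that must not share a cluster.
    init : {"k-means++", "random"}, default="k-means++"
        "random" picks k distinct data points; "k-means++" uses the usual
        distance-weighted seeding.
    n_init : int, default=10
        Independent initialisations per fit; the run with the lowest
        within-cluster sum of squares wins.
    max_iter : int, default=300
    n_feasibility_restarts : int, default=10
        Extra re-initialisations attempted before declaring cannot-links
        infeasible.
    random_state : int, RandomState or None

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster index (0-based) per sample.
    cluster_centers_ : ndarray of shape (n_clusters, n_features)
    inertia_ : float
        Sum of squared distances of samples to their centre.
    n_iter_ : int
    n_feasibility_restarts_ : int
        Restarts actually consumed (0 for must-link-only problems).
    """

    def __init__(
        self,
        n_clusters: int = 8,
        must_links: Sequence[tuple[int, int]] = (),
        cannot_links: Sequence[tuple[int, int]] = (),
        init: str = "k-means++",
        n_init: int = 10,
        max_iter: int = 300,
        n_feasibility_restarts: int = 10,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.must_links = must_links
        self.cannot_links = cannot_links
        self.init = init
        self.n_init = n_init
        self.max_iter = max_iter
        self.n_feasibility_restarts = n_feasibility_restarts
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n, _ = X.shape
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters={k} must lie in [1, n_samples={n}]")
        if self.init not in ("random", "k-means++"):
            raise ValueError(f"unknown init: {self.init!r}")
        rng = check_random_state(self.random_state)

        block_of = _union_find_blocks(n, list(self.must_links))
        n_blocks = int(block_of.max()) + 1
        if k > n_blocks:
            raise ValueError(
                f"n_clusters={k} exceeds the {n_blocks} must-link blocks available"
            )
        # block means and sizes (blocks are assigned as units)
        sizes = np.bincount(block_of, minlength=n_blocks).astype(float)
        bmeans = np.zeros((n_blocks, X.shape[1]))
        for j in range(X.shape[1]):
            bmeans[:, j] = np.bincount(block_of, weights=X[:, j], minlength=n_blocks)
        bmeans /= sizes[:, None]

        cl_blocks: list[tuple[int, int]] = []
        for a, b in self.cannot_links:
            ba, bb = int(block_of[a]), int(block_of[b])
            if ba == bb:
                raise InfeasibleConstraintsError([(a, b)])
            cl_blocks.append((ba, bb))

        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        self.n_feasibility_restarts_ = 0
        best = None  # (block inertia, labels_b, centers, n_iter)
        successes = 0
        for _ in range(self.n_init + self.n_feasibility_restarts):
            result = self._lloyd(X, bmeans, sizes, block_of, cl_blocks, k, rng)
            if result is None:
                self.n_feasibility_restarts_ += 1
                continue
            labels_b, centers, n_iter = result
            diffs = bmeans - centers[labels_b]
            inertia_b = float(np.sum(sizes * np.einsum("ij,ij->i", diffs, diffs)))
            if best is None or inertia_b < best[0]:
                best = (inertia_b, labels_b, centers, n_iter)
            successes += 1
            if successes >= self.n_init:
                break
        if best is None:
            raise InfeasibleConstraintsError(list(self.cannot_links))
        _, labels_b, centers, n_iter = best
        self.labels_ = labels_b[block_of]
        self.cluster_centers_ = centers
        self.n_iter_ = n_iter
        d = np.linalg.norm(X - centers[self.labels_], axis=1)
        self.inertia_ = float(np.sum(d * d))
        return self

    def _lloyd(self, X, bmeans, sizes, block_of, cl_blocks, k, rng):
        n_blocks = bmeans.shape[0]
        centers = self._init_centers(bmeans, sizes, k, rng)
        labels = np.full(n_blocks, -1)
        for it in range(1, self.max_iter + 1):
            D = cdist(bmeans, centers)
            if not cl_blocks:
                new_labels = np.argmin(D, axis=1)
            else:
                new_labels = self._greedy_assign(D, cl_blocks)
                if new_labels is None:
                    return None
            # re-seed empty clusters from the farthest block (deterministic)
            for c in range(k):
                if not np.any(new_labels == c):
                    far = int(np.argmax(D[np.arange(n_blocks), new_labels]))
                    new_labels[far] = c
                    centers[c] = bmeans[far]
            for c in range(k):
                mask = new_labels == c
                w = sizes[mask]
                centers[c] = np.average(bmeans[mask], axis=0, weights=w)
            if np.array_equal(new_labels, labels):
                return labels, centers, it
            labels = new_labels
        return labels, centers, self.max_iter

    def _init_centers(self, bmeans, sizes, k, rng):
        n_blocks = bmeans.shape[0]
        if self.init == "random":
            idx = rng.choice(n_blocks, size=k, replace=False)
            return bmeans[idx].copy()
        # k-means++ on block means
        centers = np.empty((k, bmeans.shape[1]))
        centers[0] = bmeans[rng.randint(n_blocks)]
        d2 = np.sum((bmeans - centers[0]) ** 2, axis=1)
        for c in range(1, k):
            probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n_blocks, 1 / n_blocks)
            centers[c] = bmeans[rng.choice(n_blocks, p=probs)]
            d2 = np.minimum(d2, np.sum((bmeans - centers[c]) ** 2, axis=1))
        return centers

    @staticmethod
    def _greedy_assign(D, cl_blocks):
        """Assign blocks (largest uncertainty last is unnecessary; use index
        order, deterministic) to nearest feasible centre w.r.t. cannot-links."""
        n_blocks, k = D.shape
        forbidden: dict[int, set[int]] = {}
        for a, b in cl_blocks:
            forbidden.setdefault(a, set()).add(b)
            forbidden.setdefault(b, set()).add(a)
        labels = np.full(n_blocks, -1)
        order = np.argsort(np.min(D, axis=1), kind="stable")
        for i in order:
            banned = {labels[j] for j in forbidden.get(int(i), ()) if labels[j] >= 0}
            for c in np.argsort(D[i], kind="stable"):
                if int(c) not in banned:
                    labels[i] = int(c)
                    break
            else:
                return None
        return labels

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict(self, X):
        X = check_array(X, dtype=float)
        return np.argmin(cdist(X, self.cluster_centers_), axis=1)


def mean_silhouette(X, labels) -> float:
    """Mean silhouette index s(i) = (b - a) / max(a, b) with Euclidean distance.

    ``a(i)`` is the mean distance to the other members of i's cluster, ``b(i)``
    the smallest mean distance to another cluster. Points in singleton
    clusters score 0, as do points with a = b = 0 (exact duplicates).
    Requires at least two clusters.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    D = cdist(X, X)
    n = len(labels)
    a = np.zeros(n)
    b = np.full(n, np.inf)
    singleton = np.zeros(n, dtype=bool)
    cluster_sums = {c: D[:, labels == c].sum(axis=1) for c in uniq}
    counts = {c: int(np.sum(labels == c)) for c in uniq}
    for c in uniq:
        mask = labels == c
        if counts[c] == 1:
            singleton[mask] = True
        else:
            a[mask] = cluster_sums[c][mask] / (counts[c] - 1)
        for c2 in uniq:
            if c2 == c:
                continue
            b[mask] = np.minimum(b[mask], cluster_sums[c2][mask] / counts[c2])
    denom = np.maximum(a, b)
    s = np.zeros(n)
    ok = (~singleton) & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return float(np.mean(s))


@dataclass
class ClusterResult:
    """Outcome of silhouette-driven constrained clustering.

    ``assignments`` maps each gene to a 1-based cluster label; labels are
    canonicalised by ascending mean scaled profile over the early third of
    the time course, so down-regulated clusters come first (cosmetic only).
    """

    k: int
    assignments: dict[str, int]
    silhouette_by_k: dict[int, tuple[float, float]]
    seeds: list[int] = field(default_factory=list)
    n_restarts_for_feasibility: int = 0

    def members(self, label: int) -> list[str]:
        return [g for g, c in self.assignments.items() if c == label]

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for c in self.assignments.values():
            sizes[c] = sizes.get(c, 0) + 1
        return sizes


def _constraint_indices(
    matrix: TimeCourseMatrix, constraints: ConstraintSet | None
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    if constraints is None:
        return [], []
    pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    def conv(pairs):
        out = []
        for a, b in sorted(pairs):
            if a not in pos or b not in pos:
                raise ValueError(f"constraint pair ({a!r}, {b!r}) references genes "
                                 "outside the clustering input")
            out.append((pos[a], pos[b]))
        return out
    return conv(constraints.must_links), conv(constraints.cannot_links)


def cop_kmeans(
    matrix: TimeCourseMatrix,
    k: int,
    constraints: ConstraintSet | None = None,
    seed: int | None = None,
    max_iter: int = 300,
) -> dict[str, int]:
    """One constrained k-means run; returns gene -> 1-based cluster label."""
    ml, cl = _constraint_indices(matrix, constraints)
    est = ConstrainedKMeans(
        n_clusters=k, must_links=ml, cannot_links=cl,
        max_iter=max_iter, random_state=seed,
    ).fit(matrix.values)
    return {g: int(lab) + 1 for g, lab in zip(matrix.gene_ids, est.labels_)}


def _canonical_relabel(matrix: TimeCourseMatrix, labels: np.ndarray) -> np.ndarray:
    """Order clusters by mean profile over the first third of time points."""
    t_third = max(1, int(np.ceil(matrix.n_times / 3)))
    uniq = np.unique(labels)
    keys = []
    for c in uniq:
        keys.append((float(matrix.values[labels == c, :t_third].mean()), int(c)))
    order = [c for _, c in sorted(keys)]
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[int(c)] for c in labels])


def select_k(
    matrix: TimeCourseMatrix,
    constraints: ConstraintSet | None,
    config: Config,
) -> ClusterResult:
    """Silhouette-driven choice of the cluster number.

    For every k in ``config.k_range`` runs ``config.repeats_per_k`` seeded
    restarts of constrained k-means on the scaled profiles, records mean and
    sd of the silhouette index, picks the k with the largest mean (ties ->
    smallest k) and returns the best-silhouette partition at that k. Fully
    deterministic given ``config.seed``.
    """
    lo, hi = config.k_range
    n = matrix.n_genes
    hi = min(hi, n - 1)
    if lo > hi:
        raise ValueError(f"k_range lower bound {lo} exceeds usable maximum {hi}")
    ml, cl = _constraint_indices(matrix, constraints)
    ks = list(range(lo, hi + 1))
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(ks) * config.repeats_per_k)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    silhouette_by_k: dict[int, tuple[float, float]] = {}
    best_run: dict[int, tuple[float, np.ndarray]] = {}
    restarts_used = 0
    i = 0
    for k in ks:
        scores = []
        for _ in range(config.repeats_per_k):
            est = ConstrainedKMeans(
                n_clusters=k, must_links=ml, cannot_links=cl, random_state=seeds[i]
            ).fit(matrix.values)
            i += 1
            restarts_used += est.n_feasibility_restarts_
            s = mean_silhouette(matrix.values, est.labels_)
            scores.append(s)
            if k not in best_run or s > best_run[k][0]:
                best_run[k] = (s, est.labels_.copy())
        sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
        silhouette_by_k[k] = (float(np.mean(scores)), sd)
    best_k = max(ks, key=lambda k: (silhouette_by_k[k][0], -k))
    labels = _canonical_relabel(matrix, best_run[best_k][1])
    assignments = {g: int(c) for g, c in zip(matrix.gene_ids, labels)}
    return ClusterResult(
        k=best_k,
        assignments=assignments,
        silhouette_by_k=silhouette_by_k,
        seeds=seeds,
        n_restarts_for_feasibility=restarts_used,
    )
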