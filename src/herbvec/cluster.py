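"""k-means partitioning of herbs in activity-score planes.

Two solvers share one result type: a Lloyd iteration with k-means++
seeding and many restarts, and an exact solver that finds the globally
wss-minimal partition by depth-first enumeration of set partitions with
branch-and-bound pruning (feasible for small panels; for n=15, k=3 there
are 2,375,101 partitions into exactly 3 non-empty blocks).

Clusters are canonically labelled 1..k by ascending Euclidean norm of the
centroid: because the percent scale is inverted, cluster 1 is always the
most active (strongest combined inhibition) group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["ClusterConfig", "ClusterResult", "kmeans_lloyd", "kmeans_exact",
           "canonical_labels", "cluster_points"]

Point = tuple[str, tuple[float, ...]]


@dataclass(frozen=True)
class ClusterConfig:
    k: int = 3
    algorithm: str = "auto"  # "auto" | "exact" | "lloyd"
    restarts: int = 100
    seed: int = 0
    scaling: str = "none"  # "none" | "zscore"
    exact_max_n: int = 18  # enumeration guard

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.algorithm not in ("auto", "exact", "lloyd"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.scaling not in ("none", "zscore"):
            raise ValueError(f"unknown scaling {self.scaling!r}")


@dataclass(frozen=True)
class ClusterResult:
    """A k-means partition: assignments, centroids (in input coordinates),
    total within-cluster sum of squares, and the label order."""

    assignments: dict[str, int]
    centroids: dict[int, tuple[float, ...]]
    wss: float
    labels: tuple[int, ...]
    algorithm: str = ""

    def members(self, label: int) -> tuple[str, ...]:
        return tuple(sorted(h for h, c in self.assignments.items() if c == label))

    def sizes(self) -> dict[int, int]:
        return {lab: len(self.members(lab)) for lab in self.labels}


def _prepare(points: Sequence[Point], config: ClusterConfig):
    """Sort by herb_id (order invariance) and optionally z-score the axes."""
    pts = sorted(points, key=lambda p: p[0])
    ids = [p[0] for p in pts]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate herb_id among points")
    X = np.asarray([p[1] for p in pts], dtype=float)
    if X.size and not np.all(np.isfinite(X)):
        raise ValueError("coordinates must be finite")
    if config.k > len(ids):
        raise ValueError(f"k={config.k} exceeds number of points n={len(ids)}")
    scale_mean = np.zeros(X.shape[1]) if X.size else np.zeros(0)
    scale_sd = np.ones_like(scale_mean)
    if config.scaling == "zscore":
        scale_mean = X.mean(axis=0)
        scale_sd = X.std(axis=0, ddof=0)
        scale_sd[scale_sd == 0] = 1.0
        X = (X - scale_mean) / scale_sd
    return ids, X, (scale_mean, scale_sd)


def _wss_of(X: np.ndarray, assign: np.ndarray, k: int) -> float:
    total = 0.0
    for c in range(k):
        m = X[assign == c]
        if len(m):
            total += float(((m - m.mean(axis=0)) ** 2).sum())
    return total


def _result_from(ids, X, assign, k, scale, algorithm) -> ClusterResult:
    mean, sd = scale
    assignments = {}
    centroids = {}
    labels_present = sorted(set(int(a) for a in assign))
    # compact labels to 0..m-1 preserving order of first appearance by id order
    remap = {lab: i for i, lab in enumerate(labels_present)}
    for herb, a in zip(ids, assign):
        assignments[herb] = remap[int(a)]
    for lab in labels_present:
        cen = X[assign == lab].mean(axis=0) * sd + mean
        centroids[remap[lab]] = tuple(float(v) for v in cen)
    wss = _wss_of(X, assign, k)
    return ClusterResult(
        assignments=assignments,
        centroids=centroids,
        wss=wss,
        labels=tuple(range(len(labels_present))),
        algorithm=algorithm,
    )


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
        else:
            centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd_once(X: np.ndarray, k: int, rng: np.random.Generator):
    centers = _kmeanspp_init(X, k, rng)
    prev = None
    for _ in range(300):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)  # ties -> lowest centroid index
        # repair empty clusters: re-seed at the point farthest from its centroid
        for c in range(k):
            if not np.any(assign == c):
                far = d2[np.arange(len(X)), assign].argmax()
                assign[far] = c
        if prev is not None and np.array_equal(assign, prev):
            break
        prev = assign.copy()
        for c in range(k):
            centers[c] = X[assign == c].mean(axis=0)
    return assign, _wss_of(X, assign, k)


def kmeans_lloyd(points: Sequence[Point], config: ClusterConfig) -> ClusterResult:
    """Best-of-restarts Lloyd k-means, deterministic given ``config.seed``."""
    ids, X, scale = _prepare(points, config)
    rng = np.random.default_rng(config.seed)
    best_assign, best_wss = None, math.inf
    for _ in range(config.restarts):
        assign, wss = _lloyd_once(X, config.k, rng)
        if wss < best_wss - 1e-12:
            best_assign, best_wss = assign, wss
    result = _result_from(ids, X, best_assign, config.k, scale, "lloyd")
    return canonical_labels(result)


def kmeans_exact(points: Sequence[Point], config: ClusterConfig) -> ClusterResult:
    """Globally wss-minimal partition into at most k non-empty clusters.

    Depth-first search over restricted-growth strings (points sorted by
    herb_id) with an additive lower bound: appending point x to a cluster
    of current size m and mean mu increases wss by m/(m+1) * ||x - mu||^2,
    so a partial wss already exceeding the incumbent prunes the branch.
    Ties resolve to the lexicographically smallest assignment vector
    because the search visits assignment vectors in lexicographic order
    and only strictly better solutions replace the incumbent.
    """
    ids, X, scale = _prepare(points, config)
    n, k = len(ids), config.k
    if n > config.exact_max_n:
        raise ValueError(
            f"n={n} exceeds exact_max_n={config.exact_max_n}; use algorithm='lloyd'"
        )
    d = X.shape[1]
    counts = [0] * k
    sums = np.zeros((k, d))
    assign = np.zeros(n, dtype=int)
    best_assign = None
    best_wss = math.inf

    def dfs(i: int, used: int, wss_so_far: float) -> None:
        nonlocal best_assign, best_wss
        if wss_so_far >= best_wss:
            return
        if i == n:
            best_wss = wss_so_far
            best_assign = assign.copy()
            return
        x = X[i]
        max_label = min(used, k - 1)  # RGS: may open at most one new block
        for c in range(max_label + 1):
            m = counts[c]
            if m == 0:
                delta = 0.0
            else:
                mu = sums[c] / m
                diff = x - mu
                delta = (m / (m + 1)) * float(diff @ diff)
            new_wss = wss_so_far + delta
            if new_wss >= best_wss:
                continue
            assign[i] = c
            counts[c] += 1
            sums[c] += x
            dfs(i + 1, max(used, c + 1), new_wss)
            counts[c] -= 1
            sums[c] -= x
        assign[i] = 0

    dfs(0, 0, 0.0)
    result = _result_from(ids, X, best_assign, k, scale, "exact")
    return canonical_labels(result)


def canonical_labels(result: ClusterResult) -> ClusterResult:
    """Relabel clusters 1..k by ascending centroid norm (1 = most active).

    Equal-norm ties are broken by the smallest member herb_id.
    """
    order = sorted(
        result.centroids,
        key=lambda lab: (
            math.sqrt(sum(v * v for v in result.centroids[lab])),
            result.members(lab)[0] if result.members(lab) else "",
        ),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return replace(
        result,
        assignments={h: remap[c] for h, c in result.assignments.items()},
        centroids={remap[c]: cen for c, cen in result.centroids.items()},
        labels=tuple(range(1, len(order) + 1)),
    )


def cluster_points(points: Sequence[Point], config: ClusterConfig) -> ClusterResult:
    """Dispatch to the exact solver for small panels, Lloyd otherwise."""
    if config.algorithm == "exact":
        return kmeans_exact(points, config)
    if config.algorithm == "lloyd":
        return kmeans_lloyd(points, config)
    if len(points) <= config.exact_max_n:
        return kmeans_exact(points, config)
    return kmeans_lloyd(points, config)
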