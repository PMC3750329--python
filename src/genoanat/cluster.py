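"""k-means voxel parcellation with the min-WCSS restart protocol.

Lloyd's algorithm is restarted (default 10 times) from initial centers
drawn uniformly without replacement from distinct data rows, and the run
with the smallest within-cluster sum of squares (WCSS) is kept. The number
of clusters is tied to the anatomy: k equals the number of distinct brain
structures present at the ontology level under study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = ["ClusteringResult", "kmeans", "choose_k"]

MAX_LLOYD_ITER = 300


@dataclass
class ClusteringResult:
    """Best-of-restarts k-means partition.

    ``wcss`` is the minimum within-cluster sum of squared distances across
    all restarts; ``best_restart`` indexes which restart achieved it;
    ``wcss_per_restart`` keeps the full log for diagnostics.
    """

    labels: np.ndarray
    k: int
    wcss: float
    restarts_run: int
    best_restart: int
    wcss_per_restart: np.ndarray

    def __post_init__(self) -> None:
        assert self.labels.min() >= 0 and self.labels.max() < self.k
        assert self.wcss >= 0


def _assign(X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-center assignment and per-point squared distance."""
    # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; ||x||^2 constant per row
    cross = X @ centers.T
    c_sq = np.einsum("ij,ij->i", centers, centers)
    scores = c_sq[None, :] - 2.0 * cross
    labels = np.argmin(scores, axis=1)
    x_sq = np.einsum("ij,ij->i", X, X)
    d2 = x_sq + scores[np.arange(len(labels)), labels]
    return labels, np.maximum(d2, 0.0)


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    prev_wcss = np.inf
    for _ in range(MAX_LLOYD_ITER):
        new_labels, d2 = _assign(X, centers)
        # empty-cluster repair: seed each empty cluster with the point
        # farthest from its current center, then reassign
        for j in range(k):
            if not (new_labels == j).any():
                far = int(np.argmax(d2))
                centers[j] = X[far]
                new_labels, d2 = _assign(X, centers)
        wcss = float(d2.sum())
        # WCSS never increases across Lloyd iterations
        assert wcss <= prev_wcss + 1e-6 * max(1.0, abs(prev_wcss))
        if (new_labels == labels).all():
            labels = new_labels
            break
        labels = new_labels
        prev_wcss = wcss
        for j in range(k):
            mask = labels == j
            centers[j] = X[mask].mean(axis=0)
    _, d2 = _assign(X, centers)
    return labels, float(d2.sum())


def kmeans(X: np.ndarray, k: int, restarts: int = 10, seed: int = 0) -> ClusteringResult:
    """Cluster rows of X into k groups, keeping the min-WCSS restart.

    Restarts use distinct sub-seeds spawned deterministically from ``seed``,
    so the whole procedure is reproducible.

    Raises
    ------
    DomainError
        If k < 1 or k > n.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError(f"X must be 2-D, got {X.shape}")
    if not np.isfinite(X).all():
        raise ValidationError("X must be finite")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise DomainError(f"k={k} must be in [1, n={n}]")
    if restarts < 1:
        raise DomainError("restarts must be >= 1")

    seeds = np.random.SeedSequence(seed).spawn(restarts)
    best_labels: np.ndarray | None = None
    log = np.empty(restarts)
    best = 0
    for r in range(restarts):
        labels, wcss = _lloyd(X, k, np.random.default_rng(seeds[r]))
        log[r] = wcss
        if best_labels is None or wcss < log[best]:
            best_labels, best = labels, r
    assert best_labels is not None
    return ClusteringResult(
        labels=best_labels,
        k=k,
        wcss=float(log[best]),
        restarts_run=restarts,
        best_restart=best,
        wcss_per_restart=log,
    )


def choose_k(labels_at_level: np.ndarray) -> int:
    """k = number of distinct anatomical structures present in the data.

    Structures at the level that annotate no retained voxel are not counted:
    after filtering they cannot appear, and a cluster with no attainable
    members would be vacuous.
    """
    labels_at_level = np.asarray(labels_at_level)
    if labels_at_level.size == 0:
        raise DomainError("cannot choose k from an empty label vector")
    return int(np.unique(labels_at_level).size)
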