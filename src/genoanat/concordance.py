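"""Class-to-cluster consistency measures: NMI, ARI, purity, S-index.

Voxel annotations act as class labels; a k-means partition supplies the
cluster labels. All four measures are computed from one r x c contingency
table (classes by clusters):

* **purity** — each cluster is assigned to its most frequent class; the
  measure is the fraction of correctly assigned voxels. Insensitive to
  over-clustering.
* **NMI** — mutual information between the two labelings normalized by the
  arithmetic mean of their entropies (natural logs; the base cancels).
* **ARI** — Hubert-Arabie adjusted Rand index: the chance-corrected
  fraction of voxel pairs on which the two partitions agree.
* **S-index** — voxel-weighted containment, sum over cells of
  (n_ij / N) * n_ij / min(n_i., n_.j). Equal to 1 exactly when every
  cluster nests inside a class or vice versa; any cluster that straddles
  class boundaries is penalized, unlike purity. (The published parcellation-
  comparison literature defines an S-index only verbally; this is the
  simplest statistic with the stated subset-relationship property, and the
  ``variant`` flag leaves room for alternatives behind the same contract.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ValidationError

__all__ = [
    "ContingencyTable",
    "ConcordanceScores",
    "contingency",
    "purity",
    "nmi",
    "ari",
    "s_index",
    "score_all",
]


@dataclass
class ContingencyTable:
    """Counts of voxels per (class, cluster) cell, with marginals."""

    counts: np.ndarray  # (r, c) nonnegative ints
    class_ids: np.ndarray  # row index -> original class label
    cluster_ids: np.ndarray  # col index -> original cluster label

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or (self.counts < 0).any():
            raise ValidationError("counts must be a nonnegative 2-D table")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def N(self) -> int:
        return int(self.counts.sum())


@dataclass
class ConcordanceScores:
    nmi: float
    ari: float
    purity: float
    s_index: float


def contingency(class_labels, cluster_labels) -> ContingencyTable:
    """Cross-tabulate two equal-length label vectors.

    Rows/columns are ordered by sorted unique label value, so the table is
    deterministic for a given pair of inputs.
    """
    a = np.asarray(class_labels)
    b = np.asarray(cluster_labels)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"label vectors must be equal-length 1-D, got {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValidationError("label vectors must be non-empty")
    class_ids, ai = np.unique(a, return_inverse=True)
    cluster_ids, bi = np.unique(b, return_inverse=True)
    counts = np.zeros((class_ids.size, cluster_ids.size), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)
    return ContingencyTable(counts=counts, class_ids=class_ids, cluster_ids=cluster_ids)


def _require_nonempty(t: ContingencyTable) -> None:
    if t.N == 0:
        raise DomainError("contingency table is empty")


def purity(t: ContingencyTable) -> float:
    """Fraction of voxels whose cluster's plurality class matches their own.

    Ties between classes within a cluster break toward the smallest class
    index; the score is unaffected (only the implied assignment is)."""
    _require_nonempty(t)
    return float(t.counts.max(axis=0).sum() / t.N)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi(t: ContingencyTable) -> float:
    """Mutual information over the arithmetic mean of marginal entropies.

    Defined as 1 when both labelings are single-block (zero entropies: each
    is perfectly predictable from the other)."""
    _require_nonempty(t)
    N = t.N
    pij = t.counts / N
    pi = t.row_totals / N
    pj = t.col_totals / N
    h_class = _entropy(pi)
    h_clust = _entropy(pj)
    if h_class == 0.0 and h_clust == 0.0:
        return 1.0
    if _identical_partitions(t) and h_class > 0.0:
        return 1.0  # exact by definition; avoids rounding to 1 - eps
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])).sum())
    denom = (h_class + h_clust) / 2.0
    if denom == 0.0:
        # one labeling constant, the other not: no information to gain
        return 0.0
    # MI and the entropy mean are equal up to rounding for identical
    # partitions; the true value always lies in [0, 1]
    return float(min(1.0, max(0.0, mi / denom)))


def ari(t: ContingencyTable) -> float:
    """Hubert-Arabie adjusted Rand index.

    (sum_ij C(n_ij,2) - E) / (mean of marginal pair sums - E), where E is
    the expected pair agreement under the permutation null. Degenerate
    denominators (both partitions all singletons or both single-block) give
    1 for identical partitions, else 0.
    """
    _require_nonempty(t)
    N = t.N
    if N < 2:
        raise DomainError("ARI needs at least 2 samples")

    def c2(x: np.ndarray) -> float:
        x = x.astype(float)
        return float((x * (x - 1) / 2.0).sum())

    sum_ij = c2(t.counts.reshape(-1))
    sum_i = c2(t.row_totals)
    sum_j = c2(t.col_totals)
    total = N * (N - 1) / 2.0
    expected = sum_i * sum_j / total
    denom = (sum_i + sum_j) / 2.0 - expected
    if denom == 0.0:
        return 1.0 if _identical_partitions(t) else 0.0
    return float((sum_ij - expected) / denom)


def _identical_partitions(t: ContingencyTable) -> bool:
    # identical iff every row and every column has exactly one nonzero cell
    nz_per_row = (t.counts > 0).sum(axis=1)
    nz_per_col = (t.counts > 0).sum(axis=0)
    return bool((nz_per_row == 1).all() and (nz_per_col == 1).all())


def s_index(t: ContingencyTable, variant: str = "weighted-containment") -> float:
    """Voxel-weighted containment between classes and clusters.

    sum_ij (n_ij / N) * n_ij / min(n_i., n_.j). Every pure subset
    relationship contributes its full weight; straddling overlaps are
    penalized by the containment factor < 1.
    """
    if variant != "weighted-containment":
        raise DomainError(f"unknown S-index variant {variant!r}")
    _require_nonempty(t)
    mins = np.minimum.outer(t.row_totals, t.col_totals).astype(float)
    nz = t.counts > 0
    return float((t.counts[nz] / t.N * (t.counts[nz] / mins[nz])).sum())


def score_all(class_labels, cluster_labels) -> ConcordanceScores:
    """All four measures from one contingency table."""
    t = contingency(class_labels, cluster_labels)
    return ConcordanceScores(
        nmi=nmi(t), ari=ari(t), purity=purity(t), s_index=s_index(t)
    )
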