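"""Exact t-SNE (from first principles) and a centered-PCA baseline.

t-SNE maps n voxels with d-dimensional expression vectors x_i to map points
y_i in 2 or 10 dimensions. The high-dimensional similarity of x_j to x_i is
the Gaussian conditional probability

    p_{j|i} = exp(-||x_i - x_j||^2 / 2 sigma_i^2) / sum_{k != i} exp(-||x_i - x_k||^2 / 2 sigma_i^2)

with p_{i|i} = 0. Each sigma_i is tuned by binary search so the row's
perplexity 2^H(P_i) matches a user-set value (default 30, recommended range
5-50) — a smooth effective-neighbor count. Conditionals are symmetrized,
p_ij = (p_{j|i} + p_{i|j}) / 2, and divided by 2n so P sums to one over all
pairs. Low-dimensional similarities use the heavy-tailed Student t kernel
with one degree of freedom,

    q_ij = (1 + ||y_i - y_j||^2)^-1 / sum_{k != l} (1 + ||y_k - y_l||^2)^-1,

which sidesteps the crowding problem. The map is learned by gradient descent
with momentum on KL(P || Q) = sum_ij p_ij log(p_ij / q_ij), whose gradient is

    dC/dy_i = 4 sum_j (p_ij - q_ij) (y_i - y_j) (1 + ||y_i - y_j||^2)^-1 ,

with early exaggeration of P during the first iterations. The asymmetry of
the KL divergence makes the method favor preserving local structure: placing
true neighbors far apart is expensive, merging far-apart points is cheap.

This is the exact O(n^2) algorithm: memory grows with the square of the
voxel count (~3 GB of working set near n = 30,000, the enforced cap); for
larger inputs use a tree-approximated implementation instead.

The PCA baseline centers the matrix and projects it onto the top-m right
singular directions, with a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numba
import numpy as np

from .exceptions import DomainError, ShapeError, ValidationError

__all__ = [
    "TsneConfig",
    "AffinityMatrix",
    "Embedding",
    "pairwise_sq_dists",
    "calibrate_affinities",
    "low_dim_affinities",
    "kl_cost",
    "tsne_gradient",
    "run_tsne",
    "run_pca",
]

N_CAP = 30_000  # exact t-SNE keeps several n x n matrices in memory


@dataclass(frozen=True)
class TsneConfig:
    """Optimization schedule and affinity settings.

    The defaults are the standard published schedule for exact t-SNE:
    1000 gradient steps at learning rate 200, momentum 0.5 switching to 0.8
    at step 250, early exaggeration x4 for the first 100 steps, and a tiny
    Gaussian initialization (sd 1e-4).
    """

    perplexity: float = 30.0
    n_iter: int = 1000
    learning_rate: float = 200.0
    momentum_early: float = 0.5
    momentum_late: float = 0.8
    momentum_switch_iter: int = 250
    early_exaggeration_factor: float = 4.0
    early_exaggeration_iter: int = 100
    init_sd: float = 1e-4
    seed: int = 0
    min_prob_floor: float = 1e-12
    calib_tol: float = 1e-7  # on log-perplexity
    calib_max_iter: int = 50

    def __post_init__(self) -> None:
        if self.perplexity < 1:
            raise DomainError(f"perplexity must be >= 1, got {self.perplexity}")
        if self.n_iter < 1:
            raise DomainError("n_iter must be >= 1")


@dataclass
class AffinityMatrix:
    """Symmetrized high-dimensional affinities and their calibration.

    ``P_cond[i, j]`` is p_{j|i} (rows sum to 1, zero diagonal); ``P`` is the
    symmetrized matrix normalized to total sum 1; ``sigmas[i]`` is the
    Gaussian bandwidth realizing the requested perplexity at point i.
    """

    P: np.ndarray
    P_cond: np.ndarray
    sigmas: np.ndarray
    perplexity: float

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def realized_perplexities(self) -> np.ndarray:
        """2^H of each conditional row (base-2 entropy)."""
        Pc = self.P_cond
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(Pc > 0, Pc * np.log2(Pc), 0.0)
        return 2.0 ** (-plogp.sum(axis=1))


@dataclass
class Embedding:
    """Map points produced by one dimensionality-reduction run."""

    Y: np.ndarray
    m: int
    method: Literal["tsne", "pca"]
    final_cost: float | None = None

    @property
    def n(self) -> int:
        return self.Y.shape[0]


# ---------------------------------------------------------------------------
# affinities


def pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances ||x_i - x_j||^2, symmetric, zero diagonal."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError(f"X must be 2-D, got shape {X.shape}")
    if not np.isfinite(X).all():
        raise ValidationError("X must be finite")
    sq = np.einsum("ij,ij->i", X, X)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _rows_entropy(D_rows: np.ndarray, beta: np.ndarray,
                  diag_cols: np.ndarray) -> np.ndarray:
    """Shannon entropies (nats) of Gaussian conditional rows at precisions
    beta = 1 / (2 sigma^2), computed stably without materializing the
    probabilities: with logits l_j = -beta d_j shifted by their max L,
    H = log(sum_j e^{l_j - L}) + L + beta * E_p[d]."""
    r = np.arange(len(diag_cols))
    logits = -beta[:, None] * D_rows
    logits[r, diag_cols] = -np.inf  # p_{i|i} = 0
    L = logits.max(axis=1, keepdims=True)
    logits -= L
    np.exp(logits, out=logits)
    e = logits  # renamed: now holds exp(l - L)
    s = e.sum(axis=1)
    mean_d = np.einsum("ij,ij->i", e, D_rows) / s
    return np.log(s) + L[:, 0] + beta * mean_d


def _rows_probs(D_rows: np.ndarray, beta: np.ndarray,
                diag_cols: np.ndarray) -> np.ndarray:
    """Conditional probability rows at the given precisions."""
    r = np.arange(len(diag_cols))
    logits = -beta[:, None] * D_rows
    logits[r, diag_cols] = -np.inf
    logits -= logits.max(axis=1, keepdims=True)
    np.exp(logits, out=logits)
    logits /= logits.sum(axis=1, keepdims=True)
    return logits


def calibrate_affinities(
    D: np.ndarray,
    perplexity: float = 30.0,
    tol: float = 1e-7,
    max_iter: int = 50,
) -> AffinityMatrix:
    """Tune each sigma_i so every conditional row hits the target perplexity.

    Per point, a binary search on the precision beta_i = 1/(2 sigma_i^2)
    drives |log(perplexity_i) - log(perplexity)| below ``tol`` (or stops
    after ``max_iter`` halvings/doublings). Bounds start at (0, inf),
    emulated by doubling/halving until the target is bracketed; the search
    runs vectorized over all not-yet-converged rows at once.

    Raises
    ------
    DomainError
        If ``perplexity`` is below 1 or exceeds n - 1 (a Gaussian row over
        n - 1 neighbors cannot have more than n - 1 effective neighbors).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ShapeError(f"D must be square, got {D.shape}")
    if n < 2:
        raise DomainError("need at least 2 points")
    if not (1.0 <= perplexity <= n - 1):
        raise DomainError(
            f"perplexity {perplexity} infeasible for n={n}: effective neighbors "
            f"must lie in [1, n-1]"
        )
    target_logH = np.log(perplexity)  # 2^{H_2} = e^{H_nats}

    active = np.arange(n)
    beta = np.ones(n)
    lo = np.zeros(n)
    hi = np.full(n, np.inf)

    H = _rows_entropy(D[active], beta[active], active)
    for _ in range(max_iter):
        err = H - target_logH
        conv = np.abs(err) <= tol
        if conv.all():
            break
        # settle converged rows, keep searching on the rest
        active = active[~conv]
        err = err[~conv]
        too_flat = err > 0  # entropy too high -> sharpen (raise beta)
        a_hi = active[too_flat]
        lo[a_hi] = beta[a_hi]
        beta[a_hi] = np.where(np.isinf(hi[a_hi]), beta[a_hi] * 2.0,
                              (beta[a_hi] + hi[a_hi]) / 2.0)
        a_lo = active[~too_flat]
        hi[a_lo] = beta[a_lo]
        beta[a_lo] = np.where(lo[a_lo] == 0.0, beta[a_lo] / 2.0,
                              (beta[a_lo] + lo[a_lo]) / 2.0)
        H = _rows_entropy(D[active], beta[active], active)

    P_cond = _rows_probs(D, beta, np.arange(n))
    sigmas = np.sqrt(1.0 / (2.0 * beta))
    P_sym = (P_cond + P_cond.T) / (2.0 * n)
    return AffinityMatrix(P=P_sym, P_cond=P_cond, sigmas=sigmas,
                          perplexity=perplexity)


def low_dim_affinities(Y: np.ndarray) -> np.ndarray:
    """Student-t (one degree of freedom) joint probabilities q_ij."""
    Q, _ = _student_t_q(np.asarray(Y, dtype=float))
    return Q


def _student_t_q(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (Q, W) where W_ij = (1 + ||y_i - y_j||^2)^-1 with zero
    diagonal and Q = W / W.sum()."""
    if Y.ndim != 2:
        raise ShapeError(f"Y must be 2-D, got {Y.shape}")
    if Y.shape[0] < 2:
        raise DomainError("need at least 2 map points")
    if not np.isfinite(Y).all():
        raise ValidationError("Y must be finite")
    sq = np.einsum("ij,ij->i", Y, Y)
    W = sq[:, None] + sq[None, :]
    W -= 2.0 * (Y @ Y.T)
    W += 1.0
    np.reciprocal(W, out=W)
    np.fill_diagonal(W, 0.0)
    Q = W / W.sum()
    return Q, W


def kl_cost(P: np.ndarray, Q: np.ndarray, floor: float = 1e-12) -> float:
    """KL(P || Q) over off-diagonal pairs, with 0 log(0/q) := 0.

    Q entries are floored at ``floor`` before the log so vanishing kernel
    values cannot produce infinities.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValidationError(f"shape mismatch {P.shape} vs {Q.shape}")
    Qf = np.maximum(Q, floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P / Qf), 0.0)
    np.fill_diagonal(terms, 0.0)
    return float(terms.sum())


def tsne_gradient(P: np.ndarray, W: np.ndarray, Q: np.ndarray,
                  Y: np.ndarray) -> np.ndarray:
    """Analytic gradient of KL(P||Q) with respect to the map points:
    dC/dy_i = 4 sum_j (p_ij - q_ij) W_ij (y_i - y_j)."""
    n = Y.shape[0]
    if P.shape != (n, n) or Q.shape != (n, n) or W.shape != (n, n):
        raise ShapeError("P, W, Q must be n x n matching Y's n")
    M = (P - Q) * W
    return 4.0 * (Y * M.sum(axis=1)[:, None] - M @ Y)


# ---------------------------------------------------------------------------
# optimizers

# fused single-pass kernels for the O(n^2) gradient step; they avoid the
# repeated full-matrix temporaries that dominate the numpy formulation at
# atlas scale (thousands of voxels)


@numba.njit(cache=False, fastmath=True)
def _student_t_kernel_inplace(Y, W):  # pragma: no cover - exercised via run_tsne
    n, m = Y.shape
    wsum = 0.0
    for i in range(n):
        W[i, i] = 0.0
        for j in range(i + 1, n):
            d = 0.0
            for t in range(m):
                diff = Y[i, t] - Y[j, t]
                d += diff * diff
            w = 1.0 / (1.0 + d)
            W[i, j] = w
            W[j, i] = w
            wsum += 2.0 * w
    return wsum


@numba.njit(cache=False, fastmath=True)
def _student_t_kernel_inplace_2d(Y, W):  # pragma: no cover
    n = Y.shape[0]
    wsum = 0.0
    for i in range(n):
        yi0 = Y[i, 0]
        yi1 = Y[i, 1]
        s = 0.0
        for j in range(n):
            d0 = yi0 - Y[j, 0]
            d1 = yi1 - Y[j, 1]
            w = 1.0 / (1.0 + d0 * d0 + d1 * d1)
            W[i, j] = w
            s += w
        W[i, i] = 0.0
        wsum += s - 1.0  # drop the self-pair (d = 0 -> w = 1)
    return wsum


@numba.njit(cache=False, fastmath=True)
def _gradient_inplace_2d(Y, P, W, inv_wsum, exag, grad):  # pragma: no cover
    n = Y.shape[0]
    for i in range(n):
        msum = 0.0
        g0 = 0.0
        g1 = 0.0
        for j in range(n):
            w = W[i, j]
            mij = (exag * P[i, j] - w * inv_wsum) * w
            msum += mij
            g0 += mij * Y[j, 0]
            g1 += mij * Y[j, 1]
        grad[i, 0] = 4.0 * (msum * Y[i, 0] - g0)
        grad[i, 1] = 4.0 * (msum * Y[i, 1] - g1)


@numba.njit(cache=False, fastmath=True)
def _gradient_inplace(Y, P, W, inv_wsum, exag, grad):  # pragma: no cover
    n, m = Y.shape
    for i in range(n):
        msum = 0.0
        for t in range(m):
            grad[i, t] = 0.0
        for j in range(n):
            w = W[i, j]
            mij = (exag * P[i, j] - w * inv_wsum) * w
            msum += mij
            for t in range(m):
                grad[i, t] -= mij * Y[j, t]
        for t in range(m):
            grad[i, t] = 4.0 * (grad[i, t] + msum * Y[i, t])


def run_tsne(X: np.ndarray, m: int = 2, cfg: TsneConfig | None = None) -> Embedding:
    """Embed the rows of X into m dimensions by exact t-SNE.

    Fully deterministic for a fixed config (including the seed). The
    reported ``final_cost`` is the KL divergence against the un-exaggerated
    P at the returned map.
    """
    cfg = cfg or TsneConfig()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise DomainError(f"t-SNE needs at least 4 points, got {n}")
    if n > N_CAP:
        raise DomainError(
            f"n={n} exceeds the exact-algorithm cap of {N_CAP}; the O(n^2) "
            f"affinity matrices would not fit in ordinary memory"
        )
    if not cfg.perplexity < n - 1:
        raise DomainError(
            f"perplexity {cfg.perplexity} infeasible for n={n} (must be < n-1)"
        )
    D = pairwise_sq_dists(X)
    aff = calibrate_affinities(D, cfg.perplexity, tol=cfg.calib_tol,
                               max_iter=cfg.calib_max_iter)
    P = np.maximum(aff.P, cfg.min_prob_floor)

    # float32 keeps the O(n^2) inner loop memory-bandwidth friendly at
    # atlas scale; small problems stay in float64
    dtype = np.float32 if n >= 1000 else np.float64
    P_run = P.astype(dtype)
    rng = np.random.default_rng(cfg.seed)
    Y = rng.normal(0.0, cfg.init_sd, (n, m)).astype(dtype)
    V = np.zeros_like(Y)
    W = np.empty((n, n), dtype=dtype)  # Student-t kernel, reused per iter
    grad = np.empty_like(Y)

    for it in range(cfg.n_iter):
        exag = cfg.early_exaggeration_factor if it < cfg.early_exaggeration_iter else 1.0
        if m == 2:
            w_sum = _student_t_kernel_inplace_2d(Y, W)
            _gradient_inplace_2d(Y, P_run, W, dtype(1.0 / w_sum), dtype(exag), grad)
        else:
            w_sum = _student_t_kernel_inplace(Y, W)
            _gradient_inplace(Y, P_run, W, dtype(1.0 / w_sum), dtype(exag), grad)
        mom = cfg.momentum_early if it < cfg.momentum_switch_iter else cfg.momentum_late
        V *= mom
        V -= cfg.learning_rate * grad
        Y = Y + V
        Y -= Y.mean(axis=0, keepdims=True)

    Yf = Y.astype(float)
    final_kl = kl_cost(P, low_dim_affinities(Yf), floor=cfg.min_prob_floor)
    return Embedding(Y=Yf, m=m, method="tsne", final_cost=final_kl)


def run_pca(X: np.ndarray, m: int) -> Embedding:
    """Project the centered matrix onto its top-m principal components.

    Components are ordered by decreasing singular value; each component's
    sign is fixed so its largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError(f"X must be 2-D, got {X.shape}")
    n, d = X.shape
    if not 1 <= m <= min(n, d):
        raise DomainError(f"m={m} must be in [1, min(n, d)={min(n, d)}]")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(m):
        k = np.argmax(np.abs(Vt[j]))
        if Vt[j, k] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    Y = U[:, :m] * S[:m]
    return Embedding(Y=Y, m=m, method="pca", final_cost=None)
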