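"""Matrix-factorization solvers for linear unmixing.

A hyperspectral matrix ``X (m, n)`` — channels by pixels — is approximated
as ``X ~ U V`` with ``U (m, k)`` holding the k endmember spectra and
``V (k, n)`` the per-pixel abundances.  One framework covers the classical
unmixing family by switching loss, hard constraints and soft regularizers:

======================  =============================================
truncated SVD / PCA     Frobenius loss, orthonormal factors
NMF                     ``min ||X - UV||_F^2,  U >= 0, V >= 0``
sparse NMF              ``+ lambda1 * ||V||_1`` (drives insignificant
                        abundances toward zero)
graph-regularized NMF   ``+ lambda2 * tr(V L V^T)`` over a pixel graph
                        (smooth abundance maps)
sum-to-one NMF (pLSI)   KL loss, abundance columns on the simplex
======================  =============================================

Multiplicative (Lee-Seung style) updates are the default solver: each step
is a closed-form majorize-minimize move, so the objective trace is
non-increasing — a property the tests assert on every run.  HALS
(hierarchical alternating least squares) is offered for faster Frobenius
fits.  Scale and permutation ambiguity is resolved only at reporting time:
columns of ``U`` are normalized to unit l2 at exit with the scales folded
into ``V``, leaving the product ``U V`` unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .datamodel import DataMatrix
from .graph import SpatialGraph, edge_roughness
from .preprocess import mean_center

__all__ = [
    "UnmixingConfig",
    "FactorModel",
    "svd_truncated",
    "pca",
    "nmf",
    "sparse_nmf",
    "graph_nmf",
    "sum_to_one_nmf",
    "objective",
    "reconstruct",
    "residual",
    "WORKED_PIXEL_ABUNDANCE",
    "count_insignificant",
]

_EPS = 1e-12

#: Textbook four-endmember pixel: two significant abundances and two
#: insignificant ones that an l1 penalty would push to zero.  Carried as a
#: fixture for the significance-floor bookkeeping.
WORKED_PIXEL_ABUNDANCE = np.array([0.48, 0.49, 0.015, 0.015])


def count_insignificant(abundances: np.ndarray, floor: float = 0.05) -> int:
    """Number of abundance entries below the significance floor."""
    return int(np.count_nonzero(np.asarray(abundances) < floor))


@dataclass
class UnmixingConfig:
    """Everything that determines a factorization run.

    Parameters
    ----------
    k
        Number of endmembers (components), >= 1.
    loss
        ``"frobenius"`` or ``"kl"`` (generalized Kullback-Leibler; requires
        non-negative data).
    lambda1
        Weight of the l1 sparsity penalty on ``V`` (>= 0, Frobenius only).
    lambda2
        Weight of the spatial smoothness penalty ``tr(V L V^T)``
        (>= 0, Frobenius only; needs a pixel graph).
    sum_to_one
        Constrain every abundance column to the probability simplex.
        Solved by the pLSI route (KL loss), so ``loss`` must be ``"kl"``.
    solver
        ``"multiplicative"`` (monotone, any loss) or ``"hals"``
        (Frobenius only, supports lambda1, no graph term).
    init
        ``"random"`` (seeded uniform, scaled to the data) or ``"nndsvd"``
        (deterministic SVD-based non-negative start).
    literal_penalty
        Use the literal penalty form ``lambda2 * ||V W V^T||_F^2`` with the
        similarity matrix ``W`` instead of the Laplacian trace.  Provided
        for fidelity to the printed formulation; it shrinks
        similarity-weighted co-activation rather than roughness and carries
        no monotonicity guarantee.
    """

    k: int
    loss: str = "frobenius"
    lambda1: float = 0.0
    lambda2: float = 0.0
    sum_to_one: bool = False
    solver: str = "multiplicative"
    init: str = "random"
    seed: int = 0
    tol: float = 1e-6
    max_iter: int = 500
    literal_penalty: bool = False

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.loss not in ("frobenius", "kl"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization constants must be non-negative")
        if self.solver not in ("multiplicative", "hals"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.solver == "hals" and self.loss != "frobenius":
            raise ValueError("hals solver supports the frobenius loss only")
        if self.solver == "hals" and self.lambda2 > 0:
            raise ValueError("the spatial penalty requires the multiplicative solver")
        if self.sum_to_one and self.loss != "kl":
            raise ValueError("sum_to_one uses the pLSI route: set loss='kl'")
        if self.loss == "kl" and (self.lambda1 > 0 or self.lambda2 > 0):
            raise ValueError("sparsity/spatial penalties are defined for the frobenius loss")
        if self.init not in ("random", "nndsvd"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be > 0 and max_iter >= 1")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "loss": self.loss,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "sum_to_one": self.sum_to_one,
            "solver": self.solver,
            "init": self.init,
            "seed": self.seed,
            "tol": self.tol,
            "max_iter": self.max_iter,
            "literal_penalty": self.literal_penalty,
        }


@dataclass
class FactorModel:
    """Result of a factorization: factors, diagnostics, and provenance."""

    U: np.ndarray
    V: np.ndarray
    config: Optional[UnmixingConfig] = None
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = False
    n_iter: int = 0
    method: str = "nmf"
    singular_values: Optional[np.ndarray] = None
    mean: Optional[np.ndarray] = None
    explained_variance_ratio: Optional[np.ndarray] = None
    column_scales: Optional[np.ndarray] = None
    grid_shape: Optional[tuple[int, int]] = None
    channel_axis: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.U.shape[1]


# ---------------------------------------------------------------------------
# orthogonal family: truncated SVD and PCA
# ---------------------------------------------------------------------------


def _unwrap(X) -> tuple[np.ndarray, Optional[tuple[int, int]], Optional[np.ndarray]]:
    if isinstance(X, DataMatrix):
        return X.X, X.grid_shape, np.asarray(X.channel_axis)
    return np.asarray(X, dtype=float), None, None


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-magnitude spectral coordinate positive."""
    for i in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] *= -1
            V[i, :] *= -1
    return U, V


def svd_truncated(X, k: int) -> FactorModel:
    """Best rank-``k`` approximation in the Frobenius norm (Eckart-Young).

    Returns orthonormal ``U (m, k)``, ``V (k, n)`` (orthonormal rows) and the
    non-increasing singular values; reconstruction is ``U diag(s) V``.
    """
    arr, grid, chan = _unwrap(X)
    m, n = arr.shape
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k={k} out of range for a {m} x {n} matrix")
    U, s, Vt = np.linalg.svd(arr, full_matrices=False)
    U, Vt = _fix_signs(U[:, :k].copy(), Vt[:k].copy())
    err = float(np.sum(s[k:] ** 2))
    return FactorModel(
        U=U,
        V=Vt,
        singular_values=s[:k].copy(),
        method="svd",
        objective_trace=np.array([err]),
        converged=True,
        grid_shape=grid,
        channel_axis=chan,
        meta={"all_singular_values": s},
    )


def pca(A, k: int) -> FactorModel:
    """PCA as SVD of the mean-centered matrix, with explained variance.

    The mean over samples is subtracted from each feature, the centered
    matrix is decomposed by SVD, and the top-``k`` components are kept.
    Component signs follow the convention of :func:`svd_truncated`.
    """
    arr, grid, chan = _unwrap(A)
    Xc, mu = mean_center(arr)
    model = svd_truncated(Xc, k)
    s_all = model.meta["all_singular_values"]
    total = float(np.sum(s_all**2))
    evr = (model.singular_values**2 / total) if total > 0 else np.zeros(k)
    model.method = "pca"
    model.mean = mu
    model.explained_variance_ratio = evr
    model.grid_shape = grid
    model.channel_axis = chan
    return model


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def _generalized_kl(P: np.ndarray, Q: np.ndarray) -> float:
    """sum P log(P/Q) - P + Q with the 0 log 0 = 0 convention."""
    Q = np.maximum(Q, _EPS)
    mask = P > 0
    val = float(np.sum(Q) - np.sum(P))
    val += float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))
    return val


def objective(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    config: UnmixingConfig,
    graph: Optional[SpatialGraph] = None,
) -> float:
    """Configured loss plus penalties — the pure function solvers minimize.

    For sum-to-one (pLSI) models the loss is evaluated against the
    column-normalized data, so pass the matrix on the scale the solver used.
    """
    X = np.asarray(X, dtype=float)
    R = U @ V
    if config.loss == "frobenius":
        val = float(np.sum((X - R) ** 2))
    else:
        val = _generalized_kl(X, R)
    if config.lambda1 > 0:
        val += config.lambda1 * float(np.sum(np.abs(V)))
    if config.lambda2 > 0:
        if graph is None:
            raise ValueError("lambda2 > 0 requires a pixel graph")
        if config.literal_penalty:
            W = graph.W
            M = (W @ V.T).T if not isinstance(W, np.ndarray) else V @ W
            val += config.lambda2 * float(np.sum((M @ V.T) ** 2))
        else:
            val += config.lambda2 * edge_roughness(V, graph)
    return val


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _init_factors(X: np.ndarray, config: UnmixingConfig) -> tuple[np.ndarray, np.ndarray]:
    m, n = X.shape
    k = config.k
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        scale = np.sqrt(max(X.mean(), _EPS) / k)
        return rng.uniform(0, 1, (m, k)) * scale, rng.uniform(0, 1, (k, n)) * scale
    return _nndsvd(X, k)


def _nndsvd(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative double SVD start (deterministic); zeros filled with the
    data mean so multiplicative updates are not trapped at exact zeros."""
    U0, s, Vt0 = np.linalg.svd(X, full_matrices=False)
    m, n = X.shape
    U = np.zeros((m, k))
    V = np.zeros((k, n))
    U[:, 0] = np.sqrt(s[0]) * np.abs(U0[:, 0])
    V[0, :] = np.sqrt(s[0]) * np.abs(Vt0[0, :])
    for j in range(1, min(k, len(s))):
        u, v = U0[:, j], Vt0[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            base, uu, vv = n_up * n_vp, up / max(n_up, _EPS), vp / max(n_vp, _EPS)
        else:
            base, uu, vv = n_un * n_vn, un / max(n_un, _EPS), vn / max(n_vn, _EPS)
        U[:, j] = np.sqrt(s[j] * base) * uu
        V[j, :] = np.sqrt(s[j] * base) * vv
    fill = max(X.mean(), _EPS) / 100.0
    U[U <= 0] = fill
    V[V <= 0] = fill
    return U, V


# ---------------------------------------------------------------------------
# NMF solvers
# ---------------------------------------------------------------------------


def _check_monotone(trace: np.ndarray, rel_tol: float = 1e-10) -> bool:
    prev = trace[:-1]
    ok = trace[1:] <= prev + rel_tol * np.maximum(np.abs(prev), 1.0)
    return bool(np.all(ok))


def _converged(trace: list[float], tol: float) -> bool:
    if len(trace) < 2:
        return False
    prev, cur = trace[-2], trace[-1]
    return abs(prev - cur) <= tol * max(abs(prev), _EPS)


def _mu_frobenius(
    X: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    config: UnmixingConfig,
    graph: Optional[SpatialGraph],
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    lam1, lam2 = config.lambda1, config.lambda2
    W = d = None
    if graph is not None and lam2 > 0 and not config.literal_penalty:
        W, d = graph.W, graph.degree
    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        U *= (X @ V.T) / (U @ (V @ V.T) + _EPS)
        numer = U.T @ X
        denom = (U.T @ U) @ V + _EPS
        if lam1 > 0:
            denom = denom + lam1 / 2.0
        if lam2 > 0 and not config.literal_penalty:
            VW = (W @ V.T).T if not isinstance(W, np.ndarray) else V @ W
            numer = numer + lam2 * VW
            denom = denom + lam2 * (V * d[None, :])
        elif lam2 > 0 and config.literal_penalty:
            # heuristic positive-gradient split of  lambda2 ||V W V^T||_F^2
            Wg = graph.W
            VW = (Wg @ V.T).T if not isinstance(Wg, np.ndarray) else V @ Wg
            denom = denom + 2.0 * lam2 * (VW @ V.T) @ VW
        V *= numer / denom
        trace.append(objective(X, U, V, config, graph))
        if _converged(trace, config.tol):
            converged = True
            break
    return U, V, trace, converged


def _mu_kl(
    X: np.ndarray, U: np.ndarray, V: np.ndarray, config: UnmixingConfig
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        R = X / np.maximum(U @ V, _EPS)
        U *= (R @ V.T) / (V.sum(axis=1)[None, :] + _EPS)
        R = X / np.maximum(U @ V, _EPS)
        V *= (U.T @ R) / (U.sum(axis=0)[:, None] + _EPS)
        trace.append(objective(X, U, V, config))
        if _converged(trace, config.tol):
            converged = True
            break
    return U, V, trace, converged


def _plsi(
    X: np.ndarray, config: UnmixingConfig
) -> tuple[np.ndarray, np.ndarray, list[float], bool, np.ndarray, np.ndarray]:
    """pLSI EM: KL-NMF with column-stochastic factors.

    The data matrix is column-normalized (per-pixel totals stored); the EM
    iteration keeps every column of ``U`` and of ``V`` exactly on the
    simplex while monotonically decreasing KL(Xn || U V).
    """
    m, n = X.shape
    k = config.k
    col_sums = X.sum(axis=0)
    zero_cols = col_sums <= 0
    if np.any(zero_cols):
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero pixel column(s): abundances set to uniform 1/k",
            RuntimeWarning,
        )
    safe = np.where(zero_cols, 1.0, col_sums)
    Xn = X / safe[None, :]
    rng = np.random.default_rng(config.seed)
    U = rng.uniform(0.1, 1.0, (m, k))
    U /= U.sum(axis=0, keepdims=True)
    V = rng.uniform(0.1, 1.0, (k, n))
    V /= V.sum(axis=0, keepdims=True)
    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        R = Xn / np.maximum(U @ V, _EPS)
        V_new = V * (U.T @ R)
        U_new = U * (R @ V.T)
        U = U_new / np.maximum(U_new.sum(axis=0, keepdims=True), _EPS)
        vsum = V_new.sum(axis=0, keepdims=True)
        V = np.where(vsum > 0, V_new / np.maximum(vsum, _EPS), 1.0 / k)
        trace.append(_generalized_kl(Xn, U @ V))
        if _converged(trace, config.tol):
            converged = True
            break
    V[:, zero_cols] = 1.0 / k
    # exact renormalization of the simplex columns (float drift <= 1e-12)
    V /= V.sum(axis=0, keepdims=True)
    return U, V, trace, converged, col_sums, zero_cols


def _hals(
    X: np.ndarray, U: np.ndarray, V: np.ndarray, config: UnmixingConfig
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    lam1 = config.lambda1
    trace: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        A = X @ V.T
        B = V @ V.T
        for j in range(config.k):
            bjj = max(B[j, j], _EPS)
            u = U[:, j] + (A[:, j] - U @ B[:, j]) / bjj
            U[:, j] = np.maximum(u, 0.0)
        C = U.T @ X
        D = U.T @ U
        for j in range(config.k):
            djj = max(D[j, j], _EPS)
            v = V[j, :] + (C[j, :] - D[j, :] @ V) / djj - lam1 / (2.0 * djj)
            V[j, :] = np.maximum(v, 0.0)
        trace.append(objective(X, U, V, config))
        if _converged(trace, config.tol):
            converged = True
            break
    return U, V, trace, converged


def nmf(X, config: UnmixingConfig, graph: Optional[SpatialGraph] = None) -> FactorModel:
    """Non-negative matrix factorization under the configured constraints.

    Dispatches on ``config``: plain/sparse/graph-regularized Frobenius NMF
    (multiplicative or HALS), KL NMF, or the pLSI sum-to-one route.  The
    returned model's objective trace includes every penalty term and is
    non-increasing for the multiplicative and HALS solvers.
    """
    config.validate()
    arr, grid, chan = _unwrap(X)
    m, n = arr.shape
    if np.any(arr < 0):
        raise ValueError("NMF requires a non-negative matrix (preprocess first)")
    if config.k >= min(m, n):
        warnings.warn(
            f"k={config.k} is not small relative to min(m, n)={min(m, n)}; "
            "the factorization is no longer a low-rank summary",
            RuntimeWarning,
        )
    if config.lambda2 > 0:
        if graph is None:
            raise ValueError("lambda2 > 0 requires a pixel graph")
        if graph.n_pixels != n:
            raise ValueError(
                f"graph covers {graph.n_pixels} pixels but the matrix has {n}"
            )

    meta: dict = {}
    column_scales = None
    if config.sum_to_one:
        U, V, trace, converged, col_sums, zero_cols = _plsi(arr, config)
        column_scales = col_sums
        meta["zero_pixel_columns"] = int(zero_cols.sum())
    else:
        U, V = _init_factors(arr, config)
        if config.loss == "kl":
            U, V, trace, converged = _mu_kl(arr, U, V, config)
        elif config.solver == "hals":
            U, V, trace, converged = _hals(arr, U, V, config)
        else:
            U, V, trace, converged = _mu_frobenius(arr, U, V, config, graph)
        # reporting-time scale convention: unit-l2 endmembers, scales in V
        norms = np.linalg.norm(U, axis=0)
        norms[norms == 0] = 1.0
        U = U / norms[None, :]
        V = V * norms[:, None]

    trace_arr = np.asarray(trace)
    if not config.literal_penalty and len(trace_arr) > 1 and not _check_monotone(trace_arr):
        warnings.warn("objective trace increased beyond tolerance", RuntimeWarning)
        meta["monotone"] = False
    else:
        meta["monotone"] = True
    return FactorModel(
        U=U,
        V=V,
        config=config,
        objective_trace=trace_arr,
        converged=converged,
        n_iter=len(trace_arr),
        method="plsi" if config.sum_to_one else "nmf",
        column_scales=column_scales,
        grid_shape=grid,
        channel_axis=chan,
        meta=meta,
    )


def sparse_nmf(X, config: UnmixingConfig, graph: Optional[SpatialGraph] = None) -> FactorModel:
    """NMF with an l1 abundance penalty (``lambda1 > 0``)."""
    if config.lambda1 < 0:
        raise ValueError("lambda1 must be non-negative")
    return nmf(X, config, graph)


def graph_nmf(X, graph: SpatialGraph, config: UnmixingConfig) -> FactorModel:
    """Spatially regularized (graph-Laplacian) sparse NMF."""
    if graph is None:
        raise ValueError("graph_nmf requires a pixel graph")
    return nmf(X, config, graph)


def sum_to_one_nmf(X, config: UnmixingConfig) -> FactorModel:
    """Simplex-constrained unmixing: abundances are fractional weights."""
    if not config.sum_to_one:
        config = replace(config, sum_to_one=True, loss="kl")
    return nmf(X, config)


# ---------------------------------------------------------------------------
# reconstruction and residuals
# ---------------------------------------------------------------------------


def reconstruct(model: FactorModel) -> np.ndarray:
    """Model reconstruction on the scale of the original data matrix."""
    if model.method in ("svd", "pca"):
        R = model.U @ np.diag(model.singular_values) @ model.V
        if model.mean is not None:
            R = R + model.mean[:, None]
        return R
    R = model.U @ model.V
    if model.column_scales is not None:
        R = R * model.column_scales[None, :]
    return R


def residual(model: FactorModel, X) -> np.ndarray:
    """Per-pixel relative l2 reconstruction error, rendered on the grid.

    ``err_j = ||x_j - xhat_j|| / ||x_j||`` (absolute norm where ``x_j = 0``).
    Returns a ``(ny, nx)`` map when the model knows its grid, else a vector.
    """
    arr, grid, _ = _unwrap(X)
    R = reconstruct(model)
    if R.shape != arr.shape:
        raise ValueError("model and matrix shapes disagree")
    num = np.linalg.norm(arr - R, axis=0)
    den = np.linalg.norm(arr, axis=0)
    err = np.where(den > 0, num / np.where(den > 0, den, 1.0), num)
    grid = grid if grid is not None else model.grid_shape
    if grid is not None:
        return err.reshape(grid)
    return err
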