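"""Pixel-similarity graphs for the spatial-smoothness regularizer.

The regularized solvers penalize abundance roughness across graph edges via
the graph Laplacian quadratic form
``tr(V L V^T) = 1/2 * sum_ij W_ij * ||v_i - v_j||^2``,
where ``W`` is a symmetric non-negative similarity matrix with zero
diagonal and ``L = D - W`` with ``D = diag(row sums)``.

Two constructions are provided: the default cheap grid adjacency (the
neighboring pixels (x-1, y), (x+1, y), ... around each (x, y)), and a
Gaussian kernel on pairwise spectral distances — for a 128 x 128-pixel
dataset the latter is conceptually a 16384 x 16384 symmetric zero-diagonal
matrix, which is why a kNN-truncated sparse variant is offered alongside
the dense float32 path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .datamodel import DataMatrix

__all__ = [
    "SpatialGraph",
    "build_grid_adjacency",
    "build_feature_similarity",
    "laplacian",
    "edge_roughness",
]


@dataclass
class SpatialGraph:
    """Symmetric non-negative similarity matrix over pixels, plus its Laplacian.

    ``W`` may be a scipy sparse matrix or a dense ndarray; invariants
    (symmetry, zero diagonal) are checked at construction.
    """

    W: "sp.spmatrix | np.ndarray"
    scheme: str = "unspecified"
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        n = self.W.shape[0]
        if self.W.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if sp.issparse(self.W):
            self.W = self.W.tocsr()
            if self.W.diagonal().any():
                raise ValueError("similarity matrix must have zero diagonal")
            asym = abs(self.W - self.W.T)
            if asym.nnz and asym.max() > 1e-10:
                raise ValueError("similarity matrix must be symmetric")
            if self.W.nnz and self.W.data.min() < 0:
                raise ValueError("similarity weights must be non-negative")
        else:
            self.W = np.asarray(self.W)
            if np.any(np.diagonal(self.W) != 0):
                raise ValueError("similarity matrix must have zero diagonal")
            # sampled symmetry check keeps the dense 16384^2 path cheap
            if n > 512:
                idx = np.random.default_rng(0).integers(0, n, size=(2048, 2))
                if not np.allclose(
                    self.W[idx[:, 0], idx[:, 1]], self.W[idx[:, 1], idx[:, 0]], atol=1e-6
                ):
                    raise ValueError("similarity matrix must be symmetric")
            elif not np.allclose(self.W, self.W.T, atol=1e-10):
                raise ValueError("similarity matrix must be symmetric")
            if n and self.W.min() < 0:
                raise ValueError("similarity weights must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.W.shape[0]

    @property
    def degree(self) -> np.ndarray:
        """Per-pixel total edge weight (row sums of W)."""
        if sp.issparse(self.W):
            return np.asarray(self.W.sum(axis=1)).ravel()
        return self.W.sum(axis=1)

    def laplacian(self) -> "sp.spmatrix | np.ndarray":
        return laplacian(self)

    def to_edge_list(self) -> np.ndarray:
        """Upper-triangular edges as (i, j, weight) rows for text export."""
        if sp.issparse(self.W):
            coo = sp.triu(self.W, k=1).tocoo()
            return np.column_stack([coo.row, coo.col, coo.data])
        iu = np.triu_indices(self.n_pixels, k=1)
        w = self.W[iu]
        keep = w != 0
        return np.column_stack([iu[0][keep], iu[1][keep], w[keep]])


def laplacian(graph: SpatialGraph) -> "sp.spmatrix | np.ndarray":
    """Graph Laplacian ``D - W``; rows sum to zero and the matrix is PSD."""
    d = graph.degree
    if sp.issparse(graph.W):
        return (sp.diags(d) - graph.W).tocsr()
    return np.diag(d) - graph.W


def build_grid_adjacency(grid_shape: tuple[int, int], connectivity: int = 4) -> SpatialGraph:
    """Unit-weight adjacency of the pixel grid (4- or 8-neighborhood).

    Pixels are indexed in the package raster order (``y * nx + x``).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    ny, nx = int(grid_shape[0]), int(grid_shape[1])
    if ny < 1 or nx < 1:
        raise ValueError("grid dimensions must be >= 1")
    idx = np.arange(ny * nx).reshape(ny, nx)
    rows, cols = [], []

    def add(a: np.ndarray, b: np.ndarray) -> None:
        rows.append(a.ravel())
        cols.append(b.ravel())

    if nx > 1:
        add(idx[:, :-1], idx[:, 1:])
    if ny > 1:
        add(idx[:-1, :], idx[1:, :])
    if connectivity == 8 and ny > 1 and nx > 1:
        add(idx[:-1, :-1], idx[1:, 1:])
        add(idx[:-1, 1:], idx[1:, :-1])

    n = ny * nx
    if rows:
        i = np.concatenate(rows)
        j = np.concatenate(cols)
        data = np.ones(len(i))
        W = sp.coo_matrix((data, (i, j)), shape=(n, n))
        W = (W + W.T).tocsr()
    else:
        W = sp.csr_matrix((n, n))
    return SpatialGraph(W=W, scheme=f"grid{connectivity}", grid_shape=(ny, nx))


def _median_pairwise_distance(points: np.ndarray, seed: int = 0, max_points: int = 1000) -> float:
    """Median Euclidean distance over a seeded subsample (bandwidth heuristic)."""
    rng = np.random.default_rng(seed)
    n = points.shape[0]
    if n > max_points:
        points = points[rng.choice(n, size=max_points, replace=False)]
    from scipy.spatial.distance import pdist

    d = pdist(points)
    med = float(np.median(d)) if d.size else 1.0
    return med if med > 0 else 1.0


def build_feature_similarity(
    X: "DataMatrix | np.ndarray",
    kernel_bandwidth: float | None = None,
    knn: int | None = None,
    seed: int = 0,
    dtype: type = np.float32,
) -> SpatialGraph:
    """Gaussian-kernel similarity on pairwise spectral distances between pixels.

    ``W_ij = exp(-d_ij^2 / (2 sigma^2))`` on the Euclidean distance between
    pixel spectra (columns of ``X``), symmetrized, diagonal forced to zero.
    With ``knn`` set, only each pixel's ``knn`` nearest neighbors are kept
    and the result is sparse (``W <- max(W, W^T)`` preserves symmetry);
    otherwise the full dense ``n x n`` matrix is built in ``dtype``
    (float32 by default: 1 GiB for 16384 pixels).

    ``sigma`` defaults to the median pairwise distance of a seeded
    1000-pixel subsample.
    """
    arr = X.X if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    grid_shape = X.grid_shape if isinstance(X, DataMatrix) else None
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need an (m, n) matrix with at least 2 pixels")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite features")
    points = np.ascontiguousarray(arr.T)  # (n, m): one row per pixel
    n = points.shape[0]
    sigma = kernel_bandwidth if kernel_bandwidth is not None else _median_pairwise_distance(points, seed=seed)
    if sigma <= 0:
        raise ValueError("kernel_bandwidth must be positive")
    gamma = 1.0 / (2.0 * sigma * sigma)

    if knn is not None:
        k = min(int(knn), n - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(points)
        dist, ind = nn.kneighbors(points)
        w = np.exp(-gamma * dist[:, 1:] ** 2)
        rows = np.repeat(np.arange(n), k)
        W = sp.coo_matrix((w.ravel(), (rows, ind[:, 1:].ravel())), shape=(n, n)).tocsr()
        W = W.maximum(W.T)
        W.setdiag(0.0)
        W.eliminate_zeros()
        return SpatialGraph(W=W, scheme=f"feature-knn{k}", grid_shape=grid_shape)

    # dense path, chunked so peak memory stays near the n x n output itself
    pts = points.astype(dtype, copy=False)
    sq = np.einsum("ij,ij->i", pts, pts)
    W = np.empty((n, n), dtype=dtype)
    chunk = max(1, int(2**25 // max(n, 1)))  # ~32M-entry row blocks
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * pts[start:stop] @ pts.T
        np.maximum(d2, 0.0, out=d2)
        W[start:stop] = np.exp(-gamma * d2)
    W = np.maximum(W, W.T) if n <= 4096 else _symmetrize_inplace(W)
    np.fill_diagonal(W, 0.0)
    return SpatialGraph(W=W, scheme="feature-dense", grid_shape=grid_shape)


def _symmetrize_inplace(W: np.ndarray, block: int = 2048) -> np.ndarray:
    """Blockwise W <- max(W, W^T) without allocating a full transposed copy."""
    n = W.shape[0]
    for i0 in range(0, n, block):
        i1 = min(i0 + block, n)
        for j0 in range(i0, n, block):
            j1 = min(j0 + block, n)
            a = W[i0:i1, j0:j1]
            b = W[j0:j1, i0:i1].T
            m = np.maximum(a, b)
            W[i0:i1, j0:j1] = m
            W[j0:j1, i0:i1] = m.T
    return W


def edge_roughness(V: np.ndarray, graph: SpatialGraph) -> float:
    """Abundance roughness across graph edges: ``sum_ij W_ij ||v_i - v_j||^2 / 2``.

    Equals ``tr(V L V^T)`` — the quantity the spatial regularizer shrinks.
    """
    V = np.asarray(V, dtype=float)
    L = graph.laplacian()
    if sp.issparse(L):
        return float(np.sum(V * (L @ V.T).T))
    return float(np.trace(V @ L @ V.T))
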