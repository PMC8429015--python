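"""kNN heat-kernel affinity graphs and graph Laplacians.

The subspace objective penalizes projections that tear apart samples
that are close in the original feature space. The penalty is the
Laplacian quadratic form tr(P'X L X'P) of a k-nearest-neighbour graph
with heat-kernel weights w_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import squareform, pdist


class GraphParameterError(ValueError):
    pass


@dataclasses.dataclass
class AffinityGraph:
    """Symmetric nonnegative affinity matrix with its construction parameters."""

    W: np.ndarray
    k: int
    sigma: float
    view_tag: str = ""


@dataclasses.dataclass
class GraphLaplacian:
    """Unnormalized graph Laplacian L = D - W with degree diagonal D."""

    L: np.ndarray
    D: np.ndarray  # diagonal entries D_ii = sum_j w_ij

    @property
    def n(self) -> int:
        return self.L.shape[0]


def build_affinity(X: np.ndarray, k: int, sigma: float | str = "median", view_tag: str = "") -> AffinityGraph:
    """Build the kNN heat-kernel affinity graph over the columns of X.

    An edge (i, j) receives weight exp(-||x_i - x_j||^2 / (2 sigma^2))
    when x_i is among the k nearest neighbours of x_j (i != j); the
    directed weight matrix is then symmetrized by elementwise maximum
    (union-kNN), which keeps the graph undirected while preserving all
    neighbour relations. Neighbour ties are broken toward the lowest
    column index.

    Parameters
    ----------
    X
        d x n feature block; graph nodes are columns (subjects).
    k
        Neighbour count, 1 <= k <= n - 1.
    sigma
        Heat-kernel bandwidth: a positive float, or ``"median"`` to use
        the median Euclidean distance over the retained kNN pairs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise GraphParameterError(f"X must be 2-D (d x n), got shape {X.shape}")
    n = X.shape[1]
    if n < 2:
        raise GraphParameterError(f"need at least 2 samples, got n={n}")
    if not 1 <= k <= n - 1:
        raise GraphParameterError(f"k must satisfy 1 <= k <= n-1={n - 1}, got {k}")

    dist = squareform(pdist(X.T, metric="euclidean"))
    # neighbour sets: k nearest columns of each x_j, stable sort for tie-breaks
    neighbour_mask = np.zeros((n, n), dtype=bool)
    for j in range(n):
        order = np.argsort(dist[:, j], kind="stable")
        order = order[order != j][:k]
        neighbour_mask[order, j] = True

    if isinstance(sigma, str):
        if sigma != "median":
            raise GraphParameterError(f"unknown sigma policy {sigma!r}")
        retained = dist[neighbour_mask]
        sigma_val = float(np.median(retained))
        if sigma_val <= 0.0:  # all retained pairs coincident
            sigma_val = 1.0
    else:
        sigma_val = float(sigma)
        if sigma_val <= 0.0:
            raise GraphParameterError(f"sigma must be > 0, got {sigma_val}")

    W = np.where(neighbour_mask, np.exp(-(dist**2) / (2.0 * sigma_val**2)), 0.0)
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    return AffinityGraph(W=W, k=k, sigma=sigma_val, view_tag=view_tag)


def build_laplacian(graph: AffinityGraph) -> GraphLaplacian:
    """L = D - W with D_ii the row sums of W; requires symmetric W."""
    W = np.asarray(graph.W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise GraphParameterError(f"W must be square, got shape {W.shape}")
    if not np.allclose(W, W.T, atol=1e-12):
        raise GraphParameterError("affinity matrix must be symmetric")
    D = W.sum(axis=1)
    L = np.diag(D) - W
    return GraphLaplacian(L=L, D=D)


def smoothness(P: np.ndarray, X: np.ndarray, lap: GraphLaplacian) -> float:
    """Graph-regularization value tr(P'X L X'P).

    Equals 0.5 * sum_ij w_ij ||a_i - a_j||^2 where a_i is the i-th
    column of P'X, hence is nonnegative for any valid Laplacian.
    """
    P = np.asarray(P, dtype=float)
    X = np.asarray(X, dtype=float)
    if P.shape[0] != X.shape[0]:
        raise GraphParameterError(
            f"P has {P.shape[0]} rows but X has {X.shape[0]} features"
        )
    if X.shape[1] != lap.n:
        raise GraphParameterError(
            f"X has {X.shape[1]} samples but Laplacian is {lap.n} x {lap.n}"
        )
    A = P.T @ X  # c x n
    return float(np.sum((A @ lap.L) * A))
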