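"""kNN graphs in the kernel feature space and their unnormalized Laplacians.

The RKHS squared distance between feature-mapped points is
``2 - 2 K[i, j]`` for a unit-diagonal Gaussian kernel, so neighbor ranking
by kernel value is equivalent to ranking by RKHS (and, monotonically, by
input Euclidean) distance.  Edges are binary and OR-symmetrized: i ~ j if
either is among the other's k nearest.  The Laplacian L = D - W provides
the smoothness penalty Tr(E' L E) = 1/2 sum_ij W_ij ||e_i - e_j||^2 that
keeps kernel-space neighbors close in the shared latent space.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._exceptions import ParameterError, ValidationError
from .kernels import KernelMatrix

__all__ = [
    "GraphLaplacian",
    "rkhs_knn_adjacency",
    "laplacian_from_adjacency",
    "smoothness_penalty",
    "build_graph",
]


@dataclasses.dataclass
class GraphLaplacian:
    adjacency: np.ndarray  # binary, symmetric, hollow
    degree: np.ndarray  # diagonal of D
    laplacian: np.ndarray  # D - W
    k_neighbors: int


def rkhs_knn_adjacency(kernel: KernelMatrix | np.ndarray, k_neighbors: int) -> np.ndarray:
    """Binary OR-symmetrized kNN adjacency from a Gram matrix.

    Neighbors are the k largest off-diagonal kernel entries per row
    (equivalently the k smallest RKHS distances); ties break toward the
    lower index for cross-platform determinism.  A point is never its own
    neighbor.
    """
    gram = kernel.gram if isinstance(kernel, KernelMatrix) else np.asarray(kernel)
    n = gram.shape[0]
    if not 1 <= k_neighbors < n:
        raise ParameterError(f"k_neighbors must be in [1, {n - 1}], got {k_neighbors}")
    masked = gram.copy()
    np.fill_diagonal(masked, -np.inf)
    # stable argsort of -K: descending kernel value, ties by lower index
    order = np.argsort(-masked, axis=1, kind="stable")[:, :k_neighbors]
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k_neighbors)
    W[rows, order.ravel()] = 1.0
    np.maximum(W, W.T, out=W)  # OR symmetrization
    return W


def laplacian_from_adjacency(W: np.ndarray, k_neighbors: int = 0) -> GraphLaplacian:
    """Unnormalized Laplacian L = D - W of a binary symmetric adjacency."""
    W = np.asarray(W, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError("adjacency must be square")
    if not np.array_equal(W, W.T):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValidationError("adjacency must have a zero diagonal")
    if not np.all(np.isin(W, (0.0, 1.0))):
        raise ValidationError("adjacency must be binary")
    degree = W.sum(axis=1)
    laplacian = np.diag(degree) - W
    return GraphLaplacian(adjacency=W, degree=degree, laplacian=laplacian, k_neighbors=k_neighbors)


def build_graph(kernel: KernelMatrix, k_neighbors: int) -> GraphLaplacian:
    """Convenience: adjacency + Laplacian in one call."""
    W = rkhs_knn_adjacency(kernel, k_neighbors)
    return laplacian_from_adjacency(W, k_neighbors=k_neighbors)


def smoothness_penalty(embedding: np.ndarray, laplacian: GraphLaplacian | np.ndarray) -> float:
    """Laplacian quadratic form Tr(E' L E) >= 0 of an embedding."""
    L = laplacian.laplacian if isinstance(laplacian, GraphLaplacian) else np.asarray(laplacian)
    E = np.asarray(embedding, dtype=np.float64)
    if E.ndim == 1:
        E = E[:, None]
    if E.shape[0] != L.shape[0]:
        raise ValidationError(
            f"embedding has {E.shape[0]} rows but Laplacian is {L.shape[0]} x {L.shape[1]}"
        )
    return float(np.einsum("ik,ij,jk->", E, L, E))
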