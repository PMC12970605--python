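"""Gaussian (RBF) intra-dataset kernels with data-driven bandwidths.

Each modality gets its own Gram matrix ``K[i, j] = exp(-||x_i - x_j||^2 /
(2 sigma^2))`` where the bandwidth ``sigma`` defaults to the mean of the
pairwise Euclidean distances within that dataset, so the kernel is tuned
to the dataset's own scale of variability.  The equivalent rate
parameterization ``gamma = 1 / (2 sigma^2)`` is exposed for the
feature-attribution derivatives, which use the same kernel.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import pdist

from ._exceptions import ParameterError, ValidationError

__all__ = ["KernelMatrix", "mean_pairwise_bandwidth", "gaussian_gram", "kernel_cross"]


@dataclasses.dataclass(frozen=True)
class KernelMatrix:
    """An n x n Gaussian Gram matrix together with its bandwidth."""

    gram: np.ndarray
    sigma: float

    @property
    def gamma(self) -> float:
        """Rate parameterization 1 / (2 sigma^2) of the same kernel."""
        return 1.0 / (2.0 * self.sigma**2)

    @property
    def n(self) -> int:
        return self.gram.shape[0]


def mean_pairwise_bandwidth(values: np.ndarray) -> float:
    """Mean Euclidean distance over the n(n-1)/2 unordered point pairs.

    Self-distances are excluded: they are identically zero and carry no
    information about the data's dispersion.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError("bandwidth needs a 2-D matrix with at least 2 rows")
    sigma = float(pdist(values).mean())
    if sigma <= 0.0:
        raise ValidationError("all rows are identical; bandwidth is degenerate (0)")
    return sigma


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances via the expanded inner-product
    form, clamped at zero against floating-point negatives."""
    sq = (
        np.sum(a * a, axis=1)[:, None]
        + np.sum(b * b, axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    np.maximum(sq, 0.0, out=sq)
    return sq


def gaussian_gram(values: np.ndarray, sigma: float | None = None) -> KernelMatrix:
    """Gaussian Gram matrix of a dataset; bandwidth defaults to the mean
    pairwise distance heuristic.  The diagonal is exactly 1."""
    values = np.asarray(values, dtype=np.float64)
    if sigma is None:
        sigma = mean_pairwise_bandwidth(values)
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    sq = _sq_dists(values, values)
    np.fill_diagonal(sq, 0.0)
    gram = np.exp(-sq / (2.0 * sigma**2))
    return KernelMatrix(gram=gram, sigma=float(sigma))


def kernel_cross(
    values_train: np.ndarray, values_query: np.ndarray, sigma: float
) -> np.ndarray:
    """Cross kernel between query and training points.

    Entry ``[q, i] = exp(-||x_query_q - x_train_i||^2 / (2 sigma^2))``;
    with ``values_query == values_train`` this reproduces the Gram matrix.
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    train = np.asarray(values_train, dtype=np.float64)
    query = np.asarray(values_query, dtype=np.float64)
    if train.ndim != 2 or query.ndim != 2 or train.shape[1] != query.shape[1]:
        raise ValidationError(
            f"feature dimensions differ: train {train.shape} vs query {query.shape}"
        )
    return np.exp(-_sq_dists(query, train) / (2.0 * sigma**2))
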