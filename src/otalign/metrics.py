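"""Alignment and clustering evaluation.

FOSCTTM (fraction of samples closer than the true match) scores a paired
alignment: for each cell x_i, the fraction of cells in the other domain
that sit strictly closer to x_i in the shared space than its true partner
does.  0 is perfect, 0.5 is the random-alignment level.  Label transfer
accuracy (LTA) predicts each x cell's label as the modal label of its k
nearest cross-domain neighbors.  Both use Euclidean distance in the
shared space, matching the transport cost's geometry.  Ground-truth
pairings and labels are evaluation-only inputs; the alignment itself
never sees them.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from ._exceptions import ParameterError, ValidationError

__all__ = [
    "foscttm",
    "per_sample_foscttm",
    "label_transfer_accuracy",
    "clustering_scores",
    "foscttm_null",
]


def per_sample_foscttm(
    xe: np.ndarray, ye: np.ndarray, true_match: np.ndarray | None = None
) -> np.ndarray:
    """Per-sample fractions R_i of y cells strictly closer than the true
    match, each normalized by |Y| - 1 (the true match itself excluded)."""
    xe = np.atleast_2d(np.asarray(xe, dtype=np.float64))
    ye = np.atleast_2d(np.asarray(ye, dtype=np.float64))
    n = xe.shape[0]
    if ye.shape[0] != n:
        raise ValidationError(
            "paired evaluation requires equally sized domains "
            f"({n} vs {ye.shape[0]})"
        )
    true_match = np.arange(n) if true_match is None else np.asarray(true_match, dtype=int)
    D = cdist(xe, ye)
    d_true = D[np.arange(n), true_match]
    # strict inequality: equidistant samples (incl. the match) never count
    closer = (D < d_true[:, None]).sum(axis=1)
    return closer / (n - 1)


def foscttm(
    xe: np.ndarray, ye: np.ndarray, true_match: np.ndarray | None = None
) -> float:
    """Mean of the per-sample fractions; lower is better, 0.5 ~ random."""
    return float(per_sample_foscttm(xe, ye, true_match).mean())


def foscttm_null(
    xe: np.ndarray,
    ye: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """FOSCTTM distribution under random cell pairings of the given
    embeddings (the permutation null used to judge alignment
    significance)."""
    xe = np.atleast_2d(np.asarray(xe, dtype=np.float64))
    ye = np.atleast_2d(np.asarray(ye, dtype=np.float64))
    n = xe.shape[0]
    D = cdist(xe, ye)
    rng = np.random.default_rng(seed)
    rows = np.arange(n)
    out = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = rng.permutation(n)
        d_true = D[rows, perm]
        out[p] = (D < d_true[:, None]).sum() / (n * (n - 1))
    return out


def label_transfer_accuracy(
    xe: np.ndarray,
    ye: np.ndarray,
    labels_x: np.ndarray,
    labels_y: np.ndarray,
    k: int = 5,
) -> float:
    """Fraction of x cells whose label matches the modal label of their k
    nearest y neighbors in the shared space.

    Distance ties break toward the lower index (stable sort); modal-label
    ties break toward the smallest label in sort order.
    """
    xe = np.atleast_2d(np.asarray(xe, dtype=np.float64))
    ye = np.atleast_2d(np.asarray(ye, dtype=np.float64))
    labels_x = np.asarray(labels_x)
    labels_y = np.asarray(labels_y)
    if k < 1 or k > ye.shape[0]:
        raise ParameterError(f"k must be in [1, {ye.shape[0]}], got {k}")
    if len(labels_x) != xe.shape[0] or len(labels_y) != ye.shape[0]:
        raise ValidationError("label lengths must match embedding row counts")
    D = cdist(xe, ye)
    nn = np.argsort(D, axis=1, kind="stable")[:, :k]
    correct = 0
    for i in range(xe.shape[0]):
        neigh = labels_y[nn[i]]
        uniq, counts = np.unique(neigh, return_counts=True)
        predicted = uniq[np.argmax(counts)]  # np.unique sorts: smallest label wins ties
        correct += predicted == labels_x[i]
    return correct / xe.shape[0]


def clustering_scores(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Adjusted Rand index, NMI (arithmetic normalization), and purity.

    Entries where ``pred`` carries the pruned sentinel (-1 or "pruned")
    are excluded pairwise before scoring.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValidationError("pred and truth must have equal lengths")
    keep = ~((pred == -1) | (pred.astype(str) == "pruned"))
    pred, truth = pred[keep], truth[keep]
    if len(pred) == 0:
        raise ValidationError("all cells are pruned; nothing to score")
    ari = adjusted_rand_score(truth, pred)
    nmi = normalized_mutual_info_score(truth, pred, average_method="arithmetic")
    purity = 0.0
    for c in np.unique(pred):
        members = truth[pred == c]
        _, counts = np.unique(members, return_counts=True)
        purity += counts.max()
    purity /= len(pred)
    return {"ari": float(ari), "nmi": float(nmi), "purity": float(purity)}
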