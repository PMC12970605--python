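"""Co-clustering of the two cell sets through the transport plan.

The converged transport plan is a weighted bipartite graph between
x-cells (rows) and y-cells (columns); mass concentrates where the two
modalities agree.  Rows and columns are grouped simultaneously by
alternating maximization of bipartite modularity

    Q = (1/m) sum_ij (T_ij - r_i c_j / m) 1[row_cluster(i) = col_cluster(j)],

with m the total transported mass and r, c the plan marginals (a
degree-product null model).  The number of clusters is chosen at the
elbow of the block-constant reconstruction error, and clusters smaller
than a cell-count floor are pruned as noise.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.cluster import KMeans

from ._exceptions import ParameterError, ValidationError

__all__ = [
    "CoClustering",
    "bipartite_modularity",
    "cocluster",
    "select_k_elbow",
    "prune_small",
]

PRUNED = -1  # sentinel assignment for members of pruned clusters


@dataclasses.dataclass
class CoClustering:
    row_assignments: np.ndarray
    col_assignments: np.ndarray
    n_clusters: int
    modularity: float
    pruned: set = dataclasses.field(default_factory=set)


def _as_plan(plan) -> np.ndarray:
    T = plan.plan if hasattr(plan, "plan") else np.asarray(plan, dtype=np.float64)
    if T.ndim != 2 or T.size == 0:
        raise ValidationError("transport plan must be a nonempty 2-D matrix")
    if T.sum() <= 0:
        raise ValidationError("transport plan carries no mass")
    return T


def bipartite_modularity(plan, row_assign: np.ndarray, col_assign: np.ndarray) -> float:
    """Barber-style bipartite modularity of a row/column co-partition."""
    T = _as_plan(plan)
    ra = np.asarray(row_assign, dtype=int)
    ca = np.asarray(col_assign, dtype=int)
    if len(ra) != T.shape[0] or len(ca) != T.shape[1]:
        raise ValidationError("assignment lengths must match plan shape")
    m = T.sum()
    r = T.sum(axis=1)
    c = T.sum(axis=0)
    q = 0.0
    for u in np.unique(np.concatenate([ra, ca])):
        rows = ra == u
        cols = ca == u
        if not rows.any() or not cols.any():
            continue
        q += T[np.ix_(rows, cols)].sum() - r[rows].sum() * c[cols].sum() / m
    return float(q / m)


def _sweep(T, ra, ca, n_clusters, max_sweeps):
    """Alternating coordinate maximization of modularity; each half-sweep
    reassigns one side to its best cluster given the other, so Q never
    decreases."""
    m = T.sum()
    r = T.sum(axis=1)
    c = T.sum(axis=0)
    for _ in range(max_sweeps):
        changed = False
        col_onehot = np.zeros((T.shape[1], n_clusters))
        col_onehot[np.arange(T.shape[1]), ca] = 1.0
        col_mass = c @ col_onehot
        score_rows = T @ col_onehot - np.outer(r, col_mass) / m
        new_ra = np.argmax(score_rows, axis=1)  # ties -> lowest index
        changed |= not np.array_equal(new_ra, ra)
        ra = new_ra
        row_onehot = np.zeros((T.shape[0], n_clusters))
        row_onehot[np.arange(T.shape[0]), ra] = 1.0
        row_mass = r @ row_onehot
        score_cols = T.T @ row_onehot - np.outer(c, row_mass) / m
        new_ca = np.argmax(score_cols, axis=1)
        changed |= not np.array_equal(new_ca, ca)
        ca = new_ca
        if not changed:
            break
    return ra, ca


def cocluster(
    plan,
    n_clusters: int,
    seed: int = 0,
    n_restarts: int = 20,
    max_sweeps: int = 100,
) -> CoClustering:
    """Co-cluster the plan's rows and columns into ``n_clusters`` groups.

    The first restart initializes column assignments by k-means on the
    column profiles of the plan; the remaining restarts start from
    uniform-random column assignments.  Rows are then assigned from the
    columns, and alternating sweeps run to a fixed point.  The restart
    with the highest modularity wins.  Initialization touches only the
    column side, so permuting the plan's rows permutes the row
    assignments identically.
    """
    T = _as_plan(plan)
    n_x, n_y = T.shape
    if n_clusters < 2:
        raise ParameterError("n_clusters must be >= 2")
    if n_clusters > min(n_x, n_y):
        raise ParameterError(
            f"n_clusters={n_clusters} exceeds min(n_x, n_y)={min(n_x, n_y)}"
        )
    rng = np.random.default_rng(seed)
    best: CoClustering | None = None
    for restart in range(n_restarts):
        if restart == 0:
            km = KMeans(n_clusters=n_clusters, n_init=4, random_state=seed)
            ca = km.fit_predict(T.T)
        elif restart == 1:
            # spectral co-clustering start: k-means on the leading left/
            # right singular vectors of the degree-normalized plan;
            # columns only, to keep row-permutation equivariance
            r = T.sum(axis=1)
            c = T.sum(axis=0)
            Tn = T / np.sqrt(np.outer(r, c) + 1e-30)
            _, _, Vt = np.linalg.svd(Tn, full_matrices=False)
            emb_cols = Vt[1:n_clusters].T
            if emb_cols.shape[1] == 0:
                ca = rng.integers(0, n_clusters, size=n_y)
            else:
                km = KMeans(n_clusters=n_clusters, n_init=4, random_state=seed)
                ca = km.fit_predict(emb_cols)
        else:
            ca = rng.integers(0, n_clusters, size=n_y)
        ra = np.zeros(n_x, dtype=int)
        ra, ca = _sweep(T, ra, ca, n_clusters, max_sweeps)
        q = bipartite_modularity(T, ra, ca)
        if best is None or q > best.modularity:
            best = CoClustering(
                row_assignments=ra,
                col_assignments=ca,
                n_clusters=n_clusters,
                modularity=q,
            )
    return best


def _block_means(T, ra, ca, k):
    row_onehot = np.zeros((T.shape[0], k))
    row_onehot[np.arange(T.shape[0]), ra] = 1.0
    col_onehot = np.zeros((T.shape[1], k))
    col_onehot[np.arange(T.shape[1]), ca] = 1.0
    sums = row_onehot.T @ T @ col_onehot
    counts = np.outer(row_onehot.sum(axis=0), col_onehot.sum(axis=0))
    means = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    return means, row_onehot, col_onehot


def _reconstruction_error(T, ra, ca, k) -> float:
    means, row_onehot, col_onehot = _block_means(T, ra, ca, k)
    approx = row_onehot @ means @ col_onehot.T
    return float(np.linalg.norm(T - approx))


def _reconstruction_descent(T, ra, ca, k, max_sweeps=50):
    """Alternating block-k-means sweeps; the squared block-constant
    residual is non-increasing per half-sweep."""
    ra = ra.copy()
    ca = ca.copy()
    for _ in range(max_sweeps):
        means, _, col_onehot = _block_means(T, ra, ca, k)
        S = T @ col_onehot  # S[i, v] = sum over columns in v
        n_v = col_onehot.sum(axis=0)
        # ||T_i - M_u||^2 over columns = const - 2 sum_v S_iv M_uv + sum_v n_v M_uv^2
        cost = -2.0 * S @ means.T + (means**2 @ n_v)[None, :]
        new_ra = np.argmin(cost, axis=1)
        means, row_onehot, _ = _block_means(T, new_ra, ca, k)
        S2 = T.T @ row_onehot
        n_u = row_onehot.sum(axis=0)
        cost2 = -2.0 * S2 @ means + (n_u @ means**2)[None, :]
        new_ca = np.argmin(cost2, axis=1)
        if np.array_equal(new_ra, ra) and np.array_equal(new_ca, ca):
            break
        ra, ca = new_ra, new_ca
    return ra, ca


def _split_largest_residual(T, ra, ca, k):
    """Refine a k-cluster co-partition into k+1 clusters by splitting the
    row or column with the largest residual into a singleton cluster.
    Partition refinement never increases the block-constant error."""
    means, row_onehot, col_onehot = _block_means(T, ra, ca, k)
    resid = T - row_onehot @ means @ col_onehot.T
    row_res = np.sum(resid**2, axis=1)
    col_res = np.sum(resid**2, axis=0)
    ra, ca = ra.copy(), ca.copy()
    if row_res.max() >= col_res.max():
        ra[int(np.argmax(row_res))] = k
    else:
        ca[int(np.argmax(col_res))] = k
    return ra, ca


def select_k_elbow(plan, k_range, seed: int = 0):
    """Choose the cluster count at the elbow of the reconstruction curve.

    For each k (ascending) the co-partition is taken as the better of a
    fresh modularity co-clustering and a refinement of the previous k's
    partition, then polished by block-k-means descent; this nesting makes
    e(k) monotone non-increasing.  The elbow is the k with the largest
    discrete curvature (second difference) of e; a flat curve triggers a
    warning and returns the smallest k.
    """
    T = _as_plan(plan)
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ParameterError("k_range must contain at least 3 values")
    errors = []
    prev = None
    for k in ks:
        candidates = []
        cc = cocluster(T, k, seed=seed)
        candidates.append((cc.row_assignments, cc.col_assignments))
        if prev is not None:
            ra, ca = prev
            for cur_k in range(prev_k, k):
                ra, ca = _split_largest_residual(T, ra, ca, cur_k)
            candidates.append((ra, ca))
        polished = []
        for ra, ca in candidates:
            ra2, ca2 = _reconstruction_descent(T, ra, ca, k)
            polished.append((_reconstruction_error(T, ra2, ca2, k), ra2, ca2))
        err, ra_best, ca_best = min(polished, key=lambda t: t[0])
        if errors and err > errors[-1]:
            # descent guarantees nesting; guard against float slack
            err = errors[-1]
        errors.append(err)
        prev = (ra_best, ca_best)
        prev_k = k
    errors = np.asarray(errors)
    curvature = errors[:-2] - 2 * errors[1:-1] + errors[2:]
    scale = max(errors.max(), 1e-30)
    if curvature.size == 0 or curvature.max() <= 1e-9 * scale:
        warnings.warn("reconstruction curve has no distinct elbow; returning smallest k")
        return ks[0], dict(zip(ks, errors.tolist()))
    k_star = ks[1:-1][int(np.argmax(curvature))]
    return k_star, dict(zip(ks, errors.tolist()))


def prune_small(clusters: CoClustering, min_cells: int = 20) -> CoClustering:
    """Prune co-clusters whose combined row + column membership is below
    ``min_cells``; members get the sentinel assignment and survivors are
    re-indexed densely."""
    ra = np.asarray(clusters.row_assignments).copy()
    ca = np.asarray(clusters.col_assignments).copy()
    labels = np.unique(np.concatenate([ra, ca]))
    labels = labels[labels != PRUNED]
    sizes = {u: int((ra == u).sum() + (ca == u).sum()) for u in labels}
    removed = {u for u, s in sizes.items() if s < min_cells}
    survivors = [u for u in labels if u not in removed]
    remap = {u: i for i, u in enumerate(survivors)}
    new_ra = np.array([remap.get(u, PRUNED) for u in ra])
    new_ca = np.array([remap.get(u, PRUNED) for u in ca])
    return CoClustering(
        row_assignments=new_ra,
        col_assignments=new_ca,
        n_clusters=len(survivors),
        modularity=clusters.modularity,
        pruned=removed,
    )
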