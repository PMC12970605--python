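"""Synthetic two-domain datasets with ground-truth correspondence.

Four designs emulate the benchmark geometries used for unpaired
alignment methods: a three-armed branch in 2-D, a Swiss roll in 3-D, a
circular frustum in 3-D -- each sampled once in latent space, then
nonlinearly lifted into two high-dimensional "modalities" through
independent random two-layer maps -- plus a count-valued design that
mimics scRNA-seq via a gamma-Poisson hierarchy (groups of cells with
group-specific mean expression, per-cell library sizes, overdispersed
rates).

Both domains of a pair derive from the *same* latent points, so a true
bijective cell pairing exists; rows are independently shuffled and the
pairing is stored for evaluation only.  Generators are deterministic
under their seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._exceptions import ParameterError
from .io import DataMatrix, zscore

__all__ = [
    "SimulatedPair",
    "sample_manifold",
    "nonlinear_lift",
    "make_pair",
    "sample_synthetic_counts",
]

DESIGNS = ("branch", "swiss_roll", "circular_frustum", "synthetic_counts")

# branch arms: (length, angle in radians); deliberately asymmetric so the
# sampled density has no nontrivial symmetry for alignment to confuse
_BRANCH_ARMS = ((1.2, 0.0), (1.8, 1.92), (1.0, 3.93))
_BRANCH_NOISE_FRAC = 0.05  # noise sd as a fraction of arm length


@dataclasses.dataclass
class SimulatedPair:
    """A paired two-domain dataset with held-out ground truth.

    ``true_match[i]`` is the row of ``domain_y`` generated from the same
    latent point as row ``i`` of ``domain_x``.
    """

    domain_x: DataMatrix
    domain_y: DataMatrix
    latent: np.ndarray
    true_match: np.ndarray
    cluster_labels: np.ndarray  # in latent (unshuffled) order
    design: str


def sample_manifold(design: str, n: int, seed: int = 0):
    """Sample latent manifold coordinates and cluster labels.

    branch: three line-segment arms from the origin with Gaussian jitter,
    clusters = arms.  swiss_roll: (t cos t, h, t sin t) with t in
    [1.5 pi, 4.5 pi], clusters = t-tertiles.  circular_frustum: lateral
    surface of a cone frustum (radius linear in height, angle uniform),
    clusters = angular sectors.
    """
    if n < 30:
        raise ParameterError(f"need n >= 30, got {n}")
    rng = np.random.default_rng(seed)
    if design == "branch":
        sizes = [n // 3 + (1 if r < n % 3 else 0) for r in range(3)]
        coords, labels = [], []
        for arm, (length, angle) in enumerate(_BRANCH_ARMS):
            t = rng.uniform(0.0, length, size=sizes[arm])
            pts = t[:, None] * np.array([np.cos(angle), np.sin(angle)])[None, :]
            pts += rng.normal(0.0, _BRANCH_NOISE_FRAC * length, size=pts.shape)
            coords.append(pts)
            labels.append(np.full(sizes[arm], arm))
        return np.vstack(coords), np.concatenate(labels)
    if design == "swiss_roll":
        t = rng.uniform(1.5 * np.pi, 4.5 * np.pi, size=n)
        h = rng.uniform(0.0, 10.0, size=n)
        coords = np.column_stack([t * np.cos(t), h, t * np.sin(t)])
        edges = np.quantile(t, [1 / 3, 2 / 3])
        labels = np.digitize(t, edges)
        return coords, labels
    if design == "circular_frustum":
        h = rng.uniform(0.0, 1.0, size=n)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        r = 1.5 - 0.8 * h  # radius shrinks linearly with height
        coords = np.column_stack([r * np.cos(theta), r * np.sin(theta), 2.0 * h])
        labels = np.minimum((theta / (2.0 * np.pi / 3.0)).astype(int), 2)
        return coords, labels
    raise ParameterError(f"unknown design {design!r}; choose from {DESIGNS[:3]}")


def nonlinear_lift(
    latent: np.ndarray,
    target_dim: int,
    seed: int = 0,
    hidden_dim: int = 64,
    noise_sigma: float = 0.05,
) -> np.ndarray:
    """Lift latent coordinates through a random two-layer nonlinear map.

    z -> tanh(z A1 + b1) A2 with seeded Gaussian weights, plus additive
    Gaussian observation noise.  Different seeds give different lifts of
    the same latent structure, emulating two modalities measuring one
    underlying manifold.
    """
    latent = np.asarray(latent, dtype=np.float64)
    p = latent.shape[1]
    if target_dim <= p:
        raise ParameterError("target_dim must exceed the latent dimension")
    rng = np.random.default_rng(seed)
    z = zscore(latent)
    A1 = rng.normal(0.0, 1.0 / np.sqrt(p), size=(p, hidden_dim))
    b1 = rng.normal(0.0, 0.5, size=hidden_dim)
    A2 = rng.normal(0.0, 1.0 / np.sqrt(hidden_dim), size=(hidden_dim, target_dim))
    lifted = np.tanh(z @ A1 + b1[None, :]) @ A2
    if noise_sigma > 0:
        lifted = lifted + rng.normal(0.0, noise_sigma, size=lifted.shape)
    return lifted


def _shuffle_pair(lift_x, lift_y, labels, latent, design, rng, normalize):
    n = lift_x.shape[0]
    order_x = rng.permutation(n)
    order_y = rng.permutation(n)
    inv_y = np.empty(n, dtype=int)
    inv_y[order_y] = np.arange(n)
    true_match = inv_y[order_x]  # y row paired with x row i
    vx = zscore(lift_x[order_x]) if normalize else lift_x[order_x]
    vy = zscore(lift_y[order_y]) if normalize else lift_y[order_y]
    dm_x = DataMatrix(vx, labels=labels[order_x])
    dm_y = DataMatrix(vy, labels=labels[order_y])
    return SimulatedPair(
        domain_x=dm_x,
        domain_y=dm_y,
        latent=latent,
        true_match=true_match,
        cluster_labels=labels,
        design=design,
    )


def make_pair(
    design: str,
    n: int = 300,
    target_dim: int = 100,
    seed: int = 0,
    hidden_dim: int = 64,
    noise_sigma: float = 0.05,
    normalize: bool = True,
) -> SimulatedPair:
    """Generate a shuffled two-domain pair from one manifold design.

    The two domains are different nonlinear lifts of the same latent
    sample; features are z-score normalized by default, matching the
    standard preprocessing for alignment benchmarks.
    """
    if design == "synthetic_counts":
        return sample_synthetic_counts(n=n, d=target_dim, seed=seed)
    ss = np.random.SeedSequence(seed)
    s_latent, s_lift_x, s_lift_y, s_shuffle = ss.spawn(4)
    latent, labels = sample_manifold(design, n, seed=s_latent.generate_state(1)[0] % 2**31)
    lift_x = nonlinear_lift(
        latent, target_dim, seed=s_lift_x.generate_state(1)[0] % 2**31,
        hidden_dim=hidden_dim, noise_sigma=noise_sigma,
    )
    lift_y = nonlinear_lift(
        latent, target_dim, seed=s_lift_y.generate_state(1)[0] % 2**31,
        hidden_dim=hidden_dim, noise_sigma=noise_sigma,
    )
    rng = np.random.default_rng(s_shuffle.generate_state(1)[0] % 2**31)
    return _shuffle_pair(lift_x, lift_y, labels, latent, design, rng, normalize)


def _group_counts(rng, groups, n_groups, d, library_size, de_fraction, fold_change, bcv):
    n = len(groups)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=d)
    # group-specific fold changes on a random subset of features
    factors = np.ones((n_groups, d))
    for g in range(n_groups):
        de = rng.random(d) < de_fraction
        factors[g, de] = np.where(rng.random(de.sum()) < 0.5, fold_change, 1.0 / fold_change)
    means = base[None, :] * factors  # n_groups x d
    shape = 1.0 / bcv**2
    rates = rng.gamma(shape, means[groups] / shape)  # overdispersed per-cell rates
    props = rates / rates.sum(axis=1, keepdims=True)
    # library sizes: log-normal with the configured mean
    sigma_l = 0.3
    lib = library_size * rng.lognormal(mean=-(sigma_l**2) / 2.0, sigma=sigma_l, size=n)
    return rng.poisson(lib[:, None] * props).astype(np.float64)


def sample_synthetic_counts(
    n: int = 5000,
    d: int = 50,
    n_groups: int = 3,
    seed: int = 0,
    library_size: float = 2000.0,
    de_fraction: float = 0.2,
    fold_change: float = 4.0,
    bcv: float = 0.3,
    normalize: bool = False,
) -> SimulatedPair:
    """Count-valued paired design via a gamma-Poisson hierarchy.

    Cells belong to ``n_groups`` balanced groups; each group has its own
    mean expression profile (log-normal baseline times fold-change
    effects on ``de_fraction`` of features).  The second domain shares
    the group structure but draws independent feature means, emulating a
    second modality.  Counts are Poisson draws of library-size-scaled,
    gamma-overdispersed proportions, so the expected total count per cell
    equals ``library_size``.
    """
    if n_groups < 2:
        raise ParameterError("n_groups must be >= 2")
    if d < 2 or n < 30:
        raise ParameterError("need n >= 30 and d >= 2")
    ss = np.random.SeedSequence(seed)
    s_groups, s_x, s_y, s_shuffle = ss.spawn(4)
    rng_g = np.random.default_rng(s_groups.generate_state(1)[0] % 2**31)
    groups = rng_g.integers(0, n_groups, size=n)
    counts_x = _group_counts(
        np.random.default_rng(s_x.generate_state(1)[0] % 2**31),
        groups, n_groups, d, library_size, de_fraction, fold_change, bcv,
    )
    counts_y = _group_counts(
        np.random.default_rng(s_y.generate_state(1)[0] % 2**31),
        groups, n_groups, d, library_size, de_fraction, fold_change, bcv,
    )
    rng = np.random.default_rng(s_shuffle.generate_state(1)[0] % 2**31)
    latent = groups[:, None].astype(np.float64)
    return _shuffle_pair(
        counts_x, counts_y, groups, latent, "synthetic_counts", rng, normalize
    )
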