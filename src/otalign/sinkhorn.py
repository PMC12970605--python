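"""Entropic optimal transport, Sinkhorn divergence, and plan extraction.

The entropic OT cost between embedded point clouds is

    OT_eps(X, Y) = min_{T in Pi(a, b)} <C, T> + eps * sum T (log T - 1),

with squared-Euclidean cost C_ij = ||x_i - y_j||^2 and (by default)
uniform marginals.  The debiased Sinkhorn divergence

    S_eps(X, Y) = OT_eps(X, Y) - 1/2 [OT_eps(X, X) + OT_eps(Y, Y)]

vanishes when the two clouds coincide and supplies non-vanishing
gradients for distribution alignment.

All iterations run in the log domain (stabilized).  Unbalanced transport
relaxes the marginal constraints with KL penalties of strength
``rho = reach**2``; the fixed-point update then damps the potentials by
``rho / (rho + eps)``.  Gradients with respect to the point positions use
the envelope theorem: at the converged plan, only the cost matrix depends
on the positions, so d OT / d x_i = sum_j T_ij * dC_ij / d x_i.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._exceptions import NumericalError, ParameterError
from .kernels import _sq_dists


def _lse_rows(M: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp (lean inner-loop replacement for
    scipy.special.logsumexp)."""
    mx = M.max(axis=1)
    out = np.log(np.exp(M - mx[:, None]).sum(axis=1))
    out += mx
    return out

__all__ = [
    "TransportPlan",
    "entropic_ot_cost",
    "sinkhorn_divergence",
    "sinkhorn_divergence_grad",
    "extract_plan",
]


@dataclasses.dataclass
class TransportPlan:
    """A converged coupling between two embedded cell sets."""

    plan: np.ndarray  # nonnegative n_x x n_y
    marginal_a: np.ndarray
    marginal_b: np.ndarray
    epsilon: float
    reach: float | None  # None = balanced (reach = infinity)
    n_iter: int = 0
    converged: bool = True
    stop_reason: str = "tol"

    @property
    def total_mass(self) -> float:
        return float(self.plan.sum())


def _check_inputs(eps: float, a: np.ndarray, b: np.ndarray) -> None:
    if eps <= 0:
        raise ParameterError(f"epsilon must be positive, got {eps}")
    if np.any(a < 0) or np.any(b < 0):
        raise ParameterError("marginals must be nonnegative")


def _damping(eps: float, reach: float | None) -> float:
    if reach is None or np.isinf(reach):
        return 1.0
    if reach <= 0:
        raise ParameterError(f"reach must be positive or None, got {reach}")
    rho = reach**2
    return rho / (rho + eps)


def _sinkhorn_potentials(C, loga, logb, eps, lam, max_iter, tol, f=None, g=None):
    """Alternating log-domain updates; returns (f, g, n_iter, converged)."""
    n_x, n_y = C.shape
    f = np.zeros(n_x) if f is None else f.copy()
    g = np.zeros(n_y) if g is None else g.copy()
    Ce = C / eps
    CeT = np.ascontiguousarray(Ce.T)
    for it in range(1, max_iter + 1):
        f_new = -lam * eps * _lse_rows((g / eps + logb)[None, :] - Ce)
        g_new = -lam * eps * _lse_rows((f_new / eps + loga)[None, :] - CeT)
        delta = max(np.abs(f_new - f).max(), np.abs(g_new - g).max()) / eps
        f, g = f_new, g_new
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(g))):
            raise NumericalError(
                "Sinkhorn scalings diverged (non-finite potentials); "
                "try a larger epsilon"
            )
        if delta < tol:
            return f, g, it, True
    return f, g, max_iter, False


def _symmetric_potential(C, loga, eps, lam, max_iter, tol, f=None):
    """Averaged fixed-point for the symmetric self-transport problem
    (a = b, C symmetric), where the two potentials coincide."""
    n = C.shape[0]
    f = np.zeros(n) if f is None else f.copy()
    Ce = C / eps
    for it in range(1, max_iter + 1):
        f_half = -lam * eps * _lse_rows((f / eps + loga)[None, :] - Ce)
        delta = np.abs(f_half - f).max() / eps
        f = 0.5 * (f + f_half)
        if not np.all(np.isfinite(f)):
            raise NumericalError(
                "Sinkhorn scalings diverged (non-finite potentials); "
                "try a larger epsilon"
            )
        if delta < tol:
            return f, it, True
    return f, max_iter, False


def _plan_from_potentials(C, loga, logb, eps, f, g):
    return np.exp(loga[:, None] + logb[None, :] + (f[:, None] + g[None, :] - C) / eps)


def _xlogx(t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = t[pos] * np.log(t[pos])
    return out


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    """Generalized KL divergence sum p log(p/q) - p + q (0 log 0 = 0)."""
    pos = p > 0
    val = float(np.sum(p[pos] * np.log(p[pos] / q[pos])) - p.sum() + q.sum())
    return val


def _primal_cost(C, T, a, b, eps, reach) -> float:
    lin = float(np.sum(C * T))
    if reach is None or np.isinf(reach):
        ent = float(_xlogx(T).sum() - T.sum())
        return lin + eps * ent
    rho = reach**2
    kl_joint = _kl(T, a[:, None] * b[None, :])
    kl_rows = _kl(T.sum(axis=1), a)
    kl_cols = _kl(T.sum(axis=0), b)
    return lin + eps * kl_joint + rho * (kl_rows + kl_cols)


def entropic_ot_cost(
    xe: np.ndarray,
    ye: np.ndarray,
    epsilon: float,
    reach: float | None = None,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[float, TransportPlan]:
    """Converged entropic (optionally unbalanced) OT cost and plan.

    The iteration stops when the sup-norm change of the log-scaling
    vectors (potentials divided by epsilon) drops below ``tol``, or at
    ``max_iter``; the plan records which (``stop_reason``).
    """
    xe = np.atleast_2d(np.asarray(xe, dtype=np.float64))
    ye = np.atleast_2d(np.asarray(ye, dtype=np.float64))
    n_x, n_y = xe.shape[0], ye.shape[0]
    a = np.full(n_x, 1.0 / n_x) if a is None else np.asarray(a, dtype=np.float64)
    b = np.full(n_y, 1.0 / n_y) if b is None else np.asarray(b, dtype=np.float64)
    _check_inputs(epsilon, a, b)
    lam = _damping(epsilon, reach)
    C = _sq_dists(xe, ye)
    with np.errstate(divide="ignore"):
        loga, logb = np.log(a), np.log(b)
    f, g, n_iter, converged = _sinkhorn_potentials(
        C, loga, logb, epsilon, lam, max_iter, tol
    )
    T = _plan_from_potentials(C, loga, logb, epsilon, f, g)
    cost = _primal_cost(C, T, a, b, epsilon, reach)
    plan = TransportPlan(
        plan=T,
        marginal_a=a,
        marginal_b=b,
        epsilon=epsilon,
        reach=reach,
        n_iter=n_iter,
        converged=converged,
        stop_reason="tol" if converged else "max_iter",
    )
    return cost, plan


def _self_cost(xe, eps, reach, max_iter, tol, f0=None):
    n = xe.shape[0]
    a = np.full(n, 1.0 / n)
    loga = np.log(a)
    lam = _damping(eps, reach)
    C = _sq_dists(xe, xe)
    np.fill_diagonal(C, 0.0)
    f, _, _ = _symmetric_potential(C, loga, eps, lam, max_iter, tol, f=f0)
    T = _plan_from_potentials(C, loga, loga, eps, f, f)
    return _primal_cost(C, T, a, a, eps, reach), T, f


def sinkhorn_divergence(
    xe: np.ndarray,
    ye: np.ndarray,
    epsilon: float,
    reach: float | None = None,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> float:
    """Debiased Sinkhorn divergence between two embedded clouds.

    Symmetric in its arguments (a canonical argument ordering makes the
    two call orders run the identical computation) and approximately zero
    when the clouds coincide.
    """
    xe = np.atleast_2d(np.asarray(xe, dtype=np.float64))
    ye = np.atleast_2d(np.asarray(ye, dtype=np.float64))
    if (xe.shape, xe.tobytes()) > (ye.shape, ye.tobytes()):
        xe, ye = ye, xe
    value, _, _ = sinkhorn_divergence_grad(
        xe, ye, epsilon, reach=reach, max_iter=max_iter, tol=tol, compute_grad=False
    )[:3]
    return value


def sinkhorn_divergence_grad(
    xe: np.ndarray,
    ye: np.ndarray,
    epsilon: float,
    reach: float | None = None,
    max_iter: int = 1000,
    tol: float = 1e-7,
    state: dict | None = None,
    compute_grad: bool = True,
):
    """Divergence value and its gradients with respect to both clouds.

    ``state`` carries converged potentials between successive calls for
    warm starting during training.  Returns ``(value, grad_x, grad_y,
    state)``; gradients are ``None`` when ``compute_grad`` is false.
    """
    xe = np.atleast_2d(np.asarray(xe, dtype=np.float64))
    ye = np.atleast_2d(np.asarray(ye, dtype=np.float64))
    n_x, n_y = xe.shape[0], ye.shape[0]
    a = np.full(n_x, 1.0 / n_x)
    b = np.full(n_y, 1.0 / n_y)
    _check_inputs(epsilon, a, b)
    lam = _damping(epsilon, reach)
    loga, logb = np.log(a), np.log(b)
    state = state or {}

    C = _sq_dists(xe, ye)
    f, g, _, _ = _sinkhorn_potentials(
        C, loga, logb, epsilon, lam, max_iter, tol,
        f=state.get("f_xy"), g=state.get("g_xy"),
    )
    T_xy = _plan_from_potentials(C, loga, logb, epsilon, f, g)
    cost_xy = _primal_cost(C, T_xy, a, b, epsilon, reach)

    cost_xx, T_xx, f_xx = _self_cost(xe, epsilon, reach, max_iter, tol, state.get("f_xx"))
    cost_yy, T_yy, f_yy = _self_cost(ye, epsilon, reach, max_iter, tol, state.get("f_yy"))

    value = cost_xy - 0.5 * (cost_xx + cost_yy)
    new_state = {"f_xy": f, "g_xy": g, "f_xx": f_xx, "f_yy": f_yy}
    if not compute_grad:
        return value, None, None, new_state

    r = T_xy.sum(axis=1)
    c = T_xy.sum(axis=0)
    s_x = T_xx.sum(axis=1)
    s_y = T_yy.sum(axis=1)
    grad_x = 2.0 * (r[:, None] * xe - T_xy @ ye) - 2.0 * (s_x[:, None] * xe - T_xx @ xe)
    grad_y = 2.0 * (c[:, None] * ye - T_xy.T @ xe) - 2.0 * (s_y[:, None] * ye - T_yy @ ye)
    return value, grad_x, grad_y, new_state


def extract_plan(model, max_iter: int = 5000, tol: float = 1e-9) -> TransportPlan:
    """Recompute the converged coupling between a trained model's final
    embeddings at the training epsilon and reach.

    This exact plan is the input to transport-plan co-clustering; its row
    structure encodes soft cell-cell correspondences across modalities.
    """
    cfg = model.config
    _, plan = entropic_ot_cost(
        model.embedding_x,
        model.embedding_y,
        epsilon=model.epsilon_used,
        reach=cfg.reach,
        max_iter=max_iter,
        tol=tol,
    )
    return plan
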