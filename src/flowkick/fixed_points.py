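"""Fixed points of the flow-kick map: location, refinement, classification.

A fixed point of the flow-kick map is a post-kick state that repeats
exactly once per fire cycle, i.e. a periodic solution of the impulsive
system.  Stability is read off the eigenvalues of the 2x2 map Jacobian
(finite differences of the map): stable when both moduli are below 1,
saddle when exactly one exceeds 1, repellor when both do.

Up to six fixed points occur: the origin and the forest state (0, 1)
always exist; a grassland state (x_g, 0) exists when fires are frequent
or mild enough (k1 <= 1 - e^{-tau}); and up to three tree-grass
coexistence (savanna) states appear and disappear through transcritical
and fold bifurcations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    DisturbanceRegime,
    ModelParams,
    _flow_signed,
    flow,
    flow_kick_map,
    kick,
)


def _phi_safe(states, regime, params):
    """Batched flow-kick map that returns NaN rows for states whose flow
    leaves the domain, instead of raising."""
    return kick(_flow_signed(states, regime.tau, params, strict=False), regime, params)

__all__ = [
    "FixedPoint",
    "UnderlyingFixedPoint",
    "grass_only_x",
    "iterate_to_attractor",
    "map_jacobian",
    "newton_fixed_point",
    "enumerate_fixed_points",
    "classify_underlying",
    "coexistence_fixed_points_1d",
    "pre_kick_state",
]

#: eigenvalue-modulus band around 1 treated as marginal (near-bifurcation)
LAMBDA_TOL = 1e-7
#: Newton iterates outside this box are rejected (biologically meaningless)
GUARD_BOX = ((-0.05, 1.5), (-0.05, 1.5))
#: kinds are decided by whether a coordinate is within this of an axis
AXIS_TOL = 1e-8


@dataclass
class FixedPoint:
    """A fixed point of the flow-kick map (post-kick state).

    stability is one of {"stable", "saddle", "repellor"}; kind is one of
    {"origin", "forest_only", "grass_only", "coexistence"}.  ``marginal``
    flags an eigenvalue modulus within LAMBDA_TOL of 1, i.e. a regime at
    or very near a bifurcation where the class is unreliable.
    """

    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    kind: str
    marginal: bool = False
    residual: float = np.nan

    @property
    def x(self) -> float:
        return float(self.state[0])

    @property
    def y(self) -> float:
        return float(self.state[1])


def grass_only_x(regime: DisturbanceRegime) -> float:
    """Post-kick grass biomass of the grassland fixed point,
    ``x_g = (1 - (1-k1) e^tau) / (1 - e^tau)``.

    Nonnegative (the point exists) iff ``k1 <= 1 - e^{-tau}``.
    """
    e = np.exp(regime.tau)
    return (1.0 - (1.0 - regime.k1) * e) / (1.0 - e)


def pre_kick_state(state, regime: DisturbanceRegime, params: ModelParams = ModelParams()):
    """State just before the fire, for a post-kick (map) state on its
    periodic orbit: flow the state forward by one inter-fire period."""
    return flow(np.asarray(state, float), regime.tau, params)


def iterate_to_attractor(
    start,
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    max_iter: int = 300,
    tol: float = 1e-6,
):
    """Iterate the flow-kick map until successive states differ by < tol.

    Returns ``(state, converged, iterations_used)``.  Non-convergence in
    ``max_iter`` steps is signalled by the flag, not an exception.
    """
    s = np.asarray(start, dtype=float)
    for n in range(1, max_iter + 1):
        s_next = flow_kick_map(s, regime, params)
        if np.max(np.abs(s_next - s)) < tol:
            return s_next, True, n
        s = s_next
    return s, False, max_iter


def iterate_map_batch(
    states,
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    max_iter: int = 300,
    tol: float = 1e-6,
):
    """Vectorized :func:`iterate_to_attractor` over an (N, 2) batch.

    Returns ``(states, converged_mask, iterations)``; converged points are
    frozen as soon as their update falls below ``tol``.
    """
    s = np.array(states, dtype=float)
    n = s.shape[0]
    converged = np.zeros(n, dtype=bool)
    iters = np.full(n, max_iter, dtype=int)
    active = np.ones(n, dtype=bool)
    for it in range(1, max_iter + 1):
        if not active.any():
            break
        s_new = _phi_safe(s[active], regime, params)
        moved = np.max(np.abs(s_new - s[active]), axis=-1)
        s[active] = s_new
        idx = np.flatnonzero(active)
        dead = idx[~np.isfinite(moved)]
        active[dead] = False
        just_done = idx[np.isfinite(moved) & (moved < tol)]
        converged[just_done] = True
        iters[just_done] = it
        active[just_done] = False
    return s, converged, iters


def _fd_steps(states, h):
    """Per-coordinate FD step: absolute h, relative when |coordinate| > 1."""
    return h * np.maximum(1.0, np.abs(states))


def _jacobian_batch(states, regime, params, h=1e-6):
    """Central-difference map Jacobians for an (N, 2) batch -> (N, 2, 2).

    The map formulas extend smoothly across the axes, so small negative
    excursions of the perturbed states are valid here.
    """
    s = np.asarray(states, dtype=float)
    hs = _fd_steps(s, h)
    pert = np.zeros((4,) + s.shape)
    pert[0, :, 0] = hs[:, 0]
    pert[1, :, 0] = -hs[:, 0]
    pert[2, :, 1] = hs[:, 1]
    pert[3, :, 1] = -hs[:, 1]
    vals = _phi_safe(s[None, :, :] + pert, regime, params)  # (4, N, 2)
    jac = np.empty(s.shape[:1] + (2, 2))
    jac[:, :, 0] = (vals[0] - vals[1]) / (2 * hs[:, 0])[:, None]
    jac[:, :, 1] = (vals[2] - vals[3]) / (2 * hs[:, 1])[:, None]
    return jac


def map_jacobian(
    state,
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    h: float = 1e-6,
):
    """2x2 Jacobian of the flow-kick map at ``state`` by finite differences.

    Central differences with step ``h`` (relative when a coordinate
    exceeds 1); when a coordinate sits too close to an axis for the
    central stencil, a second-order one-sided stencil is used instead so
    evaluations stay in the first quadrant.
    """
    s = np.asarray(state, dtype=float)
    hs = _fd_steps(s, h)
    jac = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = hs[j]
        if s[j] - hs[j] >= 0.0:
            jac[:, j] = (
                flow_kick_map(s + e, regime, params)
                - flow_kick_map(s - e, regime, params)
            ) / (2 * hs[j])
        else:  # one-sided, O(h^2): (-3 f(s) + 4 f(s+h) - f(s+2h)) / (2h)
            jac[:, j] = (
                -3.0 * flow_kick_map(s, regime, params)
                + 4.0 * flow_kick_map(s + e, regime, params)
                - flow_kick_map(s + 2 * e, regime, params)
            ) / (2 * hs[j])
    return jac


def _kind_of(state) -> str:
    x, y = state
    if x <= AXIS_TOL and y <= AXIS_TOL:
        return "origin"
    if x <= AXIS_TOL:
        return "forest_only"
    if y <= AXIS_TOL:
        return "grass_only"
    return "coexistence"


def _classify_eigs(eigenvalues, lam_tol=LAMBDA_TOL):
    mags = np.abs(eigenvalues)
    marginal = bool(np.any(np.abs(mags - 1.0) <= lam_tol))
    n_out = int(np.sum(mags > 1.0))
    stability = {0: "stable", 1: "saddle", 2: "repellor"}[n_out]
    return stability, marginal


def classify_point(
    state,
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    lam_tol: float = LAMBDA_TOL,
) -> FixedPoint:
    """Build a :class:`FixedPoint` (eigenvalues, stability, kind) at a state
    assumed fixed; the residual of the fixed-point equation is recorded."""
    s = np.asarray(state, dtype=float)
    jac = map_jacobian(s, regime, params)
    eigs = np.linalg.eigvals(jac)
    stability, marginal = _classify_eigs(eigs, lam_tol)
    res = float(np.max(np.abs(flow_kick_map(s, regime, params) - s)))
    return FixedPoint(
        state=s,
        eigenvalues=eigs,
        stability=stability,
        kind=_kind_of(s),
        marginal=marginal,
        residual=res,
    )


def _in_guard_box(states):
    (xlo, xhi), (ylo, yhi) = GUARD_BOX
    return (
        (states[:, 0] >= xlo)
        & (states[:, 0] <= xhi)
        & (states[:, 1] >= ylo)
        & (states[:, 1] <= yhi)
    )


def newton_batch(
    starts,
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    fp_tol: float = 1e-10,
    max_iter: int = 40,
    max_halvings: int = 10,
):
    """Vectorized damped Newton iteration on ``Phi(s) - s = 0``.

    Returns ``(points, converged_mask)`` over the (N, 2) batch of starts.
    Steps are halved (up to ``max_halvings``) while the residual fails to
    decrease or the iterate leaves the guard box; points that cannot make
    progress, or whose Jacobian is singular, are abandoned.
    """
    s = np.array(starts, dtype=float).reshape(-1, 2)
    n = s.shape[0]
    active = _in_guard_box(s)
    res = np.full(n, np.inf)
    F = np.zeros_like(s)
    F[active] = _phi_safe(s[active], regime, params) - s[active]
    res[active] = np.max(np.abs(F[active]), axis=-1)
    converged = res <= fp_tol
    active &= ~converged

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        sa, Fa = s[idx], F[idx]
        jac = _jacobian_batch(sa, regime, params)
        G = jac.copy()
        G[:, 0, 0] -= 1.0
        G[:, 1, 1] -= 1.0
        det = G[:, 0, 0] * G[:, 1, 1] - G[:, 0, 1] * G[:, 1, 0]
        ok = np.abs(det) > 1e-14
        step = np.zeros_like(sa)
        step[ok, 0] = -(G[ok, 1, 1] * Fa[ok, 0] - G[ok, 0, 1] * Fa[ok, 1]) / det[ok]
        step[ok, 1] = -(G[ok, 0, 0] * Fa[ok, 1] - G[ok, 1, 0] * Fa[ok, 0]) / det[ok]
        # kill singular-Jacobian points
        active[idx[~ok]] = False
        idx, sa, step = idx[ok], sa[ok], step[ok]
        if idx.size == 0:
            continue
        res_a = res[idx]
        lam = np.ones(idx.size)
        accepted = np.zeros(idx.size, dtype=bool)
        cand = np.empty_like(sa)
        cand_F = np.empty_like(sa)
        cand_res = np.empty(idx.size)
        for _h in range(max_halvings + 1):
            trial = np.where(accepted[:, None], cand, sa + lam[:, None] * step)
            inbox = _in_guard_box(trial)
            trial_F = _phi_safe(trial, regime, params) - trial
            with np.errstate(invalid="ignore"):
                trial_res = np.max(np.abs(trial_F), axis=-1)
                better = ~accepted & inbox & np.isfinite(trial_res) & (trial_res < res_a)
            cand[better] = trial[better]
            cand_F[better] = trial_F[better]
            cand_res[better] = trial_res[better]
            accepted |= better
            if accepted.all():
                break
            lam[~accepted] *= 0.5
        # abandon points that never improved
        active[idx[~accepted]] = False
        good = idx[accepted]
        s[good] = cand[accepted]
        F[good] = cand_F[accepted]
        res[good] = cand_res[accepted]
        done = good[res[good] <= fp_tol]
        converged[done] = True
        active[done] = False
    return s, converged


def newton_fixed_point(
    guess,
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    fp_tol: float = 1e-10,
    max_iter: int = 40,
):
    """Damped Newton refinement of a single fixed-point guess.

    Returns a classified :class:`FixedPoint`, or ``None`` when the
    iteration diverges, stalls, or hits a singular Jacobian.
    """
    pts, conv = newton_batch(
        np.asarray(guess, float).reshape(1, 2), regime, params, fp_tol, max_iter
    )
    if not conv[0]:
        return None
    s = pts[0]
    s[np.abs(s) < AXIS_TOL] = 0.0  # snap machine-noise coordinates onto the axes
    if s[0] < 0 or s[1] < 0:
        return None
    return classify_point(s, regime, params)


def _analytic_seeds(regime, params):
    seeds = [(0.0, 0.0), (0.0, 1.0)]
    xg = grass_only_x(regime)
    if xg >= 0.0:
        seeds.append((xg, 0.0))
    if params.alpha < 1.0:
        seeds.append((1.0 - params.alpha, 1.0))  # underlying coexistence point
    return seeds


def enumerate_fixed_points(
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    grid_n: int = 20,
    fp_tol: float = 1e-10,
    merge_tol: float = 1e-6,
):
    """Census of flow-kick fixed points by multistart Newton.

    Starts on a ``grid_n x grid_n`` lattice over [0, 1.2]^2 plus the
    analytic seeds (origin, forest, grassland when it exists, and the
    underlying coexistence point).  Converged points are merged when
    closer than ``merge_tol`` and returned classified, sorted by (x, y)
    — deterministic for a fixed lattice.
    """
    if grid_n < 10:
        raise ValueError("grid_n must be at least 10")
    g = np.linspace(0.0, 1.2, grid_n)
    lattice = np.stack(np.meshgrid(g, g, indexing="ij"), axis=-1).reshape(-1, 2)
    starts = np.vstack([lattice, np.asarray(_analytic_seeds(regime, params))])
    pts, conv = newton_batch(starts, regime, params, fp_tol=fp_tol)
    pts = pts[conv]
    pts[np.abs(pts) < AXIS_TOL] = 0.0
    pts = pts[(pts[:, 0] >= 0.0) & (pts[:, 1] >= 0.0)]
    if pts.shape[0] == 0:
        return []
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    unique = [pts[0]]
    for p in pts[1:]:
        if np.max(np.abs(p - unique[-1])) > merge_tol and all(
            np.max(np.abs(p - q)) > merge_tol for q in unique
        ):
            unique.append(p)
    return [classify_point(p, regime, params) for p in unique]


def coexistence_fixed_points_1d(
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    n_scan: int = 400,
    xtol: float = 1e-13,
):
    """Coexistence fixed points via an exact one-dimensional reduction.

    For a fixed point with post-kick grass ``x``, the flow-end grass is
    ``x / (1 - k1)`` and, because the tree flow is logistic, the tree
    coordinate is forced:  with survival factor
    ``m(x) = 1 - k2 * omega(k1 x / (1 - k1))``, the fixed tree value is
    ``y(x) = (m e^{delta tau} - 1) / (e^{delta tau} - 1)``.  The remaining
    scalar equation ``(1 - k1) * flow_x((x, y(x)), tau) = x`` is solved by
    a sign-change scan plus Brent refinement.  Used as an independent
    census oracle for :func:`enumerate_fixed_points`.
    """
    from scipy.optimize import brentq

    from .model import _omega_raw

    k1, k2, tau = regime.k1, regime.k2, regime.tau
    edt = np.exp(params.delta * tau)

    def y_of_x(x):
        m = 1.0 - k2 * _omega_raw(k1 * np.asarray(x, float) / (1.0 - k1), params.a)
        return (m * edt - 1.0) / (edt - 1.0)

    def G(x):
        x = np.asarray(x, float)
        y = y_of_x(x)
        s = np.stack([x, y], axis=-1)
        return (1.0 - k1) * flow(s, tau, params)[..., 0] - x

    xs = np.linspace(1e-9, 1.0, n_scan)
    ys = y_of_x(xs)
    valid = ys > 1e-12
    vals = np.where(valid, G(xs), np.nan)
    roots = []
    for i in range(n_scan - 1):
        if valid[i] and valid[i + 1] and vals[i] * vals[i + 1] < 0:
            r = brentq(lambda x: float(G(x)), xs[i], xs[i + 1], xtol=xtol)
            roots.append(np.array([r, float(y_of_x(r))]))
    return roots


@dataclass
class UnderlyingFixedPoint:
    point: tuple
    name: str
    eigenvalues: tuple
    stability: str


def classify_underlying(params: ModelParams = ModelParams()):
    """The four equilibria of the underlying ODE with their stability.

    Eigenvalues are analytic (the Jacobian is triangular at each point).
    ``alpha = 1`` is degenerate (the forest and coexistence states merge)
    and raises.
    """
    a, d = params.alpha, params.delta
    if a == 1.0:
        raise ValueError("alpha = 1 is degenerate: forest and coexistence states merge")

    def stab(eigs):
        re = np.real(eigs)
        if np.all(re < 0):
            return "stable"
        if np.all(re > 0):
            return "unstable"
        return "saddle"

    table = [
        UnderlyingFixedPoint((0.0, 0.0), "desert", (1.0, d), None),
        UnderlyingFixedPoint((1.0, 0.0), "grass_only", (-1.0, d), None),
        UnderlyingFixedPoint((0.0, 1.0), "forest_only", (1.0 - a, -d), None),
        UnderlyingFixedPoint((1.0 - a, 1.0), "forest_grass", (a - 1.0, -d), None),
    ]
    for fp in table:
        fp.stability = stab(np.asarray(fp.eigenvalues))
    return table
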