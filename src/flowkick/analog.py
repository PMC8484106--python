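"""Continuous-fire comparison systems.

Holding the fire intensities ``r1 = k1/tau`` and ``r2 = k2/tau`` fixed
while the fire interval shrinks to zero turns the impulsive system into a
continuous one.  Three variants are provided:

* ``mean_limit`` — the genuine small-interval limit.  Because the burned
  grass per fire, ``k1 x``, vanishes with ``tau``, the switching function
  kills the tree-mortality term and only ``-r1 x`` survives in the grass
  equation.  This system is plain Lotka-Volterra and never bistable.
* ``hill_grass`` — a structurally analogous model with continuous tree
  mortality ``-r2 omega(x) y`` (mortality driven by the standing grass),
  the form closest to classic savanna ODE models.
* ``hill_burned`` — continuous tree mortality ``-r2 omega(r1 x) y``
  (driven by the burned grass), whose bifurcation diagram in the
  (r1, r2)-plane mirrors the impulsive one in (k1, k2) at fixed tau.

These are comparison models: the Hill variants are *not* limits of the
impulsive system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DisturbanceRegime, ModelParams, _omega_raw, flow_kick_map

__all__ = [
    "ContinuousRegime",
    "VARIANTS",
    "analog_rhs",
    "analog_fixed_points",
    "analog_bifurcation_curves",
    "analog_region_scan",
    "small_tau_limit_check",
    "ConvergenceReport",
]

VARIANTS = ("mean_limit", "hill_grass", "hill_burned")


@dataclass(frozen=True)
class ContinuousRegime:
    """Continuous fire intensities: r1 = k1/tau (grass), r2 = k2/tau (trees)."""

    r1: float
    r2: float
    variant: str = "mean_limit"

    def __post_init__(self):
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("fire intensities must be nonnegative")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


def _tree_mortality_rate(x, cregime: ContinuousRegime, params: ModelParams):
    if cregime.variant == "mean_limit":
        return np.zeros_like(np.asarray(x, float))
    arg = x if cregime.variant == "hill_grass" else cregime.r1 * np.asarray(x, float)
    return cregime.r2 * _omega_raw(arg, params.a)


def analog_rhs(state, cregime: ContinuousRegime, params: ModelParams = ModelParams()):
    """Velocity field of the chosen continuous-fire system at (x, y)."""
    s = np.asarray(state, dtype=float)
    x, y = s[..., 0], s[..., 1]
    out = np.empty_like(s)
    out[..., 0] = x * (1.0 - cregime.r1 - x - params.alpha * y)
    out[..., 1] = params.delta * y * (1.0 - y) - _tree_mortality_rate(x, cregime, params) * y
    return out


def _ode_jacobian(state, cregime, params, h=1e-7):
    s = np.asarray(state, float)
    J = np.empty((2, 2))
    for j in range(2):
        e = np.zeros(2)
        e[j] = h * max(1.0, abs(s[j]))
        J[:, j] = (analog_rhs(s + e, cregime, params) - analog_rhs(s - e, cregime, params)) / (
            2 * e[j]
        )
    return J


@dataclass
class AnalogFixedPoint:
    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str
    kind: str


def _stability_ode(eigs, tol=1e-9):
    re = np.real(eigs)
    if np.all(re < -tol):
        return "stable"
    if np.all(re > tol):
        return "unstable"
    if np.any(np.abs(re) <= tol):
        return "marginal"
    return "saddle"


def analog_fixed_points(
    cregime: ContinuousRegime, params: ModelParams = ModelParams(), n_scan: int = 400
):
    """All first-quadrant equilibria of the continuous system.

    The axes and the ``y = 1`` line are handled in closed form; interior
    coexistence equilibria reduce to a scalar root problem (the grass
    nullcline gives ``x = 1 - r1 - alpha y``) solved by scan + Brent.
    """
    from scipy.optimize import brentq

    r1 = cregime.r1
    pts = [np.array([0.0, 0.0]), np.array([0.0, 1.0])]
    if r1 < 1.0:
        pts.append(np.array([1.0 - r1, 0.0]))

    def tree_balance(y):
        # dy/dt = 0 with x on the grass nullcline; positive x required
        x = 1.0 - r1 - params.alpha * y
        return params.delta * (1.0 - y) - _tree_mortality_rate(x, cregime, params)

    if cregime.variant == "mean_limit":
        # no continuous tree mortality: the coexistence state keeps trees
        # at carrying capacity, exactly on the scan's y = 1 endpoint
        x = 1.0 - r1 - params.alpha
        if x > 1e-12:
            pts.append(np.array([x, 1.0]))
    y_hi = min(1.0, (1.0 - r1) / params.alpha if params.alpha > 0 else 1.0)
    if cregime.variant != "mean_limit" and y_hi > 1e-9:
        ys = np.linspace(1e-9, y_hi - 1e-12, n_scan)
        vals = np.array([tree_balance(y) for y in ys])
        for i in range(n_scan - 1):
            if vals[i] * vals[i + 1] < 0:
                y = brentq(tree_balance, ys[i], ys[i + 1], xtol=1e-14)
                x = 1.0 - r1 - params.alpha * y
                if x > 1e-12:
                    pts.append(np.array([x, y]))
    out = []
    for p in pts:
        eigs = np.linalg.eigvals(_ode_jacobian(p, cregime, params))
        kind = (
            "origin"
            if np.all(p < 1e-12)
            else "forest_only"
            if p[0] < 1e-12
            else "grass_only"
            if p[1] < 1e-12
            else "coexistence"
        )
        out.append(AnalogFixedPoint(p, eigs, _stability_ode(eigs), kind))
    out.sort(key=lambda fp: (fp.state[0], fp.state[1]))
    return out


def analog_bifurcation_curves(
    variant: str,
    params: ModelParams = ModelParams(),
    r1_range=(0.0, 1.2),
    r2_range=(0.0, 3.0),
    n: int = 200,
):
    """Bifurcation loci of a Hill-variant continuous system in the
    (r1, r2)-plane.

    Returns a dict with the grass-existence line ``r1 = 1``, the forest
    transcritical line ``r1 = 1 - alpha`` (independent of r2), the
    grassland transcritical curve ``r2 = delta / omega(arg(1 - r1))``
    (arg is the standing or burned grass at the grass-only state), and
    fold curves located by double roots of the coexistence reduction.
    The ``mean_limit`` variant has none of these beyond plain
    Lotka-Volterra structure and is rejected.
    """
    if variant == "mean_limit":
        raise ValueError(
            "the small-interval limit system is plain Lotka-Volterra: "
            "no Hill-type bifurcation curves exist"
        )
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    r2s = np.linspace(max(r2_range[0], 1e-6), r2_range[1], n)
    curves = {
        "grass_existence": np.column_stack([np.ones(n), r2s]),
        "forest_transcritical": np.column_stack([(1.0 - params.alpha) * np.ones(n), r2s]),
    }
    r1s = np.linspace(max(r1_range[0], 1e-6), min(r1_range[1], 1.0 - 1e-6), n)
    arg = (1.0 - r1s) if variant == "hill_grass" else r1s * (1.0 - r1s)
    with np.errstate(divide="ignore"):
        red = params.delta / _omega_raw(arg, params.a)
    ok = np.isfinite(red) & (red <= r2_range[1] * 10)
    curves["grassland_transcritical"] = np.column_stack([r1s[ok], red[ok]])
    curves["limit_point"] = _analog_fold_curve(variant, params, r1_range, r2_range, n)
    return curves


def _coexistence_count(r1, r2, variant, params, n_scan=300):
    c = ContinuousRegime(r1=r1, r2=r2, variant=variant)
    return sum(1 for fp in analog_fixed_points(c, params, n_scan) if fp.kind == "coexistence")


def _analog_fold_curve(variant, params, r1_range, r2_range, n):
    """Fold locus by bisection on the coexistence-equilibrium count."""
    pts = []
    r2s = np.linspace(max(r2_range[0], 0.05), r2_range[1], max(10, n // 10))
    for r2 in r2s:
        r1s = np.linspace(max(r1_range[0], 1e-4), min(r1_range[1], 1.2), 80)
        counts = [_coexistence_count(r1, r2, variant, params) for r1 in r1s]
        for i in range(len(r1s) - 1):
            if counts[i] != counts[i + 1]:
                lo, hi = r1s[i], r1s[i + 1]
                clo = counts[i]
                for _ in range(30):
                    mid = 0.5 * (lo + hi)
                    if _coexistence_count(mid, r2, variant, params) == clo:
                        lo = mid
                    else:
                        hi = mid
                # transcritical lines also change the count; keep only
                # genuine pair creations/annihilations (count jumps by 2)
                if abs(counts[i + 1] - counts[i]) == 2:
                    pts.append((0.5 * (lo + hi), r2))
    return np.array(pts).reshape(-1, 2)


def analog_region_scan(
    variant: str,
    params: ModelParams = ModelParams(),
    r1_grid=None,
    r2_grid=None,
):
    """Raster of stable-state combinations over the (r1, r2)-plane.

    Each cell records the sorted tuple of kinds of the stable equilibria —
    the currency in which the continuous and impulsive diagrams are
    compared.
    """
    if r1_grid is None:
        r1_grid = np.linspace(0.02, 1.18, 50)
    if r2_grid is None:
        r2_grid = np.linspace(0.02, 3.0, 50)
    r1_grid = np.asarray(r1_grid, float)
    r2_grid = np.asarray(r2_grid, float)
    combos = np.empty((r1_grid.size, r2_grid.size), dtype=object)
    for i, r1 in enumerate(r1_grid):
        for j, r2 in enumerate(r2_grid):
            fps = analog_fixed_points(
                ContinuousRegime(r1=float(r1), r2=float(r2), variant=variant), params
            )
            combos[i, j] = tuple(
                sorted(fp.kind for fp in fps if fp.stability == "stable")
            )
    return combos


@dataclass
class ConvergenceReport:
    """Difference quotients of the flow-kick map against the limit field."""

    tau_seq: np.ndarray
    quotients: np.ndarray
    errors: np.ndarray
    order: float
    tree_quotients: np.ndarray


def small_tau_limit_check(
    state,
    cregime: ContinuousRegime,
    params: ModelParams = ModelParams(),
    tau_seq=None,
) -> ConvergenceReport:
    """Verify that ``(Phi(s; k1=r1 tau, k2=r2 tau, tau) - s)/tau`` converges
    to the mean-limit vector field at first order in tau.

    The tree component of the limit carries no r2 term (the switching
    function vanishes with the burned grass), which the report makes
    visible through the raw tree quotients.  The order is a Richardson
    estimate from the last error ratios.
    """
    if tau_seq is None:
        tau_seq = 2.0 ** -np.arange(3, 13)
    tau_seq = np.asarray(tau_seq, float)
    s = np.asarray(state, float)
    limit = analog_rhs(
        s, ContinuousRegime(cregime.r1, cregime.r2, "mean_limit"), params
    )
    quotients = np.empty((tau_seq.size, 2))
    for i, tau in enumerate(tau_seq):
        k1, k2 = cregime.r1 * tau, cregime.r2 * tau
        if not (k1 < 1 and k2 < 1):
            raise ValueError("tau_seq too coarse for the given intensities")
        regime = DisturbanceRegime(k1=k1, k2=k2, tau=float(tau))
        quotients[i] = (flow_kick_map(s, regime, params) - s) / tau
    errors = np.linalg.norm(quotients - limit, axis=1)
    # Richardson: err ~ C tau^p  =>  p ~ log2(err_i / err_{i+1}) for halving
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(errors[:-1] / errors[1:])
    good = np.isfinite(ratios)
    order = float(np.median(ratios[good][-4:])) if good.any() else np.inf
    return ConvergenceReport(
        tau_seq=tau_seq,
        quotients=quotients,
        errors=errors,
        order=order,
        tree_quotients=quotients[:, 1],
    )
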