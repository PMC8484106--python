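"""Bifurcation structure of the flow-kick map in disturbance space.

Three transcritical loci have closed forms:

* grass existence (dashed): ``k1 = 1 - e^{-tau}`` — the grassland fixed
  point enters the first quadrant;
* grassland transcritical (red): ``e^{delta tau}(1 - k2 omega(xi_g)) = 1``
  with ``xi_g = k1 x_g / (1 - k1)`` — the grassland state exchanges
  stability with a savanna branch;
* forest transcritical (blue): ``k1 = 1 - e^{-(1-alpha) tau}`` — the
  forest state (0, 1) exchanges stability with a savanna branch
  (independent of ``k2``).

Fold (limit-point) curves have no closed form and are located by
pseudo-arclength continuation of fixed-point branches with a secant
predictor and Newton corrector; a fold is recorded where the branch
direction in the free parameter reverses while a real map eigenvalue
crosses +1, refined by bisection and certified by Newton on the extended
system (fixed point + eigenvalue-1 condition) together with a nonzero
quadratic normal-form coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import DisturbanceRegime, ModelParams, flow_kick_map, omega
from .fixed_points import (
    FixedPoint,
    classify_point,
    coexistence_fixed_points_1d,
    enumerate_fixed_points,
    grass_only_x,
    map_jacobian,
    newton_fixed_point,
)

__all__ = [
    "grass_existence_k1",
    "grassland_transcritical_k2",
    "forest_transcritical_k1",
    "critical_k2",
    "CriticalK2",
    "continue_branch",
    "fold_in_tau",
    "Branch",
    "BranchPoint",
    "Fold",
    "BifurcationCurve",
    "RegionLabel",
    "RegionGrid",
    "classify_region",
    "stability_diagram",
    "limit_point_curve",
    "REGION_TABLE",
]


def grass_existence_k1(tau: float) -> float:
    """Grass-mortality level at which the grassland fixed point is born:
    ``k1 = 1 - e^{-tau}`` (independent of k2)."""
    return 1.0 - np.exp(-np.asarray(tau, float))


def grassland_transcritical_k2(
    k1: float, tau: float, params: ModelParams = ModelParams()
) -> Optional[float]:
    """Tree-mortality level putting the grassland state on its
    transcritical locus, ``k2 = (1 - e^{-delta tau}) / omega(xi_g)``.

    Requires ``0 < k1 < 1 - e^{-tau}`` (the grassland point exists with
    positive burned grass).  Returns ``None`` when the required k2 is not
    an admissible proportion (>= 1).
    """
    adm = 1.0 - np.exp(-tau)
    if not (0.0 < k1 < adm):
        raise ValueError(f"k1 must be in (0, 1 - e^-tau) = (0, {adm}); got {k1}")
    regime = DisturbanceRegime(k1=k1, k2=0.0, tau=tau)
    xi_g = k1 * grass_only_x(regime) / (1.0 - k1)
    k2 = (1.0 - np.exp(-params.delta * tau)) / omega(xi_g, params.a)
    return float(k2) if k2 < 1.0 else None


def forest_transcritical_k1(tau: float, params: ModelParams = ModelParams()):
    """Grass-mortality level of the forest transcritical locus,
    ``k1 = 1 - e^{-(1-alpha) tau}`` (independent of k2).

    Only meaningful for ``alpha < 1`` (grass can invade the forest at
    all); for ``alpha >= 1`` the locus is absent and this raises.
    """
    if params.alpha >= 1.0:
        raise ValueError("forest transcritical curve requires alpha < 1")
    return 1.0 - np.exp(-(1.0 - params.alpha) * np.asarray(tau, float))


@dataclass(frozen=True)
class CriticalK2:
    """Minimum of the grassland-transcritical surface over (k1, tau)."""

    k2: float
    k1: float
    tau: float
    restart_spread: float  # max |k2 - best| over near-optimal restarts


def _k2_required(frac: float, tau: float, params: ModelParams) -> float:
    """k2 on the grassland transcritical locus, parameterized by
    ``k1 = frac * (1 - e^{-tau})`` so the admissibility strip is a box."""
    k1 = frac * (1.0 - np.exp(-tau))
    xg = (1.0 - (1.0 - k1) * np.exp(tau)) / (1.0 - np.exp(tau))
    xi = k1 * xg / (1.0 - k1)
    return (1.0 - np.exp(-params.delta * tau)) / omega(xi, params.a)


def critical_k2(
    params: ModelParams = ModelParams(),
    n_tau: int = 24,
    n_frac: int = 9,
) -> CriticalK2:
    """Minimal k2 for which the grassland transcritical condition has a
    solution, by bounded multistart minimization over the admissible
    (k1, tau) strip.  Deterministic (fixed start lattice)."""
    from scipy.optimize import minimize

    bounds = [(1e-6, 1.0 - 1e-9), (1e-3, 20.0)]
    best = None
    results = []
    for tau0 in np.geomspace(0.05, 10.0, n_tau):
        for f0 in np.linspace(0.1, 0.9, n_frac):
            r = minimize(
                lambda p: _k2_required(p[0], p[1], params),
                np.array([f0, tau0]),
                method="L-BFGS-B",
                bounds=bounds,
            )
            results.append(r)
            if best is None or r.fun < best.fun:
                best = r
    near = [r.fun for r in results if r.fun < best.fun + 1e-3]
    spread = float(max(near) - best.fun) if len(near) > 1 else 0.0
    frac, tau = best.x
    k1 = frac * (1.0 - np.exp(-tau))
    return CriticalK2(k2=float(best.fun), k1=float(k1), tau=float(tau), restart_spread=spread)


# ---------------------------------------------------------------------------
# pseudo-arclength continuation
# ---------------------------------------------------------------------------

_FREE_PARAMS = ("k1", "k2", "tau")


def _regime_with(regime: DisturbanceRegime, free_param: str, value: float):
    return replace(regime, **{free_param: float(value)})


def _param_bounds(free_param: str):
    # validity limits of the regime itself
    return (1e-9, 1.0 - 1e-9) if free_param in ("k1", "k2") else (1e-6, np.inf)


@dataclass
class BranchPoint:
    param: float
    state: np.ndarray
    eigenvalues: np.ndarray
    stability: str


@dataclass
class Fold:
    param: float
    state: np.ndarray
    eigenvalue: float
    normal_form: float
    transversality: float
    certified: bool


@dataclass
class Branch:
    free_param: str
    points: list = field(default_factory=list)
    folds: list = field(default_factory=list)
    truncated: bool = False
    message: str = ""

    def params_array(self):
        return np.array([p.param for p in self.points])

    def states_array(self):
        return np.array([p.state for p in self.points])


def _H(z, regime, free_param, params):
    """Fixed-point residual at extended coordinates z = (x, y, p)."""
    r = _regime_with(regime, free_param, z[2])
    s = z[:2]
    return flow_kick_map(s, r, params) - s


def _H_jac(z, regime, free_param, params, h=1e-6):
    """2x3 Jacobian of the residual by central differences."""
    J = np.empty((2, 3))
    for j in range(3):
        hj = h * max(1.0, abs(z[j]))
        lo, hi = _param_bounds(free_param) if j == 2 else (-np.inf, np.inf)
        e = np.zeros(3)
        e[j] = hj
        if z[j] - hj > lo and z[j] + hj < hi:
            J[:, j] = (
                _H(z + e, regime, free_param, params)
                - _H(z - e, regime, free_param, params)
            ) / (2 * hj)
        else:  # one-sided second order at the parameter-domain edge
            sgn = 1.0 if z[j] - hj <= lo else -1.0
            J[:, j] = sgn * (
                -3.0 * _H(z, regime, free_param, params)
                + 4.0 * _H(z + sgn * e, regime, free_param, params)
                - _H(z + 2 * sgn * e, regime, free_param, params)
            ) / (2 * hj)
    return J


def _tangent(z, regime, free_param, params, prev=None):
    """Unit null vector of the 2x3 residual Jacobian, oriented along prev."""
    J = _H_jac(z, regime, free_param, params)
    _, _, vt = np.linalg.svd(J)
    t = vt[-1]
    if prev is not None and np.dot(t, prev) < 0:
        t = -t
    return t


def _correct(z_pred, t, regime, free_param, params, tol=1e-10, max_iter=8):
    """Newton corrector for [H(z); t.(z - z_pred)] = 0 with fixed tangent."""
    z = z_pred.copy()
    lo, hi = _param_bounds(free_param)
    for _ in range(max_iter):
        if not (lo < z[2] < hi):
            return None
        r = np.empty(3)
        r[:2] = _H(z, regime, free_param, params)
        r[2] = np.dot(t, z - z_pred)
        if np.max(np.abs(r[:2])) < tol and abs(r[2]) < 1e-12:
            return z
        A = np.vstack([_H_jac(z, regime, free_param, params), t])
        try:
            dz = np.linalg.solve(A, -r)
        except np.linalg.LinAlgError:
            return None
        z = z + dz
        if np.max(np.abs(dz)) > 0.5:  # corrector wandering off
            return None
    r = _H(z, regime, free_param, params)
    return z if np.max(np.abs(r)) < tol else None


def _eigs_at(z, regime, free_param, params):
    r = _regime_with(regime, free_param, z[2])
    return np.linalg.eigvals(map_jacobian(z[:2], r, params)), r


def _stability(eigs):
    n_out = int(np.sum(np.abs(eigs) > 1.0))
    return {0: "stable", 1: "saddle", 2: "repellor"}[n_out]


def _normal_form_coeff(state, regime, params, eps=1e-4):
    """Quadratic fold coefficient  b = (1/2) w . D^2Phi[v, v]  with v, w the
    right/left eigenvectors for the eigenvalue nearest +1 (w.v = 1), plus
    the parameter transversality  c = w . dPhi/dp  (p = the regime's tau;
    only the nonzero-ness of b is used as the certificate)."""
    J = map_jacobian(state, regime, params)
    eigs, vecs = np.linalg.eig(J)
    i = int(np.argmin(np.abs(eigs - 1.0)))
    v = np.real(vecs[:, i])
    v /= np.linalg.norm(v)
    wl, wvecs = np.linalg.eig(J.T)
    j = int(np.argmin(np.abs(wl - 1.0)))
    w = np.real(wvecs[:, j])
    w /= np.dot(w, v)
    d2 = (
        flow_kick_map(state + eps * v, regime, params)
        - 2.0 * flow_kick_map(state, regime, params)
        + flow_kick_map(state - eps * v, regime, params)
    ) / eps**2
    return 0.5 * float(np.dot(w, d2)), float(np.real(eigs[i]))


def _certify_fold(z, regime, free_param, params, tol=1e-9, max_iter=20):
    """Newton on the extended system [Phi - s; det(DPhi - I)] = 0.

    Returns a :class:`Fold` with the refined location, the critical
    eigenvalue, and the quadratic normal-form coefficient.
    """

    def F(z):
        r = _regime_with(regime, free_param, z[2])
        s = z[:2]
        J = map_jacobian(s, r, params)
        G = J - np.eye(2)
        return np.array(
            [*(flow_kick_map(s, r, params) - s), G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0]]
        )

    zc = z.copy()
    ok = False
    for _ in range(max_iter):
        Fz = F(zc)
        if np.max(np.abs(Fz)) < tol:
            ok = True
            break
        A = np.empty((3, 3))
        for j in range(3):
            h = 1e-5 * max(1.0, abs(zc[j]))
            e = np.zeros(3)
            e[j] = h
            A[:, j] = (F(zc + e) - F(zc - e)) / (2 * h)
        try:
            dz = np.linalg.solve(A, -Fz)
        except np.linalg.LinAlgError:
            break
        zc = zc + dz
        if np.max(np.abs(dz)) > 0.5:
            break
    r = _regime_with(regime, free_param, zc[2])
    b, lam = _normal_form_coeff(zc[:2], r, params)
    return Fold(
        param=float(zc[2]),
        state=zc[:2].copy(),
        eigenvalue=lam,
        normal_form=b,
        transversality=np.nan,
        certified=bool(ok and abs(b) > 1e-4 and abs(lam - 1.0) < 1e-5),
    )


def continue_branch(
    seed: FixedPoint,
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    free_param: str = "tau",
    param_range: tuple = None,
    direction: int = +1,
    h0: float = 1e-2,
    h_min: float = 1e-4,
    h_max: float = 5e-2,
    max_steps: int = 2000,
) -> Branch:
    """Pseudo-arclength continuation of a fixed-point branch.

    Marches from ``seed`` (a verified fixed point at ``regime``) varying
    ``free_param`` initially toward ``direction``.  Secant predictor,
    Newton corrector orthogonal to the running tangent, and step length
    adapted in [h_min, h_max] by corrector performance.  Folds (branch
    direction reversals with an eigenvalue crossing +1) are refined by
    step-halving bisection to |delta param| <= 1e-5 and certified via the
    extended fold system.  Corrector breakdown at the minimum step
    truncates the branch with a diagnostic.
    """
    if free_param not in _FREE_PARAMS:
        raise ValueError(f"free_param must be one of {_FREE_PARAMS}")
    if param_range is None:
        param_range = _param_bounds(free_param)
        param_range = (param_range[0], min(param_range[1], 20.0))
    p0 = getattr(regime, free_param)
    z = np.array([seed.state[0], seed.state[1], p0])
    branch = Branch(free_param=free_param)
    eigs, _ = _eigs_at(z, regime, free_param, params)
    branch.points.append(BranchPoint(p0, z[:2].copy(), eigs, _stability(eigs)))

    t = _tangent(z, regime, free_param, params)
    if t[2] * direction < 0:
        t = -t
    h = h0
    for _ in range(max_steps):
        z_new = _correct(z + h * t, t, regime, free_param, params)
        if z_new is None:
            if h <= h_min:
                branch.truncated = True
                branch.message = f"corrector failed at {free_param}={z[2]:.6g}"
                break
            h = max(h_min, h / 2)
            continue
        t_new = _tangent(z_new, regime, free_param, params, prev=t)
        if t_new[2] * t[2] < 0:  # direction reversal: candidate fold
            z_fold = _bisect_fold(z, t, h, regime, free_param, params)
            fold = _certify_fold(z_fold, regime, free_param, params)
            branch.folds.append(fold)
        eigs, _ = _eigs_at(z_new, regime, free_param, params)
        branch.points.append(
            BranchPoint(float(z_new[2]), z_new[:2].copy(), eigs, _stability(eigs))
        )
        z, t = z_new, t_new
        h = min(h_max, h * 1.3)
        if not (param_range[0] <= z[2] <= param_range[1]):
            break
        if np.max(np.abs(z[:2])) > 2.0 or np.min(z[:2]) < -0.5:
            branch.truncated = True
            branch.message = "branch left the biologically relevant window"
            break
    return branch


def _bisect_fold(z, t, h, regime, free_param, params, dp_tol=1e-5):
    """Walk along the branch with halved steps until the direction
    reversal is bracketed to within ``dp_tol`` in the free parameter."""
    z_cur, t_cur, h_cur = z.copy(), t.copy(), h
    for _ in range(200):
        z_new = _correct(z_cur + h_cur * t_cur, t_cur, regime, free_param, params)
        if z_new is None:
            h_cur /= 2
            if h_cur < 1e-9:
                break
            continue
        t_new = _tangent(z_new, regime, free_param, params, prev=t_cur)
        if t_new[2] * t_cur[2] < 0:
            if abs(z_new[2] - z_cur[2]) <= dp_tol:
                return z_new
            h_cur /= 2
            if h_cur < 1e-9:
                return z_new
        else:
            z_cur, t_cur = z_new, t_new
    return z_cur


def fold_in_tau(
    k1: float,
    k2: float,
    params: ModelParams = ModelParams(),
    tau_start: float = 1.0,
    tau_max: float = 6.0,
    grid_n: int = 20,
) -> Fold:
    """Locate the limit point of the highest-grass stable branch continued
    in the fire interval tau, starting from ``tau_start``.

    Seeds the highest-grass stable coexistence fixed point via multistart
    Newton census, advancing tau from ``tau_start`` in small increments
    until that branch exists (near ``tau_start`` the highest-grass stable
    state may still be the grassland, whose axis branch never folds),
    continues the branch toward larger tau, and returns the first fold.
    Raises if the branch has none.
    """
    seed, regime = None, None
    for tau in np.arange(tau_start, tau_max, 0.1):
        regime = DisturbanceRegime(k1=k1, k2=k2, tau=float(tau))
        census = enumerate_fixed_points(regime, params, grid_n=grid_n)
        stable_coex = [
            fp
            for fp in census
            if fp.stability == "stable" and fp.kind == "coexistence"
        ]
        if stable_coex:
            seed = max(stable_coex, key=lambda fp: fp.x)
            break
    if seed is None:
        raise RuntimeError("no stable coexistence fixed point to seed the continuation")
    branch = continue_branch(
        seed, regime, params, free_param="tau", param_range=(1e-3, tau_max), direction=+1
    )
    if not branch.folds:
        raise RuntimeError("no fold found on the continued branch")
    return branch.folds[0]


# ---------------------------------------------------------------------------
# region taxonomy and stability diagrams
# ---------------------------------------------------------------------------

#: (forest stability, grassland stability or None, sorted coexistence
#: stabilities) -> region numeral
REGION_TABLE = {
    ("stable", None, ()): "I",
    ("stable", "saddle", ()): "II",
    ("saddle", "saddle", ("stable",)): "III",
    ("stable", "stable", ("saddle",)): "IV",
    ("stable", "saddle", ("saddle", "stable")): "V",
    ("saddle", "saddle", ("saddle", "stable", "stable")): "VI",
    ("saddle", "stable", ("saddle", "stable")): "VII",
    ("saddle", "stable", ()): "VIII",
}


@dataclass
class RegionLabel:
    """Stability-region classification of one disturbance regime.

    label is a numeral I..VIII, "unclassified" when the census matches no
    catalogued pattern, with ``boundary`` set when any eigenvalue was
    marginal (the regime sits numerically on a bifurcation locus).
    stable_set is the sorted tuple of kinds of the stable fixed points.
    """

    label: str
    stable_set: tuple
    census: list
    boundary: bool = False


def classify_region(
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    grid_n: int = 20,
) -> RegionLabel:
    """Map the fixed-point census of a regime to its stability region."""
    census = enumerate_fixed_points(regime, params, grid_n=grid_n)
    forest = next((fp for fp in census if fp.kind == "forest_only"), None)
    grass = next((fp for fp in census if fp.kind == "grass_only"), None)
    coex = tuple(sorted(fp.stability for fp in census if fp.kind == "coexistence"))
    key = (
        forest.stability if forest else None,
        grass.stability if grass else None,
        coex,
    )
    label = REGION_TABLE.get(key, "unclassified")
    stable_set = tuple(sorted(fp.kind for fp in census if fp.stability == "stable"))
    boundary = any(fp.marginal for fp in census)
    return RegionLabel(label=label, stable_set=stable_set, census=census, boundary=boundary)


@dataclass
class BifurcationCurve:
    """Polyline of a bifurcation locus; points are (k1, k2, tau) rows."""

    curve_type: str
    points: np.ndarray
    note: str = ""


@dataclass
class RegionGrid:
    """Raster of region labels over (k1, tau) at fixed k2, with the
    bifurcation curves overlaid; ``labels[i, j]`` classifies
    ``(k1_grid[i], tau_grid[j])``."""

    k2: float
    k1_grid: np.ndarray
    tau_grid: np.ndarray
    labels: np.ndarray
    stable_sets: np.ndarray
    boundary: np.ndarray
    curves: list
    failures: list = field(default_factory=list)


def _grassland_curve_at_k2(k2, tau_grid, params, n_scan=200):
    """Roots in k1 of the grassland transcritical condition at each tau,
    assembled into the closed loop (lower branch out, upper branch back)."""
    from scipy.optimize import brentq

    lower, upper = [], []
    for tau in tau_grid:
        adm = 1.0 - np.exp(-tau)
        fracs = np.linspace(1e-4, 1.0 - 1e-6, n_scan)
        vals = np.array([_k2_required(f, tau, params) - k2 for f in fracs])
        roots = []
        for i in range(n_scan - 1):
            if np.isfinite(vals[i]) and np.isfinite(vals[i + 1]) and vals[i] * vals[i + 1] < 0:
                fr = brentq(
                    lambda f: _k2_required(f, tau, params) - k2,
                    fracs[i],
                    fracs[i + 1],
                    xtol=1e-12,
                )
                roots.append(fr * adm)
        if roots:
            lower.append((min(roots), tau))
            upper.append((max(roots), tau))
    pts = [(k1, k2, tau) for k1, tau in lower] + [
        (k1, k2, tau) for k1, tau in reversed(upper)
    ]
    return BifurcationCurve(
        "grassland_transcritical",
        np.array(pts).reshape(-1, 3),
        note="loop: lower branch ascending tau, upper branch descending",
    )


def limit_point_curve(
    k2: float,
    params: ModelParams = ModelParams(),
    tau_values=None,
    k1_scan_n: int = 40,
) -> BifurcationCurve:
    """Trace the fold locus in the (k1, tau) plane at fixed k2.

    For each tau, bistable cells (more than one coexistence fixed point,
    found by the 1D census reduction) seed a continuation of the
    highest-grass coexistence branch in k1; every certified fold on the
    branch contributes a curve point.
    """
    if tau_values is None:
        tau_values = np.linspace(0.2, 4.0, 20)
    pts = []
    for tau in tau_values:
        k1s = np.linspace(0.01, 0.99, k1_scan_n)
        seed_regime = None
        seed_root = None
        for k1 in k1s:
            regime = DisturbanceRegime(k1=float(k1), k2=k2, tau=float(tau))
            roots = coexistence_fixed_points_1d(regime, params, n_scan=200)
            if len(roots) >= 2:
                seed_regime = regime
                seed_root = max(roots, key=lambda r: r[0])
                break
        if seed_regime is None:
            continue
        fp = newton_fixed_point(seed_root, seed_regime, params)
        if fp is None:
            continue
        for direction in (+1, -1):
            branch = continue_branch(
                fp,
                seed_regime,
                params,
                free_param="k1",
                param_range=(1e-3, 1 - 1e-3),
                direction=direction,
            )
            for fold in branch.folds:
                pts.append((fold.param, k2, tau))
    pts = sorted(set((round(p[0], 10), p[1], p[2]) for p in pts), key=lambda p: (p[2], p[0]))
    return BifurcationCurve("limit_point", np.array(pts).reshape(-1, 3))


def stability_diagram(
    k2: float,
    k1_grid=None,
    tau_grid=None,
    params: ModelParams = ModelParams(),
    grid_n: int = 12,
    with_limit_points: bool = True,
) -> RegionGrid:
    """Classify every (k1, tau) cell at fixed k2 and overlay the analytic
    transcritical curves plus the continued fold curve.

    Default raster 100x100 over (0, 1) x (0, 4]; per-cell failures are
    recorded in ``failures`` rather than raised.
    """
    if k1_grid is None:
        k1_grid = np.linspace(0.005, 0.995, 100)
    if tau_grid is None:
        tau_grid = np.linspace(0.04, 4.0, 100)
    k1_grid = np.asarray(k1_grid, float)
    tau_grid = np.asarray(tau_grid, float)
    labels = np.empty((k1_grid.size, tau_grid.size), dtype=object)
    stable_sets = np.empty_like(labels)
    boundary = np.zeros(labels.shape, dtype=bool)
    failures = []
    for i, k1 in enumerate(k1_grid):
        for j, tau in enumerate(tau_grid):
            try:
                rl = classify_region(
                    DisturbanceRegime(k1=float(k1), k2=k2, tau=float(tau)),
                    params,
                    grid_n=grid_n,
                )
                labels[i, j] = rl.label
                stable_sets[i, j] = rl.stable_set
                boundary[i, j] = rl.boundary
            except Exception as exc:  # pragma: no cover - defensive
                labels[i, j] = "failed"
                stable_sets[i, j] = ()
                failures.append((float(k1), float(tau), repr(exc)))
    curves = [
        BifurcationCurve(
            "grass_existence",
            np.array([(grass_existence_k1(t), k2, t) for t in tau_grid]),
        ),
        BifurcationCurve(
            "forest_transcritical",
            np.array([(forest_transcritical_k1(t, params), k2, t) for t in tau_grid])
            if params.alpha < 1
            else np.empty((0, 3)),
        ),
        _grassland_curve_at_k2(k2, tau_grid, params),
    ]
    if with_limit_points:
        curves.append(limit_point_curve(k2, params, tau_values=tau_grid[::5]))
    return RegionGrid(
        k2=k2,
        k1_grid=k1_grid,
        tau_grid=tau_grid,
        labels=labels,
        stable_sets=stable_sets,
        boundary=boundary,
        curves=curves,
        failures=failures,
    )
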