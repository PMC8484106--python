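"""Basins of attraction, saddle manifolds, and the slow region.

In bistable regimes the stable manifold of the central (coexistence)
saddle separates the basins of the two attracting fixed points, while its
unstable manifold channels trajectories: iterates collapse quickly onto a
neighbourhood of that manifold and then crawl along it toward one of the
attractors — the "slow region".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (
    DisturbanceRegime,
    FlowError,
    ModelParams,
    _flow_signed,
    _omega_raw,
    flow_kick_map,
)
from .fixed_points import (
    FixedPoint,
    enumerate_fixed_points,
    map_jacobian,
)

__all__ = [
    "BasinRaster",
    "ManifoldTrace",
    "SlowRegion",
    "compute_basins",
    "inverse_kick",
    "inverse_map",
    "saddle_manifolds",
    "slow_region",
]

DEFAULT_WINDOW = ((0.0, 1.1), (0.0, 1.1))


@dataclass
class BasinRaster:
    """Attractor index per grid cell; -1 marks cells not assigned to any
    stable attractor (non-converged, or converged onto an invariant-axis
    saddle state as the x = 0 and y = 0 lines do).

    ``labels[i, j]`` is the basin of ``(x_grid[i], y_grid[j])``;
    ``converged_fraction`` counts cells whose iteration converged, whether
    or not a stable attractor claimed them.
    """

    window: tuple
    x_grid: np.ndarray
    y_grid: np.ndarray
    labels: np.ndarray
    attractors: list
    converged_fraction: float


def compute_basins(
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    window: tuple = DEFAULT_WINDOW,
    n: int = 200,
    max_iter: int = 300,
    tol: float = 1e-6,
    match_tol: float = 1e-4,
    capture_tol: float = 1e-2,
    attractors: list = None,
) -> BasinRaster:
    """Partition a state-space window among the stable fixed points.

    Every cell centre is iterated until either the map-step displacement
    falls below ``tol`` (then matched to the nearest stable fixed point
    within ``match_tol``) or the iterate enters the ``capture_tol``
    neighbourhood of an attractor, which assigns the cell immediately.
    The capture radius is far below the separation of the attractors and
    makes the partition complete even when the slowest attractor has an
    eigenvalue close to 1 (near a fold), where displacement-based
    convergence alone would exceed the iteration cap.  Remaining cells
    get label -1.
    """
    (x0, x1), (y0, y1) = window
    if x0 < 0 or y0 < 0:
        raise ValueError("window must lie in the first quadrant")
    if attractors is None:
        census = enumerate_fixed_points(regime, params)
        attractors = [fp for fp in census if fp.stability == "stable"]
    targets = np.array([fp.state for fp in attractors]).reshape(-1, 2)
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1).reshape(-1, 2)
    n_cells = grid.shape[0]
    labels = np.full(n_cells, -1, dtype=int)
    settled = np.zeros(n_cells, dtype=bool)
    s = grid.copy()
    active = np.ones(n_cells, dtype=bool)
    if targets.size:
        from .fixed_points import _phi_safe

        for _ in range(max_iter):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            s_new = _phi_safe(s[idx], regime, params)
            moved = np.max(np.abs(s_new - s[idx]), axis=-1)
            s[idx] = s_new
            d = np.linalg.norm(s_new[:, None, :] - targets[None, :, :], axis=-1)
            nearest = np.argmin(d, axis=1)
            d_near = d[np.arange(idx.size), nearest]
            with np.errstate(invalid="ignore"):
                captured = np.isfinite(d_near) & (d_near <= capture_tol)
                settled_now = np.isfinite(moved) & (moved < tol)
                dead = ~np.isfinite(moved)
            assign = captured | (settled_now & (d_near <= match_tol))
            labels[idx[assign]] = nearest[assign]
            settled[idx[assign | settled_now]] = True
            active[idx[assign | settled_now | dead]] = False
    return BasinRaster(
        window=window,
        x_grid=xs,
        y_grid=ys,
        labels=labels.reshape(n, n),
        attractors=attractors,
        converged_fraction=float(np.mean(settled)),
    )


def inverse_kick(
    post, regime: DisturbanceRegime, params: ModelParams = ModelParams()
):
    """Invert one fire kick: recover the pre-kick state from a post-kick one.

    ``x_pre = x_post / (1 - k1)`` and, since the tree kick used the
    pre-kick grass, ``y_pre = y_post / (1 - k2 omega(k1 x_pre))``.
    Vectorized over (..., 2).
    """
    if regime.k1 >= 1.0 or regime.k2 >= 1.0:
        raise ValueError("inverse kick requires k1 < 1 and k2 < 1")
    s = np.asarray(post, dtype=float)
    x_pre = s[..., 0] / (1.0 - regime.k1)
    survival = 1.0 - regime.k2 * _omega_raw(regime.k1 * x_pre, params.a)
    if np.any(np.abs(survival) < 1e-12):
        raise ZeroDivisionError("tree survival factor vanishes; kick not invertible")
    out = np.empty_like(s)
    out[..., 0] = x_pre
    out[..., 1] = s[..., 1] / survival
    return out


def inverse_map(
    state, regime: DisturbanceRegime, params: ModelParams = ModelParams()
):
    """Inverse flow-kick map: undo the kick, then flow backward for tau.

    Backward flow can blow up in finite time (logistic states above the
    carrying capacity diverge in reverse); this surfaces as a
    :class:`FlowError`.
    """
    return _flow_signed(inverse_kick(state, regime, params), -regime.tau, params)


@dataclass
class ManifoldTrace:
    """Polyline along one manifold branch of a saddle fixed point.

    branch is 'unstable+', 'unstable-', 'stable+' or 'stable-'; the sign
    picks the eigenvector direction.  ``truncated`` marks traces cut short
    by backward-flow blow-up or the window.
    """

    saddle: FixedPoint
    branch: str
    points: np.ndarray
    truncated: bool = False


def _eig_split(jac):
    eigs, vecs = np.linalg.eig(jac)
    if np.any(np.abs(np.imag(eigs)) > 1e-10):
        raise ValueError("complex eigenvalues: not a saddle with real splitting")
    eigs = np.real(eigs)
    vecs = np.real(vecs)
    iu = int(np.argmax(np.abs(eigs)))
    i_s = 1 - iu
    if not (np.abs(eigs[iu]) > 1.0 > np.abs(eigs[i_s])):
        raise ValueError("state is not a saddle of the map")
    return (eigs[iu], vecs[:, iu] / np.linalg.norm(vecs[:, iu])), (
        eigs[i_s],
        vecs[:, i_s] / np.linalg.norm(vecs[:, i_s]),
    )


def saddle_manifolds(
    saddle: FixedPoint,
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    seed_eps: float = 1e-4,
    steps: int = 2000,
    n_seed: int = 20,
    window: tuple = DEFAULT_WINDOW,
    stall_tol: float = 1e-8,
) -> list:
    """Trace the four invariant-manifold branches of a saddle.

    A fundamental domain of ``n_seed`` points between ``seed_eps`` and
    ``|lambda| * seed_eps`` along each eigenvector is iterated (forward
    map for the unstable directions, inverse map for the stable ones) and
    the generations concatenated into an ordered polyline, truncated at
    the window or at backward blow-up.  Iteration stops early once a
    generation stops moving (the branch has reached a limiting fixed
    point); the generous ``steps`` cap accommodates weakly unstable
    saddles whose iterates advance by a factor barely above 1.
    """
    (x0, x1), (y0, y1) = window
    jac = map_jacobian(saddle.state, regime, params)
    (lam_u, v_u), (lam_s, v_s) = _eig_split(jac)
    traces = []
    for kind, lam, v in (("unstable", lam_u, v_u), ("stable", lam_s, v_s)):
        ratio = abs(lam) if kind == "unstable" else 1.0 / abs(lam)
        for sign, tag in ((+1.0, "+"), (-1.0, "-")):
            rads = seed_eps * np.geomspace(1.0, ratio, n_seed, endpoint=False)
            seg = saddle.state[None, :] + sign * rads[:, None] * v[None, :]
            pts = [seg.copy()]
            truncated = False
            cur = seg
            for _ in range(steps):
                try:
                    if kind == "unstable":
                        nxt = flow_kick_map(cur, regime, params)
                    else:
                        nxt = inverse_map(cur, regime, params)
                except FlowError:
                    truncated = True
                    break
                if np.max(np.abs(nxt - cur)) < stall_tol:
                    break
                cur = nxt
                inside = (
                    (cur[:, 0] >= x0 - 1e-9)
                    & (cur[:, 0] <= x1)
                    & (cur[:, 1] >= y0 - 1e-9)
                    & (cur[:, 1] <= y1)
                )
                if not inside.any():
                    truncated = True
                    break
                pts.append(cur.copy())
                if not inside.all():
                    truncated = True
                    break
            poly = np.vstack(pts)
            keep = (
                (poly[:, 0] >= x0 - 1e-9)
                & (poly[:, 0] <= x1)
                & (poly[:, 1] >= y0 - 1e-9)
                & (poly[:, 1] <= y1)
            )
            traces.append(
                ManifoldTrace(
                    saddle=saddle,
                    branch=f"{kind}{tag}",
                    points=poly[keep],
                    truncated=truncated,
                )
            )
    return traces


@dataclass
class SlowRegion:
    """Raster of the slow band around the central saddle's unstable manifold.

    Operational definition (the band is only described graphically in the
    savanna literature): cells whose per-map-step displacement is below
    ``speed_factor`` times the window median, and which lie within
    max(local displacement, one cell diagonal) of the unstable-manifold
    polyline.  The threshold used is recorded.
    """

    window: tuple
    x_grid: np.ndarray
    y_grid: np.ndarray
    mask: np.ndarray
    speed_threshold: float
    traces: list = field(default_factory=list)


def _central_saddle(regime, params):
    census = enumerate_fixed_points(regime, params)
    saddles = [
        fp for fp in census if fp.kind == "coexistence" and fp.stability == "saddle"
    ]
    return max(saddles, key=lambda fp: fp.x) if saddles else None


def slow_region(
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    window: tuple = DEFAULT_WINDOW,
    n: int = 200,
    speed_factor: float = 0.1,
) -> SlowRegion:
    """Locate the slow band of a bistable (savanna-savanna type) regime.

    Returns an empty band when the regime has no interior coexistence
    saddle.
    """
    (x0, x1), (y0, y1) = window
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    grid = np.stack(np.meshgrid(xs, ys, indexing="ij"), axis=-1)
    flat = grid.reshape(-1, 2)
    disp = np.linalg.norm(flow_kick_map(flat, regime, params) - flat, axis=-1)
    threshold = speed_factor * float(np.median(disp))
    saddle = _central_saddle(regime, params)
    if saddle is None:
        return SlowRegion(
            window, xs, ys, np.zeros((n, n), dtype=bool), threshold, traces=[]
        )
    traces = [
        tr
        for tr in saddle_manifolds(saddle, regime, params, window=window)
        if tr.branch.startswith("unstable")
    ]
    poly = np.vstack([tr.points for tr in traces if len(tr.points)])
    from scipy.spatial import cKDTree

    tree = cKDTree(poly)
    dist, _ = tree.query(flat)
    cell = float(np.hypot(xs[1] - xs[0], ys[1] - ys[0]))
    mask = (disp < threshold) & (dist <= np.maximum(disp, cell))
    return SlowRegion(window, xs, ys, mask.reshape(n, n), threshold, traces=traces)
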