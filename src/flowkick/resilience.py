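"""Social value of the grass state, hysteresis sweeps, and transient
(decadal) versus asymptotic behaviour.

The social value of a regime is the grass biomass of its highest-grass
stable fixed point — the long-term forage value under the best available
attractor.  Sweeping a disturbance parameter out and back while tracking
the occupied attractor reveals hysteresis and tipping: once the tracked
branch is lost at a fold or transcritical locus, restoring the parameter
does not restore the state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DisturbanceRegime, ModelParams, flow_kick_map
from .fixed_points import enumerate_fixed_points, iterate_to_attractor
from .phase_portrait import compute_basins

__all__ = [
    "SocialValue",
    "SocialValueMap",
    "SweepResult",
    "TransientComparison",
    "social_value",
    "social_value_map",
    "hysteresis_sweep",
    "transient_comparison",
]


@dataclass(frozen=True)
class SocialValue:
    """Grass value of the best stable state of one regime.

    ``values`` lists the grass biomass of every stable fixed point in
    descending order; ``value`` is the largest and ``bistable`` is set
    when there is more than one stable state.
    """

    value: float
    bistable: bool
    values: tuple


def social_value(
    regime: DisturbanceRegime,
    params: ModelParams = ModelParams(),
    grid_n: int = 20,
) -> SocialValue:
    """Grass biomass of the highest-grass stable fixed point (map state)."""
    census = enumerate_fixed_points(regime, params, grid_n=grid_n)
    stable = sorted(
        (fp.x for fp in census if fp.stability == "stable"), reverse=True
    )
    if not stable:
        raise RuntimeError(f"no stable fixed point found for {regime}")
    return SocialValue(value=stable[0], bistable=len(stable) > 1, values=tuple(stable))


@dataclass
class SocialValueMap:
    """Raster of social values over (k1, tau) at fixed k2.

    ``values[i, j]`` is the highest stable grass value at
    ``(k1_grid[i], tau_grid[j])``; bistable cells are flagged and all of
    their stable grass values retained.
    """

    k2: float
    k1_grid: np.ndarray
    tau_grid: np.ndarray
    values: np.ndarray
    bistable: np.ndarray
    all_values: np.ndarray
    failures: list = field(default_factory=list)


def social_value_map(
    k2: float,
    k1_grid=None,
    tau_grid=None,
    params: ModelParams = ModelParams(),
    grid_n: int = 14,
) -> SocialValueMap:
    if k1_grid is None:
        k1_grid = np.linspace(0.005, 0.995, 100)
    if tau_grid is None:
        tau_grid = np.linspace(0.04, 4.0, 100)
    k1_grid = np.asarray(k1_grid, float)
    tau_grid = np.asarray(tau_grid, float)
    shape = (k1_grid.size, tau_grid.size)
    values = np.full(shape, np.nan)
    bistable = np.zeros(shape, dtype=bool)
    all_values = np.empty(shape, dtype=object)
    failures = []
    for i, k1 in enumerate(k1_grid):
        for j, tau in enumerate(tau_grid):
            try:
                sv = social_value(
                    DisturbanceRegime(k1=float(k1), k2=k2, tau=float(tau)),
                    params,
                    grid_n=grid_n,
                )
                values[i, j] = sv.value
                bistable[i, j] = sv.bistable
                all_values[i, j] = sv.values
            except Exception as exc:
                all_values[i, j] = ()
                failures.append((float(k1), float(tau), repr(exc)))
    return SocialValueMap(
        k2=k2,
        k1_grid=k1_grid,
        tau_grid=tau_grid,
        values=values,
        bistable=bistable,
        all_values=all_values,
        failures=failures,
    )


@dataclass
class SweepResult:
    """Attractor tracking along an ordered parameter path.

    ``states[i]`` is the attractor reached at ``path[i]`` starting from
    the previous tracked state; ``transitions`` records (step index,
    from-state, to-state) whenever the tracked grass value jumped by more
    than the jump tolerance.
    """

    path: list
    states: np.ndarray
    converged: np.ndarray
    transitions: list

    @property
    def final_state(self):
        return self.states[-1]


def hysteresis_sweep(
    path,
    params: ModelParams = ModelParams(),
    start=None,
    max_iter: int = 300,
    tol: float = 1e-6,
    jump_tol: float = 0.1,
) -> SweepResult:
    """Track the occupied attractor along a path of disturbance regimes.

    At each step the map is iterated from the previously tracked state to
    its new attractor (attractor *tracking*, not a global best), so folds
    and transcritical crossings show up as logged jumps; a path that
    crosses none is reversible.
    """
    path = list(path)
    if start is None:
        raise ValueError("an initial state is required")
    s = np.asarray(start, float)
    states = np.empty((len(path), 2))
    converged = np.zeros(len(path), dtype=bool)
    transitions = []
    prev = None
    for i, regime in enumerate(path):
        s, ok, _ = iterate_to_attractor(s, regime, params, max_iter=max_iter, tol=tol)
        states[i] = s
        converged[i] = ok
        if prev is not None and abs(s[0] - prev[0]) > jump_tol:
            transitions.append((i, prev.copy(), s.copy()))
        prev = s
    return SweepResult(path=path, states=states, converged=converged, transitions=transitions)


@dataclass
class TransientComparison:
    """Per-cell agreement between the finite-horizon and asymptotic grass
    value: proportion of basin-sampled initial conditions whose grass
    value at the horizon is within tolerance of the long-term value, and
    the mean absolute distance."""

    k2: float
    k1_grid: np.ndarray
    tau_grid: np.ndarray
    proportion: np.ndarray
    mean_distance: np.ndarray
    metadata: dict


def transient_comparison(
    k2: float,
    k1_grid=None,
    tau_grid=None,
    params: ModelParams = ModelParams(),
    horizon: float = 30.0,
    rel_tol: float = 0.05,
    ic_n: int = 400,
    grid_n: int = 14,
    window=((0.0, 1.1), (0.0, 1.1)),
) -> TransientComparison:
    """Compare the grass value after a finite horizon with the long-term one.

    For each (k1, tau) cell, initial conditions on a uniform lattice of
    about ``ic_n`` points are restricted to the basin of the highest-grass
    stable fixed point; each is iterated ``floor(horizon / tau)`` kicks
    and counted as "agreeing" when its grass value is within ``rel_tol``
    (relative) of the long-term value, with an absolute floor of 1e-3 when
    the long-term value is below 0.02.  Deterministic — the lattice uses
    no randomness.  The horizon is in nondimensional time units (years
    when the grass growth rate is 1/yr), recorded in the metadata.
    """
    if k1_grid is None:
        k1_grid = np.linspace(0.05, 0.95, 10)
    if tau_grid is None:
        tau_grid = np.linspace(0.4, 4.0, 10)
    k1_grid = np.asarray(k1_grid, float)
    tau_grid = np.asarray(tau_grid, float)
    m = int(round(np.sqrt(ic_n)))
    shape = (k1_grid.size, tau_grid.size)
    proportion = np.full(shape, np.nan)
    mean_distance = np.full(shape, np.nan)
    for i, k1 in enumerate(k1_grid):
        for j, tau in enumerate(tau_grid):
            regime = DisturbanceRegime(k1=float(k1), k2=k2, tau=float(tau))
            census = enumerate_fixed_points(regime, params, grid_n=grid_n)
            stable = [fp for fp in census if fp.stability == "stable"]
            if not stable:
                continue
            target = max(stable, key=lambda fp: fp.x)
            basins = compute_basins(
                regime, params, window=window, n=m, attractors=stable
            )
            t_idx = next(
                idx
                for idx, fp in enumerate(stable)
                if np.allclose(fp.state, target.state)
            )
            cells = np.stack(
                np.meshgrid(basins.x_grid, basins.y_grid, indexing="ij"), axis=-1
            ).reshape(-1, 2)
            ics = cells[(basins.labels == t_idx).ravel()]
            if ics.shape[0] == 0:
                continue
            n_kicks = int(np.floor(horizon / tau))
            s = ics.copy()
            for _ in range(n_kicks):
                s = flow_kick_map(s, regime, params)
            x_inf = target.x
            dist = np.abs(s[:, 0] - x_inf)
            tol = max(rel_tol * x_inf, 1e-3) if x_inf < 0.02 else rel_tol * x_inf
            proportion[i, j] = float(np.mean(dist <= tol))
            mean_distance[i, j] = float(np.mean(dist))
    return TransientComparison(
        k2=k2,
        k1_grid=k1_grid,
        tau_grid=tau_grid,
        proportion=proportion,
        mean_distance=mean_distance,
        metadata={
            "horizon": horizon,
            "time_units": "nondimensional (years for gamma_G = 1/yr)",
            "rel_tol": rel_tol,
            "abs_floor": 1e-3,
            "abs_floor_below": 0.02,
            "ic_lattice": m,
        },
    )
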