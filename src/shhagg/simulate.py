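"""Stiff integration of the aggregation ODEs and steady-state detection.

The system is stiff (fast bimolecular binding against slow dispersal), so
integration uses a backward-differentiation formula with the analytic sparse
Jacobian from :mod:`shhagg.network`.  Times are minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .config import ModelConfig, ParameterSet
from .network import MassActionRHS, SpeciesIndex, build_rhs, enumerate_species


class SolverError(RuntimeError):
    """Raised when the ODE solver fails; carries the failing time."""


class MissingTimeError(KeyError):
    """Requested snapshot time was not stored in the trajectory."""


@dataclass
class Trajectory:
    """Species counts over time.

    ``states`` has one row per entry of ``times`` (minutes, strictly
    increasing); the first row is the initial condition.  ``index`` maps
    species to columns.
    """

    times: np.ndarray
    states: np.ndarray
    index: SpeciesIndex
    config: ModelConfig
    params: ParameterSet

    def snapshot(self, t: float) -> np.ndarray:
        """Exact stored state at time ``t`` (minutes)."""
        hits = np.nonzero(np.isclose(self.times, t, rtol=0.0, atol=1e-9))[0]
        if hits.size == 0:
            raise MissingTimeError(f"time {t} min not stored in trajectory")
        return self.states[hits[0]].copy()


def _time_grid(t_end: float, snapshot_times: Sequence[float] | None,
               grid_dt: float | None) -> np.ndarray:
    pts = [0.0, float(t_end)]
    if grid_dt:
        pts.extend(np.arange(0.0, t_end, grid_dt))
    if snapshot_times is not None:
        for t in snapshot_times:
            if not 0.0 <= t <= t_end:
                raise ValueError(f"snapshot time {t} outside [0, {t_end}]")
            pts.append(float(t))
    return np.unique(np.asarray(pts, dtype=float))


def integrate(config: ModelConfig, params: ParameterSet, t_end: float,
              snapshot_times: Sequence[float] | None = None, *,
              rtol: float = 1e-8, atol: float = 1e-10,
              y0: np.ndarray | None = None, grid_dt: float | None = 1.0,
              rhs: MassActionRHS | None = None) -> Trajectory:
    """Integrate the model from ``t=0`` to ``t_end`` minutes.

    The default output grid is 1-minute resolution (needed by the
    dispersal-ratio analysis) plus any requested ``snapshot_times``.  The
    initial state is all-zero unless ``y0`` is given.  Small negative solver
    excursions are clipped to zero; negatives beyond tolerance raise
    :class:`SolverError`.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if rhs is None:
        rhs = build_rhs(config, params)
    index = rhs.index
    if y0 is None:
        y0 = np.zeros(len(index))
    else:
        y0 = np.asarray(y0, dtype=float)
        if y0.shape != (len(index),):
            raise ValueError("y0 length does not match the species index")
    t_eval = _time_grid(t_end, snapshot_times, grid_dt)
    sol = solve_ivp(rhs, (0.0, float(t_end)), y0, method="BDF", jac=rhs.jac,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        t_fail = sol.t[-1] if sol.t.size else 0.0
        raise SolverError(f"stiff solver failed near t={t_fail:.3f} min: {sol.message}")
    states = sol.y.T.copy()
    neg_tol = max(10.0 * atol, 1e-12 * max(1.0, float(states.max(initial=0.0))))
    worst = float(states.min(initial=0.0))
    if worst < -neg_tol:
        raise SolverError(f"negative species count {worst:.3e} beyond tolerance {neg_tol:.1e}")
    np.clip(states, 0.0, None, out=states)
    return Trajectory(sol.t.copy(), states, index, config, params)


@dataclass
class SteadyStateResult:
    """Outcome of steady-state detection on the cell-associated pool.

    ``converged`` is False when the metric never crossed the tolerance by
    ``t_max``; ``t_ss`` is then the last grid time examined.
    """

    converged: bool
    t_ss: float
    state: np.ndarray
    metric: float
    tolerance: float


def convergence_metric(rhs: MassActionRHS, state: np.ndarray) -> float:
    """max over cell species of |dX/dt| / (|X| + 1), in min^-1.

    The dispersed pool is excluded: it accumulates without bound by
    construction, so only the cell-associated pool can reach steady state.
    """
    dy = rhs(0.0, state)
    mask = rhs.index.cell_mask
    return float(np.max(np.abs(dy[mask]) / (np.abs(state[mask]) + 1.0)))


def find_steady_state(config: ModelConfig, params: ParameterSet, *,
                      tolerance: float = 1e-6, t_max: float = 48 * 60.0,
                      grid_dt: float = 1.0, rtol: float = 1e-8,
                      atol: float = 1e-10) -> SteadyStateResult:
    """Earliest grid time at which the cell pool is stationary.

    Integrates to ``t_max`` and returns the first time on the output grid
    where the normalised cell-pool derivative falls below ``tolerance``
    (default 1e-6 min^-1).  Non-convergence is reported explicitly, not
    raised.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    rhs = build_rhs(config, params)
    traj = integrate(config, params, t_max, rtol=rtol, atol=atol,
                     grid_dt=grid_dt, rhs=rhs)
    for i, t in enumerate(traj.times):
        m = convergence_metric(rhs, traj.states[i])
        if m <= tolerance:
            return SteadyStateResult(True, float(t), traj.states[i].copy(), m, tolerance)
    m = convergence_metric(rhs, traj.states[-1])
    return SteadyStateResult(False, float(traj.times[-1]), traj.states[-1].copy(), m, tolerance)
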