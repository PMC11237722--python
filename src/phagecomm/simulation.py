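"""Numerical integration of the community model and steady-state summaries.

Integration uses scipy's LSODA (adaptive, stiffness-switching) with tight
tolerances and an extinction floor: any species whose density falls below
1e-12 is clamped to exactly zero for the remainder of the run, so
numerically extinct populations cannot resurge from round-off-sized tails.

"Steady state" follows the operational definition of integrating until
species abundances no longer change between time points.  Where the
attractor is a limit cycle rather than a fixed point (the competition
preset with both phage has no stable fixed point), the run is flagged
non-converged and summarized by the time average over a trailing window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    EXTINCTION_FLOOR,
    CommunityParams,
    CommunityState,
    rhs_array,
)

__all__ = [
    "Trajectory",
    "SteadyStateResult",
    "integrate",
    "run_to_steady_state",
    "relative_specialist_abundance",
    "DEFAULT_INIT",
]

SPECIES = ("E", "S", "G", "P")

#: Every simulated scenario starts all present species at density 0.1.
DEFAULT_INIT = CommunityState(E=0.1, S=0.1, G=0.1, P=0.1)


@dataclass
class Trajectory:
    """Dense-sampled solution of the community ODE."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 4), columns E, S, G, P
    params: CommunityParams
    converged: bool = True  # False if the integrator failed before t_end

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    @property
    def final_state(self) -> CommunityState:
        return CommunityState.from_array(self.states[-1], t=self.t_end)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SteadyStateResult:
    """Outcome of integrating to (or toward) a steady state.

    ``max_residual`` is the largest |dx/dt| component at ``final_state``
    and is reported whether or not the run converged.
    """

    final_state: CommunityState
    converged: bool
    method: str  # "pointwise" or "window_average"
    t_reached: float
    max_residual: float
    params: Optional[CommunityParams] = field(default=None, repr=False)

    def to_json(self, path: Union[str, Path]) -> None:
        d = {
            "final_state": {k: getattr(self.final_state, k) for k in SPECIES},
            "converged": self.converged,
            "method": self.method,
            "t_reached": self.t_reached,
            "max_residual": self.max_residual,
        }
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def _integrate_clamped(
    p: CommunityParams,
    y0: np.ndarray,
    t0: float,
    t1: float,
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
    floor: float,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Integrate on [t0, t1] with extinction clamping at output resolution.

    Returns ((times, states), ok).  The leg is integrated without event
    detection; if any previously-alive species has fallen below the floor
    at an output sample, the leg is truncated at the first such sample,
    that species is set to exactly 0, and integration restarts from there
    without it.  Species at exactly 0 stay at 0 (every term in the
    dynamics is proportional to the species' own biomass), so extinct
    populations cannot resurge.
    """
    y = np.asarray(y0, dtype=float).copy()
    y[y <= floor] = 0.0
    t = t0
    out_t: list[np.ndarray] = []
    out_y: list[np.ndarray] = []

    def fun(t, y):  # noqa: ANN001
        # densities below the extinction floor contribute nothing to the
        # dynamics; this keeps relaxation-oscillation troughs from driving
        # the solver into astronomically deep (or negative) excursions
        return rhs_array(np.where(y < floor, 0.0, y), p)

    for _ in range(12):  # at most 4 extinctions; margin for safety
        extinct = y == 0.0
        te_leg = t_eval[t_eval > t + 1e-12]
        if te_leg.size == 0:
            te_leg = np.array([t1])
        sol = solve_ivp(
            fun, (t, t1), y, method="LSODA", t_eval=te_leg, rtol=rtol, atol=atol
        )
        sol_t = np.asarray(sol.t, dtype=float)
        if sol_t.size == 0:
            return _concat(out_t, out_y, floor), sol.status == 0
        sol_y = sol.y.T.copy()  # (n, 4)
        sol_y[:, extinct] = 0.0
        below = (sol_y < floor) & ~extinct[None, :]
        hit = np.flatnonzero(below.any(axis=1))
        if hit.size == 0:
            out_t.append(sol_t)
            out_y.append(sol_y)
            if sol.status != 0:
                return _concat(out_t, out_y, floor), False
            return _concat(out_t, out_y, floor), True
        k = int(hit[0])
        y = sol_y[k].copy()
        y[y < floor] = 0.0
        t = float(sol_t[k])
        out_t.append(sol_t[: k + 1])
        chunk = sol_y[: k + 1].copy()
        chunk[k] = y
        out_y.append(chunk)
        if not np.any(y > 0.0):
            rest = t_eval[t_eval > t + 1e-12]
            if rest.size:
                out_t.append(rest)
                out_y.append(np.zeros((rest.size, 4)))
            return _concat(out_t, out_y, floor), True
    return _concat(out_t, out_y, floor), False


def _concat(
    out_t: list[np.ndarray], out_y: list[np.ndarray], floor: float
) -> tuple[np.ndarray, np.ndarray]:
    if not out_t:
        return np.empty(0), np.empty((0, 4))
    t = np.concatenate(out_t)
    y = np.vstack(out_y)
    y[y < floor] = 0.0  # clamp round-off tails in the sampled output
    return t, y


def integrate(
    params: CommunityParams,
    init: CommunityState = DEFAULT_INIT,
    t_end: float = 1000.0,
    step_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    floor: float = EXTINCTION_FLOOR,
) -> Trajectory:
    """Integrate the community ODE from ``init`` to ``t_end``.

    Output is sampled every ``step_out`` time units (plus t=0 and t_end).
    Raises on non-finite states; integrator failure returns the partial
    trajectory with ``converged=False``.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    y0 = init.as_array()
    t_eval = np.arange(0.0, t_end + 0.5 * step_out, step_out)
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    y0c = y0.copy()
    y0c[y0c < floor] = 0.0
    (t, y), ok = _integrate_clamped(params, y0c, 0.0, t_end, t_eval, rtol, atol, floor)
    if t.size == 0 or t[0] > 0.0:
        t = np.concatenate([[0.0], t])
        y = np.vstack([y0c, y]) if y.size else y0c[None, :]
    if not np.all(np.isfinite(y)):
        raise RuntimeError("integration produced non-finite state")
    return Trajectory(times=t, states=y, params=params, converged=ok)


def run_to_steady_state(
    params: CommunityParams,
    init: CommunityState = DEFAULT_INIT,
    tol: float = 1e-9,
    rel_tol: float = 1e-3,
    window: float = 100.0,
    t_max: float = 1e5,
    step_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    floor: float = EXTINCTION_FLOOR,
) -> SteadyStateResult:
    """Integrate until abundances no longer change between time points.

    The run is declared converged (method ``pointwise``) when every
    species' range over a trailing window of duration ``window`` is below
    ``tol`` absolutely and also small relative to the species' own level
    (``rel_tol``); the relative part keeps slowly decaying near-extinct
    tails integrating until the extinction clamp resolves them to exact
    zero.  If ``t_max`` is reached first — the attractor is a limit cycle
    or convergence is merely slow — the result is the time average over
    the trailing window (method ``window_average``) with
    ``converged=False``.
    """
    if not tol > 0:
        raise ValueError("tol must be positive")
    y = init.as_array().copy()
    y[y < floor] = 0.0
    t = 0.0
    n_keep = max(int(round(window / step_out)), 2)
    t_eval_rel = np.arange(step_out, window + 0.5 * step_out, step_out)
    while t < t_max:
        chunk_end = min(t + window, t_max)
        te = t + t_eval_rel
        te = te[te <= chunk_end + 1e-9]
        if te.size == 0:
            te = np.array([chunk_end])
        (tt, yy), ok = _integrate_clamped(params, y, t, chunk_end, te, rtol, atol, floor)
        if tt.size == 0:
            break
        if not ok:
            y = yy[-1]
            t = tt[-1]
            break
        window_states = np.vstack([y[None, :], yy])
        y = yy[-1]
        t = tt[-1]
        span = window_states.max(axis=0) - window_states.min(axis=0)
        mean = window_states.mean(axis=0)
        settled = (span < tol) & ((mean == 0.0) | (span <= rel_tol * mean))
        if np.all(settled):
            res = float(np.abs(rhs_array(y, params)).max())
            return SteadyStateResult(
                final_state=CommunityState.from_array(y, t=t),
                converged=True,
                method="pointwise",
                t_reached=t,
                max_residual=res,
                params=params,
            )
    # not converged: time-average of the trailing window
    avg = window_states.mean(axis=0) if "window_states" in locals() else y
    avg = np.where(avg < floor, 0.0, avg)
    res = float(np.abs(rhs_array(avg, params)).max())
    return SteadyStateResult(
        final_state=CommunityState.from_array(avg, t=t),
        converged=False,
        method="window_average",
        t_reached=t,
        max_residual=res,
        params=params,
    )


def relative_specialist_abundance(result: SteadyStateResult) -> Optional[float]:
    """Specialist share of total phage biomass, P/(P+G), at steady state.

    Values above 0.5 mean the specialist is the more abundant phage.
    Returns ``None`` (explicit undefined marker) when both phage are
    extinct, never a NaN.
    """
    P = result.final_state.P
    G = result.final_state.G
    tot = P + G
    if tot == 0.0:
        return None
    return float(P / tot)
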