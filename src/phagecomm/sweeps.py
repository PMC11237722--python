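"""Scenario battery and parameter-sweep surfaces.

The scenario battery runs the four phage treatments (none, specialist
only, generalist only, both) for one interaction mode and cost ratio.
1-D sweeps scan the cost-of-generalism ratio; 2-D sweeps cross it with a
prey asymmetry (relative growth rate, or relative interaction
coefficient).  Every cell is an independent steady-state run from the
standard all-species-at-0.1 inoculum; cells that never settle to a fixed
point (the competition preset with both phage can orbit indefinitely)
are summarized by a trailing-window time average and flagged
``converged=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .model_core import (
    EXTINCTION_FLOOR,
    CommunityParams,
    CommunityState,
    InteractionMode,
    apply_cost,
    preset_params,
)
from .simulation import (
    SteadyStateResult,
    relative_specialist_abundance,
    run_to_steady_state,
)

__all__ = [
    "SweepGrid",
    "scenario_battery",
    "sweep_cost",
    "sweep_cost_by_asymmetry",
    "SCENARIOS",
]

#: Phage treatments of the scenario battery, as (name, G present, P present).
SCENARIOS = (
    ("no_phage", False, False),
    ("specialist_only", False, True),
    ("generalist_only", True, False),
    ("both_phage", True, True),
)

#: Default per-cell integration cap for sweeps.  Oscillatory cells never
#: converge pointwise; by 3e4 time units their trailing-window averages are
#: stable far below the resolution at which cells are compared.
SWEEP_T_MAX = 3e4


@dataclass
class SweepGrid:
    """Rectangular sweep results in long format.

    ``table`` has one row per cell with the axis values, final densities,
    specialist relative abundance (NaN encodes the undefined no-phage
    case in the tabular output), and the convergence / prey-exclusion /
    infeasibility flags.
    """

    table: pd.DataFrame
    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: Optional[str] = None
    axis2_values: Optional[np.ndarray] = None
    mode: Optional[str] = None
    cost_kind: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".meta.json")
        d = {
            "axis1_name": self.axis1_name,
            "axis1_values": [float(v) for v in self.axis1_values],
            "axis2_name": self.axis2_name,
            "axis2_values": None
            if self.axis2_values is None
            else [float(v) for v in self.axis2_values],
            "mode": self.mode,
            "cost_kind": self.cost_kind,
            **self.meta,
        }
        sidecar.write_text(json.dumps(d, indent=2) + "\n")

    def pivot(self, value: str = "rel_abundance") -> pd.DataFrame:
        """2-D sweeps as a (axis2 x axis1) matrix of ``value``."""
        if self.axis2_name is None:
            raise ValueError("pivot requires a 2-D sweep")
        return self.table.pivot(index=self.axis2_name, columns=self.axis1_name, values=value)

    def plot_heatmap(self, value: str = "rel_abundance", ax=None, **imshow_kw):
        """Heatmap of a 2-D sweep (cost on x, asymmetry on y)."""
        import matplotlib.pyplot as plt

        mat = self.pivot(value)
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(
            mat.values,
            origin="lower",
            aspect="auto",
            extent=(
                float(self.axis1_values[0]),
                float(self.axis1_values[-1]),
                float(self.axis2_values[0]),
                float(self.axis2_values[-1]),
            ),
            **imshow_kw,
        )
        ax.set_xlabel(self.axis1_name)
        ax.set_ylabel(self.axis2_name)
        ax.figure.colorbar(im, ax=ax, label=value)
        return ax


def _cell_record(res: SteadyStateResult, floor: float = EXTINCTION_FLOOR) -> dict:
    s = res.final_state
    ra = relative_specialist_abundance(res)
    return {
        "E": s.E,
        "S": s.S,
        "G": s.G,
        "P": s.P,
        "rel_abundance": np.nan if ra is None else ra,
        "converged": res.converged,
        "E_excluded": s.E < floor,
        "S_excluded": s.S < floor,
    }


def _init_state(g_present: bool, p_present: bool, density: float = 0.1) -> CommunityState:
    return CommunityState(
        E=density, S=density, G=density if g_present else 0.0, P=density if p_present else 0.0
    )


def scenario_battery(
    mode: Union[InteractionMode, str],
    cost_ratio: float = 1.0,
    cost_kind: str = "burst",
    t_max: float = SWEEP_T_MAX,
    base_params: Optional[CommunityParams] = None,
    **ss_kwargs,
) -> pd.DataFrame:
    """End states of the four phage-treatment scenarios.

    Present species start at density 0.1, absent species at exactly 0.
    Returns one row per scenario with final densities, each prey's share
    of total prey biomass, and the specialist relative abundance.
    """
    params = base_params if base_params is not None else preset_params(mode)
    if cost_ratio != 1.0:
        params = apply_cost(params, cost_kind, cost_ratio)
    rows = []
    for name, g_on, p_on in SCENARIOS:
        res = run_to_steady_state(params, init=_init_state(g_on, p_on), t_max=t_max, **ss_kwargs)
        rec = _cell_record(res)
        prey_tot = rec["E"] + rec["S"]
        rec["prey_frac_E"] = np.nan if prey_tot == 0 else rec["E"] / prey_tot
        rec["prey_frac_S"] = np.nan if prey_tot == 0 else rec["S"] / prey_tot
        rows.append({"scenario": name, **rec})
    return pd.DataFrame(rows)


def _default_ratio_grid() -> np.ndarray:
    return np.geomspace(1.0, 10.0, 30)


def sweep_cost(
    mode: Union[InteractionMode, str],
    cost_kind: str,
    ratios: Optional[np.ndarray] = None,
    t_max: float = SWEEP_T_MAX,
    base_params: Optional[CommunityParams] = None,
    **ss_kwargs,
) -> SweepGrid:
    """1-D sweep of the cost-of-generalism ratio with both phage present."""
    ratios = _default_ratio_grid() if ratios is None else np.asarray(ratios, dtype=float)
    if np.any(ratios <= 0) or np.any(np.diff(ratios) <= 0):
        raise ValueError("ratios must be positive and strictly increasing")
    base = base_params if base_params is not None else preset_params(mode)
    rows = []
    for r in ratios:
        res = run_to_steady_state(apply_cost(base, cost_kind, float(r)), t_max=t_max, **ss_kwargs)
        rows.append({"cost_ratio": float(r), **_cell_record(res)})
    return SweepGrid(
        table=pd.DataFrame(rows),
        axis1_name="cost_ratio",
        axis1_values=ratios,
        mode=str(InteractionMode(mode).value),
        cost_kind=cost_kind,
    )


_ASYMMETRY_KINDS = ("growth_rate", "interaction_coefficient")


def _apply_asymmetry(
    params: CommunityParams, mode: InteractionMode, kind: str, value: float
) -> CommunityParams:
    """Bias prey E relative to prey S by ``value``.

    ``growth_rate`` sets mu_E = value * mu_S (mu_S stays 0.5);
    ``interaction_coefficient`` sets the E-side coefficient relative to
    the S-side one held at its default of 1: beta_ES under competition,
    alpha_ES under mutualism.
    """
    if kind == "growth_rate":
        return params.replace(mu_E=value * params.mu_S)
    if kind == "interaction_coefficient":
        if mode is InteractionMode.COMPETITION:
            return params.replace(beta_ES=value * params.beta_SE)
        return params.replace(alpha_ES=value * params.alpha_SE)
    raise ValueError(f"unknown asymmetry_kind {kind!r}; expected one of {_ASYMMETRY_KINDS}")


def sweep_cost_by_asymmetry(
    mode: Union[InteractionMode, str],
    cost_kind: str,
    ratios: Optional[np.ndarray] = None,
    asymmetry_kind: str = "growth_rate",
    asymmetry: Optional[np.ndarray] = None,
    t_max: float = SWEEP_T_MAX,
    base_params: Optional[CommunityParams] = None,
    **ss_kwargs,
) -> SweepGrid:
    """2-D sweep: cost of generalism crossed with a prey asymmetry.

    Mutualism cells where the prey pair cannot persist at all (both prey
    below the extinction floor) are flagged ``infeasible``.
    """
    mode = InteractionMode(mode)
    ratios = _default_ratio_grid() if ratios is None else np.asarray(ratios, dtype=float)
    asymmetry = (
        np.geomspace(0.25, 4.0, 30) if asymmetry is None else np.asarray(asymmetry, dtype=float)
    )
    if np.any(ratios <= 0) or np.any(asymmetry <= 0):
        raise ValueError("grids must be positive")
    base = base_params if base_params is not None else preset_params(mode)
    rows = []
    for a in asymmetry:
        biased = _apply_asymmetry(base, mode, asymmetry_kind, float(a))
        for r in ratios:
            res = run_to_steady_state(
                apply_cost(biased, cost_kind, float(r)), t_max=t_max, **ss_kwargs
            )
            rec = _cell_record(res)
            rec["infeasible"] = rec["E_excluded"] and rec["S_excluded"]
            rows.append({"cost_ratio": float(r), asymmetry_kind: float(a), **rec})
    return SweepGrid(
        table=pd.DataFrame(rows),
        axis1_name="cost_ratio",
        axis1_values=ratios,
        axis2_name=asymmetry_kind,
        axis2_values=asymmetry,
        mode=str(mode.value),
        cost_kind=cost_kind,
    )
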