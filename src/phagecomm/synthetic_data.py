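"""Synthetic plate-reader and plaque-assay observables.

Emulates the measurement layer of a phage competition experiment on top
of simulated community dynamics: species-resolved optical-density-like
prey signals sampled every 20 minutes over 48 hours, and endpoint phage
titers (PFU/mL) with a lower limit of detection.  Titers below the LOD
are reported as censored bounds — never as zero and never as a
fabricated positive value.

Noise is multiplicative lognormal with a configurable coefficient of
variation: plate signals and titers are positive, and measurement error
on both is closer to proportional than additive.  The mapping from
dimensionless model time to clock hours is a declared configuration
scale; it affects only this readout layer, never the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_core import CommunityParams, CommunityState
from .simulation import Trajectory, integrate

__all__ = [
    "Titer",
    "LnFoldChange",
    "PlateReadout",
    "simulate_readout",
    "ln_fold_change",
    "classify_winner",
    "readouts_to_frame",
    "LOD_PFU",
]

#: Lower limit of detection of the plaque assay, PFU/mL.
LOD_PFU = 500.0

SCENARIO_INITS = {
    "no_phage": (False, False),
    "specialist_only": (False, True),
    "generalist_only": (True, False),
    "both_phage": (True, True),
}


@dataclass(frozen=True)
class Titer:
    """A phage titer measurement; censored titers carry the LOD as bound."""

    value: float  # PFU/mL, or the LOD when censored
    censored: bool = False

    def __str__(self) -> str:
        return f"< {self.value:g} PFU/mL (below LOD)" if self.censored else f"{self.value:g} PFU/mL"


@dataclass(frozen=True)
class LnFoldChange:
    """ln(final/initial titer); censored finals give an upper bound."""

    value: float
    censored: bool = False


@dataclass
class PlateReadout:
    """One replicate of a synthetic 48-h plate-reader + plaque-assay run."""

    times_h: np.ndarray
    signal_E: np.ndarray  # OD-equivalent units
    signal_S: np.ndarray
    titer_G: Titer
    titer_P: Titer
    initial_titer_G: float  # PFU/mL (0 when phage absent from scenario)
    initial_titer_P: float
    lod: float = LOD_PFU
    replicate: int = 0
    seed: Optional[int] = None
    scenario: str = "both_phage"


def simulate_readout(
    params: CommunityParams,
    scenario: str = "both_phage",
    biomass_to_od: float = 1.0,
    biomass_to_pfu: float = 1e7,
    noise_cv: float = 0.1,
    n_replicates: int = 3,
    seed: int = 0,
    hours: float = 48.0,
    sample_minutes: float = 20.0,
    model_time_per_hour: float = 1.0,
    lod: float = LOD_PFU,
    init_density: float = 0.1,
) -> list[PlateReadout]:
    """Generate noisy replicate readouts of one phage-treatment scenario.

    Prey signals are biomass x ``biomass_to_od`` with multiplicative
    lognormal noise of coefficient of variation ``noise_cv``; endpoint
    titers are final phage biomass x ``biomass_to_pfu`` with the same
    noise model, censored at ``lod``.  Replicates differ only by their
    noise stream, which is derived deterministically from ``seed``.

    ``model_time_per_hour`` maps dimensionless model time onto the
    48-hour assay window (default: 1 model time unit per hour); larger
    values let the endpoint reflect long-run behavior.
    """
    if scenario not in SCENARIO_INITS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {sorted(SCENARIO_INITS)}")
    if biomass_to_od <= 0 or biomass_to_pfu <= 0:
        raise ValueError("signal scales must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    g_on, p_on = SCENARIO_INITS[scenario]
    init = CommunityState(
        E=init_density,
        S=init_density,
        G=init_density if g_on else 0.0,
        P=init_density if p_on else 0.0,
    )
    n_samples = int(round(hours * 60.0 / sample_minutes)) + 1  # 145 for 48 h / 20 min
    times_h = np.linspace(0.0, hours, n_samples)
    t_end = hours * model_time_per_hour
    step = sample_minutes / 60.0 * model_time_per_hour
    traj = integrate(params, init, t_end=t_end, step_out=step)
    # samples align with the trajectory's output grid
    idx = np.round(times_h * model_time_per_hour / step).astype(int)
    idx = np.clip(idx, 0, traj.states.shape[0] - 1)
    states = traj.states[idx]

    sigma_ln = math.sqrt(math.log(1.0 + noise_cv**2)) if noise_cv > 0 else 0.0

    def noisy(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if sigma_ln == 0.0:
            return x
        # mean-one lognormal multiplicative noise
        return x * rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=np.shape(x))

    readouts = []
    ss = np.random.SeedSequence(entropy=seed)
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rng = np.random.default_rng(child)
        sig_E = noisy(states[:, 0] * biomass_to_od, rng)
        sig_S = noisy(states[:, 1] * biomass_to_od, rng)
        titers = []
        for col in (2, 3):
            raw = float(states[-1, col]) * biomass_to_pfu
            raw = float(noisy(np.array(raw), rng))
            titers.append(Titer(value=lod, censored=True) if raw < lod else Titer(value=raw))
        readouts.append(
            PlateReadout(
                times_h=times_h,
                signal_E=sig_E,
                signal_S=sig_S,
                titer_G=titers[0],
                titer_P=titers[1],
                initial_titer_G=init.G * biomass_to_pfu,
                initial_titer_P=init.P * biomass_to_pfu,
                lod=lod,
                replicate=rep,
                seed=seed,
                scenario=scenario,
            )
        )
    return readouts


def ln_fold_change(final_titer: Union[Titer, float], initial_titer: float) -> LnFoldChange:
    """ln(final PFU/mL / initial PFU/mL); zero means no net titer change.

    A censored final titer yields the upper bound ln(LOD / initial),
    flagged censored: the true fold change is at most that value.
    """
    if initial_titer <= 0:
        raise ValueError("initial_titer must be positive")
    if isinstance(final_titer, Titer):
        return LnFoldChange(
            value=math.log(final_titer.value / initial_titer), censored=final_titer.censored
        )
    if final_titer <= 0:
        raise ValueError("observed final titer must be positive; use a censored Titer for < LOD")
    return LnFoldChange(value=math.log(final_titer / initial_titer), censored=False)


def classify_winner(readouts: Sequence[PlateReadout]) -> str:
    """Which phage dominates a replicate set by endpoint titer.

    Censoring is handled by interval bounds: a censored titer is known
    only to lie in [0, LOD].  The call is ``generalist`` or
    ``specialist`` only when the mean-titer intervals are disjoint,
    ``tie`` when they overlap, and ``both_below_LOD`` when every titer
    of both phage is censored.
    """
    if not readouts:
        raise ValueError("need at least one replicate")

    def bounds(titers: list[Titer]) -> tuple[float, float]:
        lo = float(np.mean([0.0 if t.censored else t.value for t in titers]))
        hi = float(np.mean([t.value for t in titers]))  # censored carry the LOD
        return lo, hi

    tG = [r.titer_G for r in readouts]
    tP = [r.titer_P for r in readouts]
    if all(t.censored for t in tG) and all(t.censored for t in tP):
        return "both_below_LOD"
    loG, hiG = bounds(tG)
    loP, hiP = bounds(tP)
    if loG > hiP:
        return "generalist"
    if loP > hiG:
        return "specialist"
    return "tie"


def readouts_to_frame(readouts: Sequence[PlateReadout]) -> pd.DataFrame:
    """Tidy long-format table: replicate, time_h, channel, value, censored."""
    rows = []
    for r in readouts:
        for t, e, s in zip(r.times_h, r.signal_E, r.signal_S):
            rows.append({"replicate": r.replicate, "time_h": t, "channel": "od_E",
                         "value": e, "censored": False})
            rows.append({"replicate": r.replicate, "time_h": t, "channel": "od_S",
                         "value": s, "censored": False})
        for name, titer in (("titer_G", r.titer_G), ("titer_P", r.titer_P)):
            rows.append({"replicate": r.replicate, "time_h": r.times_h[-1], "channel": name,
                         "value": titer.value, "censored": titer.censored})
    return pd.DataFrame(rows)
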