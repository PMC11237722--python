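"""Fixed points, stability, the S* invasion criterion, and cost thresholds.

Fixed points are enumerated per presence subset: for each of the 16
subsets of {E, S, G, P} the absent species are pinned to zero and the
reduced algebraic system is solved from a deterministic lattice of
starting points.  Solving subset-by-subset avoids spurious roots with
tiny negative components and gives each boundary equilibrium its own
well-conditioned problem.  Stability is classified from the analytic
Jacobian of the full 4-species system.

The S* criterion applies R*-style resource-competition logic with prey S
as the "resource" shared by the two phage: the phage that holds its net
growth at zero at the lower S density excludes the other.  For the
specialist, S_P* = delta / (gamma_P * sigma_P); for the generalist,
which also harvests prey E, S_G* = delta / (gamma_G * sigma_G) - E.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import root

from .model_core import (
    CommunityParams,
    CommunityState,
    InteractionMode,
    apply_cost,
    jacobian,
    preset_params,
    rhs_array,
)
from .simulation import run_to_steady_state

__all__ = [
    "FixedPoint",
    "SStarReport",
    "enumerate_fixed_points",
    "classify_stability",
    "sstar_criterion",
    "find_cost_threshold",
    "fixed_points_to_frame",
]

logger = logging.getLogger(__name__)

#: Eigenvalue real parts within +/- this of zero are called marginal.
MARGINAL_EPS = 1e-7
RESIDUAL_TOL = 1e-9
DEDUP_TOL = 1e-6


@dataclass
class FixedPoint:
    """A non-negative root of the community right-hand side."""

    state: CommunityState
    presence: tuple[bool, bool, bool, bool]  # (E, S, G, P) strictly positive
    residual: float
    eigenvalues: Optional[np.ndarray] = None
    stability: Optional[str] = None  # "stable" | "unstable" | "marginal"

    @property
    def max_real_eigenvalue(self) -> float:
        if self.eigenvalues is None:
            raise ValueError("stability not yet classified")
        return float(np.max(self.eigenvalues.real))


@dataclass
class SStarReport:
    """Both phages' critical prey-S densities and the exclusion inequality."""

    S_G_star: float
    S_P_star: float
    inequality_holds: bool  # True when S_P* < S_G*: specialist excludes generalist
    E_level: float


def _start_values(
    n_present: int, params: CommunityParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic per-species starting lattices (prey, G, P).

    Phage equilibrium densities scale like (growth surplus)/sigma, so the
    phage lattices include attachment-rate-scaled points: otherwise roots
    drift out of reach when a cost transform shrinks or inflates sigma.
    """
    R = max(params.R, 1.0)
    sigma_G = max(params.sigma_EG, params.sigma_SG, 1e-12)
    sigma_P = max(params.sigma_SP, 1e-12)
    if n_present <= 2:
        prey = np.array([0.02, 0.1, 0.3, 0.6, 0.9]) * R
        scaled = np.array([0.005, 0.02, 0.06, 0.2])
    else:
        prey = np.array([0.05, 0.4, 0.9]) * R
        scaled = np.array([0.02, 0.1])
    base = np.array([0.5, 25.0])
    phage_G = np.unique(np.concatenate([base, scaled / sigma_G]))
    phage_P = np.unique(np.concatenate([base, scaled / sigma_P]))
    return prey, phage_G, phage_P


def enumerate_fixed_points(
    params: CommunityParams,
    residual_tol: float = RESIDUAL_TOL,
    dedup_tol: float = DEDUP_TOL,
    classify: bool = True,
) -> list[FixedPoint]:
    """Enumerate non-negative fixed points across all 16 presence subsets.

    The origin is always included.  Root-finder non-convergence for a
    subset or starting point contributes no root (logged at debug level);
    roots are deduplicated at ``dedup_tol`` in the max norm and filtered
    to residual below ``residual_tol``.
    """
    found: list[np.ndarray] = [np.zeros(4)]
    for mask in itertools.product((False, True), repeat=4):
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        prey_sv, phage_G_sv, phage_P_sv = _start_values(idx.size, params)
        per_species = [
            prey_sv if i < 2 else (phage_G_sv if i == 2 else phage_P_sv) for i in idx
        ]

        def reduced(x: np.ndarray) -> np.ndarray:
            y = np.zeros(4)
            y[idx] = x
            return rhs_array(y, params)[idx]

        for start in itertools.product(*per_species):
            sol = root(reduced, np.asarray(start, dtype=float), method="hybr")
            if not sol.success:
                logger.debug("no root from start %s in subset %s", start, mask)
                continue
            y = np.zeros(4)
            y[idx] = sol.x
            if np.any(y < -1e-9):
                continue
            y = np.clip(y, 0.0, None)
            # components solved in this subset must actually be present;
            # roots that collapsed onto a smaller subset are found there
            if np.abs(rhs_array(y, params)).max() >= residual_tol:
                continue
            if any(np.abs(y - z).max() < dedup_tol for z in found):
                continue
            found.append(y)

    fps = [
        FixedPoint(
            state=CommunityState.from_array(y),
            presence=tuple(bool(v > 0.0) for v in y),
            residual=float(np.abs(rhs_array(y, params)).max()),
        )
        for y in found
    ]
    if classify:
        fps = [classify_stability(fp, params) for fp in fps]
    return fps


def classify_stability(fp: FixedPoint, params: CommunityParams) -> FixedPoint:
    """Fill in Jacobian eigenvalues and the stability label.

    Stable: all eigenvalue real parts below -eps; marginal: some real
    part within +/- eps of zero; otherwise unstable (eps = 1e-7).
    """
    if fp.residual >= RESIDUAL_TOL:
        raise ValueError(f"not a fixed point: residual {fp.residual:.2e} >= {RESIDUAL_TOL}")
    eig = np.linalg.eigvals(jacobian(fp.state.as_array(), params))
    re = eig.real
    if np.all(re < -MARGINAL_EPS):
        label = "stable"
    elif np.any(np.abs(re) <= MARGINAL_EPS):
        label = "marginal"
    else:
        label = "unstable"
    fp.eigenvalues = eig
    fp.stability = label
    return fp


def fixed_points_to_frame(fps: Sequence[FixedPoint]) -> pd.DataFrame:
    rows = []
    for fp in fps:
        s = fp.state
        rows.append(
            {
                "E": s.E,
                "S": s.S,
                "G": s.G,
                "P": s.P,
                "presence": "".join(n for n, p in zip("ESGP", fp.presence) if p) or "none",
                "max_re_eig": fp.max_real_eigenvalue if fp.eigenvalues is not None else np.nan,
                "stability": fp.stability,
                "residual": fp.residual,
            }
        )
    return pd.DataFrame(rows)


def sstar_criterion(params: CommunityParams, E_level: float) -> SStarReport:
    """Evaluate the R*-style exclusion inequality S_P* < S_G*.

    Requires the simplifying symmetry of the analytic reduction: the
    generalist has a single burst size and attachment rate on both prey
    (gamma_EG == gamma_SG, sigma_EG == sigma_SG) and the death/dilution
    rate is common to all four species.  Asymmetric parameter sets are
    rejected.
    """
    if abs(params.gamma_EG - params.gamma_SG) > 1e-12 or abs(params.sigma_EG - params.sigma_SG) > 1e-12:
        raise ValueError(
            "S* criterion requires the generalist to have equal burst size and "
            "attachment rate on both prey (gamma_EG == gamma_SG, sigma_EG == sigma_SG)"
        )
    deltas = (params.delta_E, params.delta_S, params.delta_G, params.delta_P)
    if max(deltas) - min(deltas) > 1e-12:
        raise ValueError("S* criterion requires a common death/dilution rate for all species")
    if E_level < 0:
        raise ValueError("E_level must be non-negative")
    delta = params.delta_G
    qG = params.gamma_SG * params.sigma_SG
    qP = params.gamma_SP * params.sigma_SP
    if qG <= 0 or qP <= 0:
        raise ValueError("phage reproduction products must be positive")
    S_P_star = delta / qP
    S_G_star = delta / qG - E_level
    holds = S_P_star < S_G_star
    # cross-check against the rearranged inequality qG/qP < 1 - qG*E/delta
    holds_ineq = qG / qP < 1.0 - qG * E_level / delta
    assert holds == holds_ineq, "S* comparison and rearranged inequality disagree"
    return SStarReport(S_G_star=S_G_star, S_P_star=S_P_star, inequality_holds=holds, E_level=E_level)


def _only_stable_is_esp(params: CommunityParams) -> bool:
    """True when no stable fixed point contains the generalist and the
    E-S-specialist coexistence point is stable.

    The all-extinct origin is always stable under obligate mutualism
    (Allee structure), so it is disregarded: the indicator concerns the
    non-trivial equilibria reachable from an inoculated community.
    """
    fps = enumerate_fixed_points(params)
    esp_stable = False
    for fp in fps:
        if fp.stability != "stable":
            continue
        if fp.presence[2]:  # generalist present at a stable point
            return False
        if fp.presence == (True, True, False, True):
            esp_stable = True
    return esp_stable


def _density_crossing(params: CommunityParams, t_max: float) -> bool:
    res = run_to_steady_state(params, t_max=t_max)
    if not res.converged:
        logger.info("non-converged run inside bisection; using window average")
    return res.final_state.P > res.final_state.G


def find_cost_threshold(
    mode: Union[InteractionMode, str],
    cost_kind: str,
    criterion: str,
    bracket: tuple[float, float] = (1.0, 6.0),
    xtol: float = 5e-3,
    t_max: float = 2e4,
    base_params: Optional[CommunityParams] = None,
) -> float:
    """Bisect the cost-of-generalism ratio where ``criterion`` flips.

    ``criterion``:

    - ``only_stable_is_ESP``: fixed-point analysis — no stable fixed
      point contains the generalist while the prey-pair + specialist
      point is stable.  Because the cost rescales one factor of the
      specialist's gamma*sigma product, burst and attachment
      parameterizations probe the same product-scale threshold.
    - ``density_crossing``: forward simulation from the standard
      all-species-at-0.1 inoculum — steady-state specialist density
      exceeds the generalist's.

    Raises if the indicator does not change truth value across
    ``bracket``.  Returns the midpoint of the final bracket (width below
    ``xtol``).
    """
    base = base_params if base_params is not None else preset_params(mode)

    if criterion == "only_stable_is_ESP":
        indicator: Callable[[float], bool] = lambda r: _only_stable_is_esp(
            apply_cost(base, cost_kind, r)
        )
    elif criterion == "density_crossing":
        indicator = lambda r: _density_crossing(apply_cost(base, cost_kind, r), t_max)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    lo, hi = float(bracket[0]), float(bracket[1])
    if not (0 < lo < hi):
        raise ValueError("bracket must be positive and increasing")
    f_lo, f_hi = indicator(lo), indicator(hi)
    if f_lo == f_hi:
        raise ValueError(
            f"indicator {criterion!r} is constant ({f_lo}) on bracket [{lo}, {hi}]; "
            "no threshold to locate"
        )
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if indicator(mid) == f_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
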