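"""Core types and dynamics of the two-prey / two-phage community model.

The community holds two bacterial prey species, E and S, that either
compete for a shared resource pool or engage in obligate cross-feeding
mutualism, plus two lytic phage: a generalist G that adsorbs to both prey
and a specialist P restricted to prey S.  All biomasses and rates are
dimensionless; the system is chemostat-like, with a common intrinsic
death/dilution rate for every species by default.

Prey growth is logistic (Lotka-Volterra) with an optional saturating
mutualistic gate: prey i grows at rate

    mu_i * [alpha_ij * x_j / (alpha_ij * x_j + kappa_i)] * (R - x_i - beta_ij * x_j)

so that with ``kappa_i > 0`` and ``beta = 0`` neither prey can grow without
its partner (obligate mutualism), while with ``kappa_i = 0`` the bracket is
identically 1 and the classic competitive Lotka-Volterra form is
recovered.  Phage grow by adsorption (attachment rate ``sigma``) times
burst size (``gamma``) and are lost to dilution.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "InteractionMode",
    "CommunityParams",
    "CommunityState",
    "preset_params",
    "apply_cost",
    "rhs",
    "rhs_array",
    "jacobian",
]


class InteractionMode(str, enum.Enum):
    """Which extreme of prey-prey interaction the preset represents."""

    COMPETITION = "competition"
    MUTUALISM = "mutualism"


# Fig-6-style mortality-cost analyses use a reduced common baseline rate so a
# chemostat mortality penalty on the generalist can be scanned upward from it.
MORTALITY_COST_BASELINE = 0.0067

#: Numerical extinction floor shared across the package (see simulation module).
EXTINCTION_FLOOR = 1e-12


@dataclass(frozen=True)
class CommunityParams:
    """All rate and interaction constants of the community model.

    ``gamma_EP`` and ``sigma_EP`` are stored for completeness of the
    parameter table but are never referenced by the dynamics: the
    specialist phage only reproduces on prey S.
    """

    # prey-prey interaction
    alpha_ES: float = 1.0  # benefit of S on E (mutualism coefficient)
    alpha_SE: float = 1.0  # benefit of E on S
    beta_ES: float = 0.0   # competitive effect of S on E
    beta_SE: float = 0.0   # competitive effect of E on S
    kappa_E: float = 1.0   # half-saturation of the mutualistic benefit to E
    kappa_S: float = 1.0   # half-saturation of the mutualistic benefit to S
    # prey growth
    mu_E: float = 0.5
    mu_S: float = 0.5
    R: float = 1.0         # system carrying capacity
    # phage reproduction
    gamma_EG: float = 20.0  # generalist burst size on E
    gamma_SG: float = 20.0  # generalist burst size on S
    gamma_SP: float = 20.0  # specialist burst size on S
    gamma_EP: float = 20.0  # unused by the dynamics
    sigma_EG: float = 0.001  # generalist attachment rate on E
    sigma_SG: float = 0.001  # generalist attachment rate on S
    sigma_SP: float = 0.001  # specialist attachment rate on S
    sigma_EP: float = 0.001  # unused by the dynamics
    # intrinsic death / dilution
    delta_E: float = 0.03
    delta_S: float = 0.03
    delta_G: float = 0.03
    delta_P: float = 0.03

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v!r}")

    # -- convenience -------------------------------------------------------

    def replace(self, **changes: float) -> "CommunityParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CommunityParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def to_file(self, path: Union[str, Path]) -> None:
        """Write a flat key-value config (.json, .yaml/.yml)."""
        path = Path(path)
        d = self.to_dict()
        if path.suffix == ".json":
            path.write_text(json.dumps(d, indent=2) + "\n")
        elif path.suffix in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(d, sort_keys=True))
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "CommunityParams":
        """Read a flat key-value config (.json, .yaml/.yml, .toml)."""
        path = Path(path)
        if path.suffix == ".json":
            d = json.loads(path.read_text())
        elif path.suffix in (".yaml", ".yml"):
            import yaml

            d = yaml.safe_load(path.read_text())
        elif path.suffix == ".toml":
            import tomllib

            d = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        return cls.from_dict(d)


@dataclass(frozen=True)
class CommunityState:
    """Densities of the four species at one time point (dimensionless biomass)."""

    E: float
    S: float
    G: float
    P: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("E", "S", "G", "P"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"state component {name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.S, self.G, self.P], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray, t: float = 0.0) -> "CommunityState":
        E, S, G, P = (float(v) for v in y)
        return cls(E=E, S=S, G=G, P=P, t=float(t))


def preset_params(mode: Union[InteractionMode, str]) -> CommunityParams:
    """Default parameter set for a pure interaction mode.

    Both modes share mu=0.5, all burst sizes 20, all attachment rates
    0.001, all death rates 0.03 and alpha=1.  Competition: beta=1,
    kappa=0, R=2 (carrying capacity raised so total prey biomass matches
    the mutualistic condition).  Mutualism: beta=0, kappa=1, R=1.
    """
    mode = InteractionMode(mode)
    if mode is InteractionMode.COMPETITION:
        return CommunityParams(beta_ES=1.0, beta_SE=1.0, kappa_E=0.0, kappa_S=0.0, R=2.0)
    return CommunityParams(beta_ES=0.0, beta_SE=0.0, kappa_E=1.0, kappa_S=1.0, R=1.0)


_COST_KINDS = ("burst", "attachment", "mortality")


def apply_cost(
    params: CommunityParams,
    cost_kind: str,
    ratio: float,
) -> CommunityParams:
    """Impose a cost of generalism as a specialist:generalist advantage ratio.

    The cost is absolute with respect to the generalist baseline, so the
    transform is idempotent under re-application with a new ratio:

    - ``burst``:      gamma_SP = ratio * gamma_SG
    - ``attachment``: sigma_SP = ratio * sigma_SG
    - ``mortality``:  delta_E = delta_S = delta_P = 0.0067 and
      delta_G = ratio * 0.0067 (the generalist pays the penalty; the
      other three species keep the common baseline rate).
    """
    if not (ratio > 0 and math.isfinite(ratio)):
        raise ValueError(f"ratio must be a positive finite scalar, got {ratio!r}")
    if cost_kind == "burst":
        return params.replace(gamma_SP=ratio * params.gamma_SG)
    if cost_kind == "attachment":
        return params.replace(sigma_SP=ratio * params.sigma_SG)
    if cost_kind == "mortality":
        b = MORTALITY_COST_BASELINE
        return params.replace(delta_E=b, delta_S=b, delta_P=b, delta_G=ratio * b)
    raise ValueError(f"unknown cost_kind {cost_kind!r}; expected one of {_COST_KINDS}")


def _bracket(partner: float, alpha: float, kappa: float) -> float:
    """Saturating mutualistic gate alpha*x/(alpha*x + kappa).

    Defined as exactly 1 when kappa == 0 (pure competition), including at
    the 0/0 point where the partner biomass is zero.
    """
    if kappa == 0.0:
        return 1.0
    ax = alpha * partner
    return ax / (ax + kappa)


def rhs_array(y: np.ndarray, p: CommunityParams) -> np.ndarray:
    """Time derivative (dE, dS, dG, dP) for a raw state vector.

    No sign checks: intended for use inside integrators, where transient
    tiny negative values can occur.  Use :func:`rhs` for the validated
    public entry point.
    """
    E, S, G, P = y
    bE = _bracket(S, p.alpha_ES, p.kappa_E)
    bS = _bracket(E, p.alpha_SE, p.kappa_S)
    dE = p.mu_E * E * bE * (p.R - E - p.beta_ES * S) - p.sigma_EG * G * E - p.delta_E * E
    dS = (
        p.mu_S * S * bS * (p.R - S - p.beta_SE * E)
        - p.sigma_SP * P * S
        - p.sigma_SG * G * S
        - p.delta_S * S
    )
    dG = p.gamma_SG * p.sigma_SG * G * S + p.gamma_EG * p.sigma_EG * G * E - p.delta_G * G
    dP = p.gamma_SP * p.sigma_SP * P * S - p.delta_P * P
    return np.array([dE, dS, dG, dP])


def rhs(state: CommunityState, params: CommunityParams) -> np.ndarray:
    """Time derivative of the community at ``state`` (validated)."""
    return rhs_array(state.as_array(), params)


def jacobian(y: np.ndarray, p: CommunityParams) -> np.ndarray:
    """Analytic Jacobian of the right-hand side at state vector ``y``.

    The kappa = 0 gate is treated as the constant 1 (zero derivative), so
    the competition preset linearizes exactly as plain Lotka-Volterra.
    """
    E, S, G, P = y
    bE = _bracket(S, p.alpha_ES, p.kappa_E)
    bS = _bracket(E, p.alpha_SE, p.kappa_S)
    # d(bracket)/d(partner): alpha*kappa/(alpha*x+kappa)^2, zero when kappa=0
    if p.kappa_E == 0.0:
        dbE = 0.0
    else:
        dbE = p.alpha_ES * p.kappa_E / (p.alpha_ES * S + p.kappa_E) ** 2
    if p.kappa_S == 0.0:
        dbS = 0.0
    else:
        dbS = p.alpha_SE * p.kappa_S / (p.alpha_SE * E + p.kappa_S) ** 2

    J = np.zeros((4, 4))
    logE = p.R - E - p.beta_ES * S
    logS = p.R - S - p.beta_SE * E
    # dE row
    J[0, 0] = p.mu_E * bE * (logE - E) - p.sigma_EG * G - p.delta_E
    J[0, 1] = p.mu_E * E * (dbE * logE - bE * p.beta_ES)
    J[0, 2] = -p.sigma_EG * E
    # dS row
    J[1, 0] = p.mu_S * S * (dbS * logS - bS * p.beta_SE)
    J[1, 1] = p.mu_S * bS * (logS - S) - p.sigma_SP * P - p.sigma_SG * G - p.delta_S
    J[1, 2] = -p.sigma_SG * S
    J[1, 3] = -p.sigma_SP * S
    # dG row
    J[2, 0] = p.gamma_EG * p.sigma_EG * G
    J[2, 1] = p.gamma_SG * p.sigma_SG * G
    J[2, 2] = p.gamma_SG * p.sigma_SG * S + p.gamma_EG * p.sigma_EG * E - p.delta_G
    # dP row
    J[3, 1] = p.gamma_SP * p.sigma_SP * P
    J[3, 3] = p.gamma_SP * p.sigma_SP * S - p.delta_P
    return J
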