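"""Growth kinetics from metabolic stoichiometry (energy-harvest form).

The specific growth rate on compound i is

    μ_i = μ^max · exp(-|y_OC,i| / (V_h·[OC_i])) · exp(-|y_O2,i| / (V_h·[O2]))

where V_h is the "harvest volume" — the volume a microbe can access to
harvest energy — and the single-limitation forms drop the factor for the
non-limiting substrate. Only the dimensionless products V_h·[OC] and
V_h·[O2] matter, so scenarios are parameterized by them directly
(1 = moderate, 0.2 = severe limitation in the comparative analyses).
Chemical rates are the metabolic coefficients times μ.

Note the exponent carries the coefficient *divided by* the harvest
product: a smaller V_h·[S] (stronger limitation) slows the rate, which is
the only reading consistent with the moderate-vs-severe convention above.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, fsum
from typing import Sequence

import numpy as np

from .formula import MolecularFormula
from .stoichiometry import I_HCO3, I_O2, I_OC
from .thermo import CompoundThermo

C = "C"
O2 = "O2"
C_AND_O2 = "C_and_O2"
_LIMITATIONS = (C, O2, C_AND_O2)


@dataclass(frozen=True)
class KineticParams:
    """The two kinetic parameters: μ^max [1/time] and V_h [volume]."""

    mu_max: float = 1.0
    v_h: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_max <= 0 or self.v_h <= 0:
            raise ValueError("mu_max and v_h must be strictly positive")


@dataclass(frozen=True)
class Scenario:
    """A substrate-limitation scenario over dimensionless V_h·[S] products."""

    limitation: str
    vh_oc: float | None = None
    vh_o2: float | None = None

    def __post_init__(self) -> None:
        if self.limitation not in _LIMITATIONS:
            raise ValueError(f"limitation must be one of {_LIMITATIONS}")
        if self.c_active and not (self.vh_oc and self.vh_oc > 0):
            raise ValueError("vh_oc must be positive for C-limited scenarios")
        if self.o2_active and not (self.vh_o2 and self.vh_o2 > 0):
            raise ValueError("vh_o2 must be positive for O2-limited scenarios")

    @property
    def c_active(self) -> bool:
        return self.limitation in (C, C_AND_O2)

    @property
    def o2_active(self) -> bool:
        return self.limitation in (O2, C_AND_O2)

    @classmethod
    def c_limited(cls, vh_oc: float) -> "Scenario":
        return cls(C, vh_oc=vh_oc)

    @classmethod
    def o2_limited(cls, vh_o2: float) -> "Scenario":
        return cls(O2, vh_o2=vh_o2)

    @classmethod
    def both_limited(cls, vh_oc: float, vh_o2: float) -> "Scenario":
        return cls(C_AND_O2, vh_oc=vh_oc, vh_o2=vh_o2)

    @property
    def key(self) -> str:
        parts = [self.limitation]
        if self.c_active:
            parts.append(f"vhOC={self.vh_oc:g}")
        if self.o2_active:
            parts.append(f"vhO2={self.vh_o2:g}")
        return ",".join(parts)


@dataclass(frozen=True)
class RateSet:
    """Specific rates on one compound: growth plus chemical fluxes.

    All per C-mol biomass per unit time; consumption negative, production
    positive; r_c = a·r_oc converts compound consumption to carbon atoms.
    """

    mu: float
    r_oc: float
    r_c: float
    r_o2: float
    r_hco3: float


def growth_rate(y_met: np.ndarray, p: KineticParams, s: Scenario) -> float:
    """Specific growth rate under the scenario's limitation(s)."""
    mu = p.mu_max
    if s.c_active:
        mu *= exp(-abs(y_met[I_OC]) / s.vh_oc)
    if s.o2_active:
        mu *= exp(-abs(y_met[I_O2]) / s.vh_o2)
    return mu


def rate_set(
    y_met: np.ndarray, f: MolecularFormula, p: KineticParams, s: Scenario
) -> RateSet:
    """Growth rate and the chemical rates it drives (coefficient × μ)."""
    mu = growth_rate(y_met, p, s)
    r_oc = float(y_met[I_OC]) * mu
    return RateSet(
        mu=mu,
        r_oc=r_oc,
        r_c=float(f.c) * r_oc,
        r_o2=float(y_met[I_O2]) * mu,
        r_hco3=float(y_met[I_HCO3]) * mu,
    )


def rates_for_profile(
    profile: CompoundThermo, p: KineticParams, s: Scenario
) -> RateSet:
    """Convenience wrapper; refuses compounds carrying exclusion flags."""
    if profile.excluded:
        raise ValueError(
            f"{profile.formula.label or profile.formula!r} is flagged "
            f"{profile.flags} and excluded from kinetics"
        )
    return rate_set(profile.y_met, profile.formula, p, s)


def cybernetic_weights(kin_rates: Sequence[float]) -> np.ndarray:
    """Resource-allocation weights u_i = μ_i^kin / Σ_j μ_j^kin.

    Weights sum to 1 whenever any rate is positive; an all-zero input
    returns all-zero weights (no activity to allocate). The regulated rate
    of reaction i is u_i·μ_i^kin.
    """
    r = np.asarray(kin_rates, dtype=float)
    if (r < 0).any():
        raise ValueError("kinetic rates must be non-negative")
    total = fsum(r.tolist())
    if total == 0.0:
        return np.zeros_like(r)
    return r / total
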