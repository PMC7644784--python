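"""Per-compound thermodynamics: NOSC → Gibbs energies → λ → metabolic vector.

The chain, per compound:

1. NOSC from the donor half reaction electron count.
2. Per-C-mol oxidation half-reaction energy: ΔG⁰_Cox = 60.3 − 28.5·NOSC
   [kJ/C-mol], an empirical linear relation valid at 25 °C.
3. Donor half-reaction energy ΔG⁰_r,D = a·ΔG⁰_Cox, and from it a formation
   energy ΔG⁰_f for the compound (the only unknown in the half reaction).
4. Catabolic and anabolic reaction energies from formation energies; the
   biological-standard (pH 7) values add R·T·y_H⁺·ln(10⁻⁷).
5. The coupling parameter λ from the thermodynamic electron equivalents
   model (TEEM) energy balance λ·(η·ΔG_cat) + η^m·ΔG_block + ΔG_syn = 0,
   with η = 0.43, ΔG_syn = 200 kJ/C-mol biomass, and ΔG_block ≡ ΔG_ana.
6. Dissipation energy ΔG_dis = λ·(−ΔG_cat) − ΔG_ana and the metabolic
   stoichiometry λ·y_cat + y_an.

Lower λ means fewer catabolic turnovers are needed per C-mol of biomass,
i.e. thermodynamically more favorable growth on that compound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formula import DEFAULT_BIOMASS, BiomassComposition, MolecularFormula
from .formula import electron_equivalents as _ne
from .formula import format_formula, nosc as _nosc
from .stoichiometry import (
    I_E,
    I_H,
    SPECIES,
    anabolic_reaction,
    catabolic_reaction,
    donor_half_reaction,
    metabolic_reaction,
)

#: Standard Gibbs energies of formation [kJ/mol] at 25 °C, 1 bar, for the
#: fixed basis species (OC's value is estimated per compound). H+ and e- are
#: zero by electrochemical convention; Biom is per C-mol.
TABLE_FORMATION_ENERGIES: dict[str, float] = {
    "H2O": -237.2,
    "HCO3-": -586.9,
    "NH4+": -79.5,
    "HPO4-2": -1089.1,
    "HS-": 12.0,
    "H+": 0.0,
    "e-": 0.0,
    "O2": 16.5,
    "Biom": -67.0,
}

LN_1E7 = math.log(1e-7)

# Quality flags. Compounds carrying any flag in EXCLUDE_FLAGS are excluded
# from kinetics and cohort aggregation by default.
FLAG_NOT_OXIDIZABLE = "not_oxidizable"
FLAG_NOSC_RANGE = "nosc_out_of_range"
FLAG_ENDERGONIC = "endergonic_catabolism"
FLAG_NONPOSITIVE_LAMBDA = "nonpositive_lambda"
EXCLUDE_FLAGS = frozenset(
    {FLAG_NOT_OXIDIZABLE, FLAG_ENDERGONIC, FLAG_NONPOSITIVE_LAMBDA}
)


@dataclass(frozen=True)
class ThermoConfig:
    """Thermodynamic constants and conventions.

    temperature in K; gas_constant in kJ/(K·mol); eta is the TEEM energy
    transfer efficiency; dg_syn the building-block→biomass synthesis cost
    in kJ/C-mol biomass; lambda_ph selects which standard state (0 or 7)
    feeds λ and the metabolic vector.
    """

    temperature: float = 298.15
    gas_constant: float = 0.008314
    eta: float = 0.43
    dg_syn: float = 200.0
    lambda_ph: int = 7
    closure: str = "donor"
    biomass: BiomassComposition = field(default=DEFAULT_BIOMASS)
    formation_energies: Mapping[str, float] = field(
        default_factory=lambda: dict(TABLE_FORMATION_ENERGIES)
    )

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0 < self.eta < 1:
            raise ValueError("eta must lie in (0, 1)")
        if self.lambda_ph not in (0, 7):
            raise ValueError("lambda_ph must be 0 or 7")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature


DEFAULT_CONFIG = ThermoConfig()


def delta_g_cox(nosc_value: float) -> float:
    """Per-C-mol standard Gibbs energy of the oxidation half reaction.

    Linear in NOSC: 60.3 − 28.5·NOSC [kJ/C-mol] at 25 °C, 1 bar.
    """
    return 60.3 - 28.5 * nosc_value


def delta_g_donor(
    f: MolecularFormula, cfg: ThermoConfig = DEFAULT_CONFIG, ph: int = 0
) -> float:
    """Donor half-reaction Gibbs energy, ΔG⁰_r,D = a·ΔG⁰_Cox [kJ/mol OC].

    ``ph=7`` adds the biological-standard correction R·T·y_H⁺·ln(10⁻⁷)
    using the half reaction's proton coefficient.
    """
    dg = float(f.c) * delta_g_cox(_nosc(f))
    if ph == 7:
        dg += cfg.rt * donor_half_reaction(f)[I_H] * LN_1E7
    elif ph != 0:
        raise ValueError("ph must be 0 or 7")
    return dg


def estimate_formation_energy(
    f: MolecularFormula, cfg: ThermoConfig = DEFAULT_CONFIG
) -> float:
    """Standard formation energy of the compound [kJ/mol].

    Back-calculated so that the donor half reaction's ΔG⁰, computed from
    formation energies, reproduces a·ΔG⁰_Cox exactly. Group-contribution
    estimates are unavailable because assigned formulae carry no structure.
    """
    y = donor_half_reaction(f)
    rest = sum(
        y[i] * cfg.formation_energies[sp] for i, sp in enumerate(SPECIES) if sp != "OC"
    )
    # y_OC = -1:  ΔG_rD = -ΔG_f,OC + rest  =>  ΔG_f,OC = rest - ΔG_rD
    return rest - delta_g_donor(f, cfg, ph=0)


def reaction_gibbs(
    y: np.ndarray,
    cfg: ThermoConfig = DEFAULT_CONFIG,
    oc_energy: float = 0.0,
    mode: str = "standard",
    activities: Mapping[str, float] | None = None,
) -> float:
    """Gibbs energy of a reaction vector [kJ].

    ``standard``: Σ y_i·ΔG⁰_i at unit activities (pH 0).
    ``biological``: adds R·T·y_H⁺·ln(10⁻⁷) (pH 7, all else unit activity).
    ``explicit``: adds R·T·ln Q over supplied activities; unsupplied
    species default to unit activity and e⁻ never enters the quotient.
    """
    energies = np.array(
        [oc_energy] + [cfg.formation_energies[sp] for sp in SPECIES[1:]]
    )
    dg = float(np.asarray(y) @ energies)
    if mode == "standard":
        return dg
    if mode == "biological":
        return dg + cfg.rt * y[I_H] * LN_1E7
    if mode == "explicit":
        for sp, act in (activities or {}).items():
            if act <= 0:
                raise ValueError(f"activity of {sp} must be positive, got {act}")
            i = SPECIES.index(sp)
            if i == I_E:
                continue  # the electron is not a solution species
            dg += cfg.rt * y[i] * math.log(act)
        return dg
    raise ValueError(f"unknown mode {mode!r}")


def lambda_coupling(
    dg_cat: float, dg_block: float, cfg: ThermoConfig = DEFAULT_CONFIG
) -> tuple[float, int]:
    """TEEM coupling parameter λ and the efficiency exponent m.

    Solves λ·(η·ΔG_cat) + η^m·ΔG_block + ΔG_syn = 0 with m = +1 when the
    carbon-source→building-block step releases energy (ΔG_block ≤ 0) and
    m = −1 when it costs energy. Requires exergonic catabolism; otherwise
    λ is NaN and the compound should be flagged infeasible.
    """
    m = 1 if dg_block <= 0 else -1
    if not dg_cat < 0:
        warnings.warn(
            f"catabolism not exergonic (ΔG_cat = {dg_cat:.3g} kJ/mol); λ undefined",
            stacklevel=2,
        )
        return float("nan"), m
    lam = -((cfg.eta**m) * dg_block + cfg.dg_syn) / (cfg.eta * dg_cat)
    return lam, m


def dissipation_energy(lam: float, dg_cat: float, dg_ana: float) -> float:
    """Energy dissipated per C-mol biomass: ΔG_dis = λ·(−ΔG_cat) − ΔG_ana."""
    return lam * (-dg_cat) - dg_ana


@dataclass(frozen=True)
class CompoundThermo:
    """Full thermodynamic and stoichiometric profile of one compound.

    Energies with suffix 0 are at pH 0 (standard state), suffix 7 at pH 7
    (biological standard). ``lam``, ``m`` and ``dg_dis`` are evaluated at
    the configured ``lambda_ph``. Under ``basis="cmol"`` the donor and
    catabolic energies are per C-mol (divided by the carbon count); λ is
    always computed from per-mol quantities.
    """

    formula: MolecularFormula
    n_e: float
    nosc: float
    dg_cox0: float
    dg_donor0: float
    dg_donor7: float
    dg_f_oc0: float
    dg_cat0: float
    dg_cat7: float
    dg_ana0: float
    dg_ana7: float
    m: int
    lam: float
    dg_dis: float
    y_cat: np.ndarray
    y_an: np.ndarray
    y_met: np.ndarray
    flags: tuple[str, ...] = ()
    basis: str = "mol"

    @property
    def excluded(self) -> bool:
        """True when the compound must not enter kinetics."""
        return bool(EXCLUDE_FLAGS.intersection(self.flags))


def compound_thermo_profile(
    f: MolecularFormula,
    cfg: ThermoConfig = DEFAULT_CONFIG,
    basis: str = "mol",
) -> CompoundThermo:
    """Run the full chain for one compound; degeneracies flag, never raise."""
    if basis not in ("mol", "cmol"):
        raise ValueError("basis must be 'mol' or 'cmol'")
    flags: list[str] = []
    a = float(f.c)
    n_e = float(_ne(f))
    nosc_value = _nosc(f)
    nan10 = np.full(10, np.nan)
    if not -4.0 <= nosc_value <= 4.0:
        flags.append(FLAG_NOSC_RANGE)
    dg_cox0 = delta_g_cox(nosc_value)
    if n_e <= 0:
        flags.append(FLAG_NOT_OXIDIZABLE)
        return CompoundThermo(
            formula=f, n_e=n_e, nosc=nosc_value, dg_cox0=dg_cox0,
            dg_donor0=float("nan"), dg_donor7=float("nan"), dg_f_oc0=float("nan"),
            dg_cat0=float("nan"), dg_cat7=float("nan"), dg_ana0=float("nan"),
            dg_ana7=float("nan"), m=1, lam=float("nan"), dg_dis=float("nan"),
            y_cat=nan10, y_an=nan10, y_met=nan10,
            flags=tuple(flags), basis=basis,
        )

    dg_donor0 = delta_g_donor(f, cfg, ph=0)
    dg_donor7 = delta_g_donor(f, cfg, ph=7)
    dg_f_oc0 = estimate_formation_energy(f, cfg)

    y_cat = catabolic_reaction(f)
    y_an = anabolic_reaction(f, cfg.biomass, closure=cfg.closure)
    dg_cat0 = reaction_gibbs(y_cat, cfg, oc_energy=dg_f_oc0, mode="standard")
    dg_cat7 = reaction_gibbs(y_cat, cfg, oc_energy=dg_f_oc0, mode="biological")
    dg_ana0 = reaction_gibbs(y_an, cfg, oc_energy=dg_f_oc0, mode="standard")
    dg_ana7 = reaction_gibbs(y_an, cfg, oc_energy=dg_f_oc0, mode="biological")

    dg_cat_sel = dg_cat7 if cfg.lambda_ph == 7 else dg_cat0
    dg_ana_sel = dg_ana7 if cfg.lambda_ph == 7 else dg_ana0
    if not dg_cat_sel < 0:
        flags.append(FLAG_ENDERGONIC)
        lam, m = float("nan"), (1 if dg_ana_sel <= 0 else -1)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lam, m = lambda_coupling(dg_cat_sel, dg_ana_sel, cfg)
        if lam <= 0:
            flags.append(FLAG_NONPOSITIVE_LAMBDA)
    dg_dis = dissipation_energy(lam, dg_cat_sel, dg_ana_sel)
    y_met = metabolic_reaction(y_cat, y_an, lam)

    if basis == "cmol":
        dg_donor0, dg_donor7 = dg_donor0 / a, dg_donor7 / a
        dg_cat0, dg_cat7 = dg_cat0 / a, dg_cat7 / a
    return CompoundThermo(
        formula=f, n_e=n_e, nosc=nosc_value, dg_cox0=dg_cox0,
        dg_donor0=dg_donor0, dg_donor7=dg_donor7, dg_f_oc0=dg_f_oc0,
        dg_cat0=dg_cat0, dg_cat7=dg_cat7, dg_ana0=dg_ana0, dg_ana7=dg_ana7,
        m=m, lam=lam, dg_dis=dg_dis,
        y_cat=y_cat, y_an=y_an, y_met=y_met,
        flags=tuple(flags), basis=basis,
    )


def profile_batch(
    formulas: Sequence[MolecularFormula],
    cfg: ThermoConfig = DEFAULT_CONFIG,
    basis: str = "mol",
) -> list[CompoundThermo]:
    """Profile many compounds; a bad row flags itself, never aborts the batch."""
    return [compound_thermo_profile(f, cfg, basis) for f in formulas]


def thermo_frame(profiles: Sequence[CompoundThermo]) -> pd.DataFrame:
    """Tabular view of profiles, one row per compound, stable column order."""
    rows = []
    for p in profiles:
        f = p.formula
        row: dict[str, object] = {
            "label": f.label or format_formula(f),
            "formula": format_formula(f),
            "C": float(f.c), "H": float(f.h), "N": float(f.n),
            "O": float(f.o), "P": float(f.p), "S": float(f.s),
            "charge": f.charge,
            "n_e": p.n_e, "nosc": p.nosc, "dg_cox0": p.dg_cox0,
            "dg_donor0": p.dg_donor0, "dg_donor7": p.dg_donor7,
            "dg_f_oc0": p.dg_f_oc0,
            "dg_cat0": p.dg_cat0, "dg_cat7": p.dg_cat7,
            "dg_ana0": p.dg_ana0, "dg_ana7": p.dg_ana7,
            "m": p.m, "lam": p.lam, "dg_dis": p.dg_dis,
        }
        for i, sp in enumerate(SPECIES):
            row[f"y_met[{sp}]"] = p.y_met[i]
        row["flags"] = ";".join(p.flags)
        rows.append(row)
    return pd.DataFrame(rows)
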