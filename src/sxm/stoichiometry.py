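"""Balanced half reactions and catabolic/anabolic/metabolic stoichiometry.

All reactions live on a fixed, ordered basis of 10 chemical species that
participate in aerobic oxidative degradation of organic carbon (OC):

    OC, H2O, HCO3-, NH4+, HPO4-2, HS-, H+, e-, O2, Biom

A reaction is a length-10 coefficient vector (negative = consumed,
positive = produced). Every constructor here returns vectors that balance
in all six elements and charge; `balance_residual` exposes the check.

Construction paths
------------------
* donor half reaction: complete oxidation of 1 mol OC to HCO3-, releasing
  n_e electrons (closed-form coefficients in the compound's element counts).
* acceptor half reaction: the O2/H2O couple, 4 electrons per O2.
* catabolic = donor + (n_e/4) · acceptor  (electrons cancel).
* anabolic: 1 C-mol biomass formed from the carbon source with NH4+ as the
  nitrogen source; electron closure by scaling the carbon-source donor half
  reaction (default) or, alternatively, by the O2 couple.
* metabolic = λ · catabolic + anabolic.
"""

from __future__ import annotations

import numpy as np

from .formula import (
    DEFAULT_BIOMASS,
    BiomassComposition,
    MolecularFormula,
    electron_equivalents,
)

#: Fixed species order; indices are stable across the whole package.
SPECIES = ("OC", "H2O", "HCO3-", "NH4+", "HPO4-2", "HS-", "H+", "e-", "O2", "Biom")

(I_OC, I_H2O, I_HCO3, I_NH4, I_HPO4, I_HS, I_H, I_E, I_O2, I_BIOM) = range(10)

#: Axes of the element/charge balance, in order.
BALANCE_AXES = ("C", "H", "N", "O", "P", "S", "charge")

# Composition rows (C, H, N, O, P, S, charge) for the fixed species.
_FIXED_COMPOSITION = {
    I_H2O: (0, 2, 0, 1, 0, 0, 0),
    I_HCO3: (1, 1, 0, 3, 0, 0, -1),
    I_NH4: (0, 4, 1, 0, 0, 0, 1),
    I_HPO4: (0, 1, 0, 4, 1, 0, -2),
    I_HS: (0, 1, 0, 0, 0, 1, -1),
    I_H: (0, 1, 0, 0, 0, 0, 1),
    I_E: (0, 0, 0, 0, 0, 0, -1),
    I_O2: (0, 0, 0, 2, 0, 0, 0),
}


def _composition_row(f: MolecularFormula) -> tuple[float, ...]:
    return tuple(float(v) for v in f.counts()) + (float(f.charge),)


def composition_matrix(
    f: MolecularFormula, biom: BiomassComposition = DEFAULT_BIOMASS
) -> np.ndarray:
    """10 x 7 matrix of species compositions over (C,H,N,O,P,S,charge)."""
    m = np.zeros((10, 7))
    m[I_OC] = _composition_row(f)
    m[I_BIOM] = _composition_row(biom.formula)
    for i, row in _FIXED_COMPOSITION.items():
        m[i] = row
    return m


def _oxidation_half(f: MolecularFormula, slot: int) -> np.ndarray:
    """Complete-oxidation half reaction of 1 mol of `f` placed at `slot`."""
    a, b, c, d, e, s = (float(v) for v in f.counts())
    z = float(f.charge)
    y = np.zeros(10)
    y[slot] = -1.0
    y[I_H2O] = -(3 * a + 4 * e - d)
    y[I_HCO3] = a
    y[I_NH4] = c
    y[I_HPO4] = e
    y[I_HS] = s
    y[I_H] = 5 * a + b - 4 * c - 2 * d + 7 * e - s
    y[I_E] = -z + 4 * a + b - 3 * c - 2 * d + 5 * e - 2 * s
    return y


def donor_half_reaction(f: MolecularFormula) -> np.ndarray:
    """Electron-donor half reaction: 1 mol OC oxidized to HCO3-.

    The e- coefficient equals `electron_equivalents(f)` by construction.
    """
    y = _oxidation_half(f, I_OC)
    assert np.max(np.abs(balance_residual(y, f))) < 1e-9, "donor half unbalanced"
    return y


def biomass_half_reaction(biom: BiomassComposition = DEFAULT_BIOMASS) -> np.ndarray:
    """Oxidation half reaction of 1 C-mol biomass (4.2 e- for the default)."""
    return _oxidation_half(biom.formula, I_BIOM)


def acceptor_half_reaction() -> np.ndarray:
    """Terminal electron acceptor couple: O2 + 4 H+ + 4 e- -> 2 H2O."""
    y = np.zeros(10)
    y[I_O2] = -1.0
    y[I_H] = -4.0
    y[I_E] = -4.0
    y[I_H2O] = 2.0
    return y


def catabolic_reaction(f: MolecularFormula) -> np.ndarray:
    """Full aerobic oxidation of 1 mol OC: donor + (n_e/4) · acceptor.

    Electrons cancel exactly; the O2 coefficient is -n_e/4.
    """
    n_e = float(electron_equivalents(f))
    y = donor_half_reaction(f) + (n_e / 4.0) * acceptor_half_reaction()
    y[I_E] = 0.0  # exact by construction; clear rounding dust
    return y


def anabolic_reaction(
    f: MolecularFormula,
    biom: BiomassComposition = DEFAULT_BIOMASS,
    closure: str = "donor",
) -> np.ndarray:
    """Biomass synthesis from the carbon source, per 1 C-mol biomass.

    NH4+ is the nitrogen source. Residual electrons between the carbon
    source (n_e/a per C-mol) and biomass (4.2 per C-mol) are closed either
    by scaling the carbon-source donor half reaction (``closure="donor"``,
    the default: the anabolic reaction stays acceptor-free, consuming
    x = n_B/(n_e/a) C-mol of substrate carbon) or by the O2 couple
    (``closure="acceptor"``: exactly 1 C-mol substrate carbon, O2 appears).
    The choice is isolated here; both yield balanced vectors.
    """
    n_e = float(electron_equivalents(f))
    if n_e <= 0:
        raise ValueError(
            f"{f.label or f!r}: n_e = {n_e} <= 0; not oxidizable in this framework"
        )
    a = float(f.c)
    y_d = _oxidation_half(f, I_OC)
    y_b = biomass_half_reaction(biom)
    n_b = y_b[I_E]
    if closure == "donor":
        x = n_b / (n_e / a)  # C-mol substrate carbon per C-mol biomass
        y = (x / a) * y_d - y_b
    elif closure == "acceptor":
        r = (n_e / a - n_b) / 4.0
        y = (1.0 / a) * y_d - y_b + r * acceptor_half_reaction()
    else:
        raise ValueError(f"unknown electron closure {closure!r}")
    y[I_E] = 0.0
    if not np.isfinite(y).all():
        raise ValueError(f"{f.label or f!r}: non-finite anabolic stoichiometry")
    return y


def metabolic_reaction(y_cat: np.ndarray, y_an: np.ndarray, lam: float) -> np.ndarray:
    """Energy-coupled metabolic reaction: λ · catabolic + anabolic.

    λ is the number of catabolic turnovers needed to pay for synthesizing
    one C-mol of biomass; the resulting vector keeps y_Biom = 1.
    """
    return lam * y_cat + y_an


def balance_residual(
    y: np.ndarray,
    f: MolecularFormula,
    biom: BiomassComposition = DEFAULT_BIOMASS,
) -> np.ndarray:
    """Element/charge residual over (C,H,N,O,P,S,charge); zero iff balanced."""
    return np.asarray(y) @ composition_matrix(f, biom)
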