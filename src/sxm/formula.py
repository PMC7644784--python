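"""Molecular formulae and carbon electron bookkeeping.

A compound entering the pipeline is described purely by its elemental
composition over CHNOPS plus a net charge, matching the information content
of an FTICR-MS assigned-formula report (no structures, no isotopes).

Two quantities drive everything downstream:

* ``n_e`` — the number of electrons transferred when the compound is fully
  oxidized to bicarbonate in its electron-donor half reaction,
  ``n_e = -z + 4a + b - 3c - 2d + 5e - 2f`` for C_a H_b N_c O_d P_e S_f
  with net charge z.
* NOSC — the nominal oxidation state of carbon, ``NOSC = 4 - n_e / a``.
  More negative NOSC means more reduced carbon and more energy released
  per C-mol on oxidation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Union

Count = Union[int, Fraction]

#: Elements accepted in a formula, in canonical output order.
ELEMENTS = ("C", "H", "N", "O", "P", "S")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+(?:\.\d+)?)?")


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed or validated."""


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition of one organic compound.

    Counts are non-negative and integral for ordinary compounds; fractional
    counts (as exact :class:`~fractions.Fraction`) are reserved for
    biomass-style average compositions such as CH1.8N0.2O0.5.
    """

    c: Count
    h: Count
    n: Count = 0
    o: Count = 0
    p: Count = 0
    s: Count = 0
    charge: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        for sym, v in zip(ELEMENTS, self.counts()):
            if v < 0:
                raise FormulaError(f"negative {sym} count in {self.label or self!r}")
        if self.c < 1:
            raise FormulaError(f"no carbon: {self.label or format_formula(self, validate=False)!r}")

    def counts(self) -> tuple[Count, ...]:
        return (self.c, self.h, self.n, self.o, self.p, self.s)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return format_formula(self)


def parse_formula(
    text: str,
    charge: int = 0,
    *,
    fractional: bool = False,
    label: str | None = None,
) -> MolecularFormula:
    """Parse a Hill-style CHNOPS formula string like ``"C6H12O6"``.

    Single-letter element tokens only, each followed by an optional count
    (default 1). Decimal counts are rejected unless ``fractional=True``
    (biomass-style compositions). Elements outside CHNOPS raise rather than
    being silently dropped, since dropping atoms corrupts every downstream
    balance.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, Count] = {}
    pos = 0
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"unparseable token {text[pos:m.start()]!r} in {text!r}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        if num is None:
            val: Count = 1
        elif "." in num:
            if not fractional:
                raise FormulaError(
                    f"fractional count {num!r} in {text!r}; only biomass-style "
                    "compositions may use fractional counts (pass fractional=True)"
                )
            val = Fraction(num)
        else:
            val = int(num)
        counts[sym] = counts.get(sym, 0) + val
    if pos != len(text):
        raise FormulaError(f"unparseable token {text[pos:]!r} in {text!r}")
    return MolecularFormula(
        c=counts.get("C", 0),
        h=counts.get("H", 0),
        n=counts.get("N", 0),
        o=counts.get("O", 0),
        p=counts.get("P", 0),
        s=counts.get("S", 0),
        charge=charge,
        label=label if label is not None else text,
    )


def _fmt_count(v: Count) -> str:
    if v == int(v):
        return "" if int(v) == 1 else str(int(v))
    return f"{float(v):g}"


def format_formula(f: MolecularFormula, *, validate: bool = True) -> str:
    """Canonical string form: elements in C,H,N,O,P,S order, 1s omitted."""
    parts = []
    for sym, v in zip(ELEMENTS, f.counts()):
        if v == 0:
            continue
        parts.append(sym + _fmt_count(v))
    return "".join(parts)


def electron_equivalents(f: MolecularFormula) -> Count:
    """Electrons transferred in the complete oxidation half reaction.

    Exact (integer or Fraction) so that stoichiometric balances built on it
    close identically. Non-positive values mean the compound cannot serve
    as an electron donor in this framework; callers flag rather than crash.
    """
    return -f.charge + 4 * f.c + f.h - 3 * f.n - 2 * f.o + 5 * f.p - 2 * f.s


def nosc(f: MolecularFormula) -> float:
    """Nominal oxidation state of carbon, ``4 - n_e / a``.

    Chemically meaningful values lie in [-4, +4]; callers attach a quality
    warning outside that range.
    """
    return float(4 - Fraction(electron_equivalents(f)) / Fraction(f.c))


#: Standard average biomass composition CH1.8N0.2O0.5 (exact rationals so
#: that reaction balances involving biomass close to machine precision).
DEFAULT_BIOMASS_FORMULA = MolecularFormula(
    c=1,
    h=Fraction(9, 5),
    n=Fraction(1, 5),
    o=Fraction(1, 2),
    charge=0,
    label="Biom",
)


@dataclass(frozen=True)
class BiomassComposition:
    """Average biomass building-block composition and its formation energy.

    The default CH1.8N0.2O0.5 with ΔG_f = -67 kJ/C-mol is the widely used
    literature convention; its electron equivalents per C-mol are
    4·1 + 1.8 - 3·0.2 - 2·0.5 = 4.2.
    """

    formula: MolecularFormula = field(default=DEFAULT_BIOMASS_FORMULA)
    formation_energy: float = -67.0  # kJ per C-mol

    @property
    def electron_equivalents(self) -> Count:
        return electron_equivalents(self.formula)


DEFAULT_BIOMASS = BiomassComposition()
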