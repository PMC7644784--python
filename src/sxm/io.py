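"""Readers and writers for formula tables and derived reports.

Input tables are CSV (TSV auto-detected by extension) with a header, UTF-8,
"." decimal separator, and exactly one of two dialects:

* a ``formula`` column holding strings like ``C6H12O6``; or
* element-count columns named C, H, N, O, S, P (case-insensitive; N, O, S,
  P optional, defaulting to 0) with an optional ``charge`` column.

Having both (or neither) resolvable is a configuration error, never a
guess. Unparseable rows are collected into a rejects report with their
line numbers instead of being silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .formula import FormulaError, MolecularFormula, parse_formula
from .thermo import CompoundThermo, thermo_frame


class TableDialectError(ValueError):
    """The table's formula dialect cannot be resolved unambiguously."""


@dataclass
class FormulaTable:
    """Parsed formula table plus row-level metadata and rejects."""

    formulas: list[MolecularFormula]
    meta: pd.DataFrame   # passthrough columns aligned with `formulas`
    rejects: pd.DataFrame  # columns: line, reason


def _read_raw(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if df.empty:
        raise TableDialectError(f"{path}: empty table")
    return df


def read_formula_table(path: str | Path) -> FormulaTable:
    """Read and parse a formula table, resolving its dialect from the header."""
    df = _read_raw(path)
    cols = {c.lower().strip(): c for c in df.columns}
    has_formula = "formula" in cols
    has_counts = "c" in cols and "h" in cols
    if has_formula and has_counts:
        raise TableDialectError(
            f"{path}: both a 'formula' column and element-count columns are "
            "present; the dialect is ambiguous"
        )
    if not has_formula and not has_counts:
        raise TableDialectError(
            f"{path}: need either a 'formula' column or element-count "
            "columns C,H(,N,O,S,P)"
        )
    charge_col = cols.get("charge")
    label_col = cols.get("label") or cols.get("id")
    formulas: list[MolecularFormula] = []
    kept_rows: list[int] = []
    rejects: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header
        charge = int(row[charge_col]) if charge_col and pd.notna(row[charge_col]) else 0
        label = str(row[label_col]) if label_col and pd.notna(row[label_col]) else ""
        try:
            if has_formula:
                f = parse_formula(str(row[cols["formula"]]), charge=charge, label=label or None)
            else:
                f = MolecularFormula(
                    c=int(row[cols["c"]]),
                    h=int(row[cols["h"]]),
                    n=int(row[cols["n"]]) if "n" in cols and pd.notna(row[cols["n"]]) else 0,
                    o=int(row[cols["o"]]) if "o" in cols and pd.notna(row[cols["o"]]) else 0,
                    p=int(row[cols["p"]]) if "p" in cols and pd.notna(row[cols["p"]]) else 0,
                    s=int(row[cols["s"]]) if "s" in cols and pd.notna(row[cols["s"]]) else 0,
                    charge=charge,
                    label=label,
                )
        except (FormulaError, ValueError) as exc:
            rejects.append((line, str(exc)))
            continue
        formulas.append(f)
        kept_rows.append(i)
    meta = df.loc[kept_rows].reset_index(drop=True)
    return FormulaTable(
        formulas=formulas,
        meta=meta,
        rejects=pd.DataFrame(rejects, columns=["line", "reason"]),
    )


def write_thermo_table(
    profiles: Sequence[CompoundThermo], path: str | Path
) -> pd.DataFrame:
    """Write one row per compound (stable column order, 6 significant digits)."""
    if not profiles:
        raise ValueError("no profiles to write")
    df = thermo_frame(profiles)
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def read_thermo_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
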