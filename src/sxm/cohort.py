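"""Per-sample aggregation and cohort-level correlation / zone comparison.

A sample is a set of detected compounds (treated as presence/absence —
FTICR intensities carry no concentration information, so the analyses work
on the normalized distribution of the OM pool) plus an optional measured
respiration proxy. Aggregates of the thermodynamic parameters (λ, donor
and catabolic energies) and of predicted rates under chosen limitation
scenarios are correlated with respiration across samples (Pearson), and
two samples can be compared zone-style (distributions plus rate ratios).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import KineticParams, Scenario, rate_set
from .thermo import CompoundThermo


@dataclass
class SampleProfile:
    """One sample: its compound profiles and optional measurements."""

    sample_id: str
    profiles: Sequence[CompoundThermo]
    respiration: float | None = None
    zone: str | None = None

    @property
    def usable(self) -> list[CompoundThermo]:
        return [p for p in self.profiles if not p.excluded]


# Aggregated thermodynamic columns and the per-scenario rate columns.
_THERMO_COLS = ("lam", "dg_donor0", "dg_donor7", "dg_cat0", "dg_cat7")
_RATE_COLS = ("mu", "abs_r_c", "abs_r_o2", "r_hco3")


def aggregate_sample(
    p: SampleProfile,
    stat: str = "mean",
    basis: str = "mol",
    scenarios: Sequence[Scenario] = (),
    params: KineticParams | None = None,
    intensities: Sequence[float] | None = None,
) -> dict[str, float]:
    """Aggregate thermodynamics and predicted rates over a sample's compounds.

    Flagged compounds are excluded (their count is reported). ``basis``
    "cmol" divides each compound's donor/catabolic energies by its own
    carbon count before aggregating. Rates use μ^max = 1 by default since
    only relative comparisons across samples matter.

    Detected compounds are weighted equally by default (peak intensities
    are not quantitative); pass ``intensities`` (one non-negative value per
    profile, flagged rows ignored) for an intensity-weighted mean instead.
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    usable = p.usable
    if not usable:
        raise ValueError(f"sample {p.sample_id!r} has no usable compounds")
    params = params or KineticParams()
    if intensities is None:
        agg = np.mean if stat == "mean" else np.median
    else:
        if stat != "mean":
            raise ValueError("intensity weighting is only defined for stat='mean'")
        if len(intensities) != len(p.profiles):
            raise ValueError("need one intensity per profile")
        w = np.array(
            [wi for wi, q in zip(intensities, p.profiles) if not q.excluded],
            dtype=float,
        )
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("intensities must be non-negative with a positive sum")

        def agg(vals):  # noqa: ANN001 - local closure
            return np.average(vals, weights=w)

    out: dict[str, float] = {
        "sample_id": p.sample_id,  # type: ignore[dict-item]
        "n_compounds": len(p.profiles),
        "n_excluded": len(p.profiles) - len(usable),
    }
    for col in _THERMO_COLS:
        vals = np.array([getattr(q, col) for q in usable], dtype=float)
        if basis == "cmol" and col.startswith("dg_"):
            vals = vals / np.array([float(q.formula.c) for q in usable])
        out[f"{stat}_{col}"] = float(agg(vals))
    for scen in scenarios:
        rates = [rate_set(q.y_met, q.formula, params, scen) for q in usable]
        series = {
            "mu": [r.mu for r in rates],
            "abs_r_c": [abs(r.r_c) for r in rates],
            "abs_r_o2": [abs(r.r_o2) for r in rates],
            "r_hco3": [r.r_hco3 for r in rates],
        }
        for name in _RATE_COLS:
            out[f"{stat}_{name}[{scen.key}]"] = float(agg(series[name]))
    return out


def aggregate_cohort(
    samples: Iterable[SampleProfile],
    stat: str = "mean",
    basis: str = "mol",
    scenarios: Sequence[Scenario] = (),
    params: KineticParams | None = None,
) -> pd.DataFrame:
    """One aggregate row per sample."""
    return pd.DataFrame(
        [aggregate_sample(s, stat, basis, scenarios, params) for s in samples]
    )


def correlate(
    summaries: pd.DataFrame,
    respiration: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Pearson ρ of each aggregate column with measured respiration.

    Requires ≥ 3 samples present in both inputs. Zero-variance columns (or
    constant respiration) yield a missing ρ with a warning rather than a
    spurious number. Returns a table with columns: column, rho, n.
    """
    resp = pd.Series(respiration, dtype=float)
    df = summaries.set_index("sample_id")
    common = df.index.intersection(resp.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 samples with both aggregate and respiration, got {len(common)}")
    df = df.loc[common]
    r = resp.loc[common].to_numpy()
    rows = []
    numeric = [
        c for c in df.columns
        if c not in ("n_compounds", "n_excluded") and pd.api.types.is_numeric_dtype(df[c])
    ]
    r_const = np.ptp(r) == 0
    for col in numeric:
        v = df[col].to_numpy(dtype=float)
        if r_const or np.ptp(v) == 0:
            warnings.warn(f"zero variance: Pearson rho undefined for {col!r}", stacklevel=2)
            rho = float("nan")
        else:
            rho = float(stats.pearsonr(v, r).statistic)
        rows.append((col, rho, len(common)))
    return pd.DataFrame(rows, columns=["column", "rho", "n"])


def _distribution(values: np.ndarray, bins: int = 20) -> dict:
    qs = np.percentile(values, [0, 25, 50, 75, 100])
    counts, edges = np.histogram(values, bins=bins)
    return {
        "min": float(qs[0]), "q1": float(qs[1]), "median": float(qs[2]),
        "q3": float(qs[3]), "max": float(qs[4]), "n": int(values.size),
        "hist_counts": counts.tolist(), "hist_edges": edges.tolist(),
    }


def zone_compare(
    sample_a: SampleProfile,
    sample_b: SampleProfile,
    scenarios: Sequence[Scenario] | None = None,
    levels: Mapping[str, float] | None = None,
    stat: str = "mean",
    params: KineticParams | None = None,
) -> dict:
    """Compare two samples the way high- vs low-activity zones are compared.

    Returns distribution summaries (quartiles + histograms) of λ, ΔG_cat,
    ΔG_donor and of |r_O2| per scenario, plus a/b ratios of the aggregate
    μ, |r_C|, |r_O2| and r_HCO3 per limitation type and level (default
    levels: moderate V_h[S] = 1, severe V_h[S] = 0.2).
    """
    levels = dict(levels or {"moderate": 1.0, "severe": 0.2})
    params = params or KineticParams()
    report: dict = {"sample_a": sample_a.sample_id, "sample_b": sample_b.sample_id}

    dists: dict = {}
    for name, attr in (("lam", "lam"), ("dg_cat7", "dg_cat7"), ("dg_donor7", "dg_donor7")):
        for tag, sample in (("a", sample_a), ("b", sample_b)):
            vals = np.array([getattr(q, attr) for q in sample.usable])
            dists[f"{name}[{tag}]"] = _distribution(vals)

    if scenarios is None:
        scenarios = []
        for level_name, vh in levels.items():
            scenarios += [
                Scenario.c_limited(vh),
                Scenario.o2_limited(vh),
                Scenario.both_limited(vh, vh),
            ]
    ratios: dict[str, dict[str, float]] = {}
    for scen in scenarios:
        for tag, sample in (("a", sample_a), ("b", sample_b)):
            r_o2 = np.array(
                [abs(rate_set(q.y_met, q.formula, params, scen).r_o2) for q in sample.usable]
            )
            dists[f"abs_r_o2[{scen.key}][{tag}]"] = _distribution(r_o2)
        agg_a = aggregate_sample(sample_a, stat, scenarios=[scen], params=params)
        agg_b = aggregate_sample(sample_b, stat, scenarios=[scen], params=params)
        ratios[scen.key] = {
            name: agg_a[f"{stat}_{name}[{scen.key}]"] / agg_b[f"{stat}_{name}[{scen.key}]"]
            for name in _RATE_COLS
        }
    report["distributions"] = dists
    report["ratios"] = ratios
    return report
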