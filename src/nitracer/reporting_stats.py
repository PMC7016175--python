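"""Derived statistics and report-table assembly.

Effect sizes (percent change under the inhibitor treatment), ratio
factors between soils, fumigation-extraction biomass arithmetic,
Benjamini-Hochberg adjustment, and the three standard report tables
(gross rates, soil pools, cumulative emissions).

Report values are rounded half-up to integer percent/factor for
presentation; unrounded values are always retained in machine output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .tracing_model import RateTable, TRANSFORM_NAMES, round_half_up

__all__ = [
    "EffectReport", "BiomassMeasurement", "percent_change", "ratio_factor",
    "biomass_from_fumigation", "bh_adjust", "build_tables",
]


@dataclass
class EffectReport:
    """Treatment effect on one reported variable."""

    variable: str
    control_mean: float
    control_se: float
    treatment_mean: float
    treatment_se: float
    percent_change: Optional[float]
    significance: str = ""

    @property
    def percent_change_rounded(self) -> Optional[int]:
        if self.percent_change is None:
            return None
        return round_half_up(self.percent_change)


@dataclass
class BiomassMeasurement:
    """Fumigated / non-fumigated extract totals, ug per g soil."""

    fumigated_c: float
    nonfumigated_c: float
    fumigated_n: float
    nonfumigated_n: float


def percent_change(control: float, treatment: float) -> float:
    """Percent change of ``treatment`` relative to ``control``.

    Raises on a zero control (the effect is undefined there).
    """
    if control == 0:
        raise ValueError("percent change undefined for zero control")
    return 100.0 * (treatment - control) / control


def ratio_factor(numerator: float, denominator: float) -> float:
    """Plain ratio, e.g. 'exceeds X by a factor of N'."""
    if denominator <= 0:
        raise ValueError("ratio factor requires a positive denominator")
    return numerator / denominator


def biomass_from_fumigation(m: BiomassMeasurement
                            ) -> Tuple[float, float, float, List[str]]:
    """(C_mic, N_mic, DOC) from chloroform fumigation-extraction.

    Plain fumigated-minus-non-fumigated differences with no extraction-
    efficiency correction factor; DOC is the total C of the
    non-fumigated extract.  Negative differences are retained but
    flagged.
    """
    c_mic = m.fumigated_c - m.nonfumigated_c
    n_mic = m.fumigated_n - m.nonfumigated_n
    doc = m.nonfumigated_c
    flags = []
    if c_mic < 0:
        flags.append("negative C_mic")
    if n_mic < 0:
        flags.append("negative N_mic")
    return c_mic, n_mic, doc, flags


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard FDR control: sorted p_(i) * m / i with cumulative-minimum
    enforcement; adjusted values never fall below the raw ones and are
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rate_row(name: str, control: RateTable, treatment: RateTable,
              ci_control: Optional[Tuple[float, float]] = None,
              ci_treatment: Optional[Tuple[float, float]] = None) -> dict:
    from .inference import ci_overlap_test

    def get(t: RateTable, n: str) -> float:
        if n == "M_tot":
            return t.m_tot
        if n == "Nit_tot":
            return t.nit_tot
        if n == "I_NH4tot":
            return t.i_nh4tot
        return t.rates[n]

    c, t = get(control, name), get(treatment, name)
    row = {"transformation": name, "control": c, "treatment": t}
    row["dmpp_effect_pct"] = percent_change(c, t) if c != 0 else np.nan
    row["dmpp_effect_pct_rounded"] = (round_half_up(row["dmpp_effect_pct"])
                                      if np.isfinite(row["dmpp_effect_pct"])
                                      else np.nan)
    if ci_control is not None and ci_treatment is not None:
        row["significance"] = ci_overlap_test(ci_control, ci_treatment)
    return row


def build_tables(rate_tables: Dict[str, RateTable],
                 emissions: Optional[pd.DataFrame] = None,
                 pool_effects: Optional[Sequence[EffectReport]] = None,
                 rate_intervals: Optional[Dict[str, Dict[str, Tuple[float, float]]]] = None,
                 ) -> Dict[str, pd.DataFrame]:
    """Assemble the report bundle.

    ``rate_tables`` maps "soil/treatment" keys (treatment in
    {fertilizer, dmpp}) to completed RateTables.  Returns a dict of
    DataFrames: ``rates`` (per-soil gross rates with inhibitor effect),
    ``pools`` (effect reports), ``emissions`` (pass-through of the
    per-treatment emission summary with product ratios).
    """
    derived = ["M_tot", "Nit_tot", "I_NH4tot"]
    rate_rows = []
    soils = sorted({k.split("/")[0] for k in rate_tables})
    for soil in soils:
        ctrl_key, trt_key = f"{soil}/fertilizer", f"{soil}/dmpp"
        if ctrl_key not in rate_tables:
            raise ValueError(f"missing rate table for {ctrl_key}")
        control = rate_tables[ctrl_key]
        treatment = rate_tables.get(trt_key)
        for name in list(TRANSFORM_NAMES) + derived:
            if treatment is None:
                row = {"transformation": name,
                       "control": control.rates.get(name)}
            else:
                ci_c = ci_t = None
                if rate_intervals:
                    ci_c = rate_intervals.get(ctrl_key, {}).get(name)
                    ci_t = rate_intervals.get(trt_key, {}).get(name)
                row = _rate_row(name, control, treatment, ci_c, ci_t)
            row["soil"] = soil
            rate_rows.append(row)
        for label, val_c, val_t in (
                ("contrib_M_Nlab_pct", control.contrib_m_nlab_pct,
                 treatment.contrib_m_nlab_pct if treatment else None),
                ("contrib_O_NH4_pct", control.contrib_o_nh4_pct,
                 treatment.contrib_o_nh4_pct if treatment else None)):
            rate_rows.append({
                "soil": soil, "transformation": label,
                "control": (round_half_up(val_c) if val_c is not None
                            else np.nan),
                "treatment": (round_half_up(val_t) if val_t is not None
                              else np.nan),
            })
    tables = {"rates": pd.DataFrame(rate_rows)}
    if pool_effects is not None:
        tables["pools"] = pd.DataFrame([{
            "variable": e.variable, "control_mean": e.control_mean,
            "control_se": e.control_se, "treatment_mean": e.treatment_mean,
            "treatment_se": e.treatment_se,
            "effect_pct": e.percent_change,
            "effect_pct_rounded": e.percent_change_rounded,
            "significance": e.significance,
        } for e in pool_effects])
    else:
        tables["pools"] = pd.DataFrame(
            columns=["variable", "control_mean", "control_se",
                     "treatment_mean", "treatment_se", "effect_pct",
                     "effect_pct_rounded", "significance"])
    if emissions is not None:
        em = emissions.copy()
        if "product_ratio_pct" in em.columns:
            em["product_ratio_pct_rounded"] = [
                round_half_up(v) if pd.notna(v) else np.nan
                for v in em["product_ratio_pct"]]
        tables["emissions"] = em
    else:
        tables["emissions"] = pd.DataFrame(
            columns=["soil", "treatment", "n2_ug_n_g", "n2o_total_ug_n_g",
                     "n2o_d_ug_n_g", "n2o_n_ug_n_g",
                     "denitrification_ug_n_g", "product_ratio_pct"])
    return tables
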