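"""The 15N gas-flux method for N2 and N2O source partitioning.

After fertilization with NO3- highly enriched in 15N, N2 (and N2O)
formed by denitrification carries the enrichment of the denitrifying
NO3- pool, while the large atmospheric N2 background does not.  Random
isotope pairing makes the pool-derived gas binomial in the pool's atom
fraction ``a_p``: molecular fractions of mass 28/29/30 are
(1-a_p)^2, 2 a_p (1-a_p), a_p^2.  A headspace sample is then a
two-source mixture of pool-derived gas (fraction ``f_p``) and
background gas (atom fraction ``a_bgd``), and the measured ion-current
ratios 29R = 29N2/28N2 and 30R = 30N2/28N2 determine both unknowns:
solving

    (x30 - b30) / (x29 - b29) = (a_p^2 - a_b^2) /
                                (2 a_p (1-a_p) - 2 a_b (1-a_b))

for ``a_p`` (the admissible quadratic root) and then
``f_p = (x30 - b30) / (a_p^2 - a_b^2)``.

The same two-source logic is applied to the N2O isotopologue ratios
((m+1)/m and (m+2)/m relative to 14N14N16O), giving the fraction of
headspace N2O derived from the denitrifying pool; N2O from
nitrification-mediated pathways is obtained by difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ATMOSPHERIC_N15", "N2_MOLE_FRACTION_AIR", "GAS_CONSTANT",
    "IsotopologueSample", "PartitionResult", "MicrocosmGeometry",
    "PartitionedEmissions", "IRMSPrecision",
    "isotopologue_forward", "invert_ap_fp", "concentration_to_mass",
    "flux_from_timeseries", "partition_n2o", "cumulative_emissions",
    "product_ratio", "detection_limit", "hybrid_consistency_check",
    "process_gas_records",
]

#: atmospheric 15N atom fraction (natural abundance)
ATMOSPHERIC_N15 = 0.003663
#: mole fraction of N2 in dry air
N2_MOLE_FRACTION_AIR = 0.7808
#: J / (mol K)
GAS_CONSTANT = 8.314

#: g/mol of N per mole of N2 or N2O (two N atoms), and of C per CO2
MOLAR_MASS_N_PER_MOL = {"N2": 28.0, "N2O-N": 28.0, "CO2-C": 12.0}


@dataclass(frozen=True)
class IRMSPrecision:
    """95%-CI half-widths of the measured ion-current ratios."""

    ci95_r29: float = 4.4e-7
    ci95_r30: float = 6.0e-7

    def __post_init__(self):
        if self.ci95_r29 <= 0 or self.ci95_r30 <= 0:
            raise ValueError("precisions must be positive")

    @property
    def sd_r29(self) -> float:
        return self.ci95_r29 / 1.96

    @property
    def sd_r30(self) -> float:
        return self.ci95_r30 / 1.96


@dataclass(frozen=True)
class IsotopologueSample:
    """Measured (29R, 30R) with its treatment-specific background."""

    r29: float
    r30: float
    background_r29: float
    background_r30: float
    microcosm: str = ""
    period: str = ""

    def __post_init__(self):
        for v in (self.r29, self.r30, self.background_r29, self.background_r30):
            if not math.isfinite(v) or v <= 0:
                raise ValueError("isotopologue ratios must be finite and > 0")


@dataclass
class PartitionResult:
    """Solution of the two-source isotopologue mixing model."""

    a_p: Optional[float]
    f_p: float
    below_detection: bool = False
    inconsistent: bool = False
    ambiguous_root: bool = False


@dataclass(frozen=True)
class MicrocosmGeometry:
    """Closed-microcosm geometry and headspace conditions.

    Defaults describe a 50 ml centrifuge tube with 8 g oven-dry soil
    packed to 1 g/cm3, incubated at 25 degC and ambient pressure.
    """

    tube_volume_ml: float = 50.0
    soil_mass_g: float = 8.0
    bulk_density_g_cm3: float = 1.0
    temperature_k: float = 298.15
    pressure_kpa: float = 101.325
    closure_days: float = 1.0

    def __post_init__(self):
        for v in (self.tube_volume_ml, self.soil_mass_g, self.bulk_density_g_cm3,
                  self.temperature_k, self.pressure_kpa, self.closure_days):
            if v <= 0:
                raise ValueError("geometry values must be positive")
        if self.headspace_ml <= 0:
            raise ValueError("soil volume exceeds tube volume")

    @property
    def headspace_ml(self) -> float:
        return self.tube_volume_ml - self.soil_mass_g / self.bulk_density_g_cm3

    @property
    def headspace_mol(self) -> float:
        """Total moles of gas in the headspace (ideal gas)."""
        # kPa * L = J, so PV/RT is directly in moles
        return (self.pressure_kpa * self.headspace_ml * 1e-3
                / (GAS_CONSTANT * self.temperature_k))

    @property
    def headspace_n2_mol(self) -> float:
        return self.headspace_mol * N2_MOLE_FRACTION_AIR


@dataclass
class PartitionedEmissions:
    """Per-microcosm (or treatment-mean) emission budget, ug per g soil."""

    n2: float
    n2o_total: float
    n2o_d: float
    n2o_n: float
    co2: float = 0.0
    microcosm: str = ""

    def __post_init__(self):
        if abs(self.n2o_d + self.n2o_n - self.n2o_total) > 1e-9:
            raise ValueError("N2O_d + N2O_n must equal total N2O")
        for v in (self.n2, self.n2o_total, self.n2o_d, self.n2o_n):
            if v < -1e-12:
                raise ValueError("emission masses must be >= 0")

    @property
    def denitrification(self) -> float:
        return self.n2 + self.n2o_d

    @property
    def product_ratio_pct(self) -> Optional[float]:
        if self.n2o_d + self.n2 <= 0:
            return None
        return product_ratio(self.n2o_d, self.n2)


def _binomial_fractions(a: float) -> Tuple[float, float, float]:
    """(x28, x29, x30) molecular fractions at atom fraction ``a``."""
    return (1.0 - a) ** 2, 2.0 * a * (1.0 - a), a * a


def isotopologue_forward(f_p: float, a_p: float,
                         a_bgd: float = ATMOSPHERIC_N15) -> Tuple[float, float]:
    """Ratios (29R, 30R) of a two-source N2 mixture.

    ``f_p`` is the molecular fraction of gas derived from the
    denitrifying pool (atom fraction ``a_p``); the rest is background
    gas at ``a_bgd``.
    """
    if not 0.0 <= f_p <= 1.0:
        raise ValueError("f_p must be in [0, 1]")
    for name, a in (("a_p", a_p), ("a_bgd", a_bgd)):
        if not 0.0 < a < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    p28, p29, p30 = _binomial_fractions(a_p)
    b28, b29, b30 = _binomial_fractions(a_bgd)
    x28 = f_p * p28 + (1 - f_p) * b28
    x29 = f_p * p29 + (1 - f_p) * b29
    x30 = f_p * p30 + (1 - f_p) * b30
    return x29 / x28, x30 / x28


def ratios_to_fractions(r29: float, r30: float) -> Tuple[float, float, float]:
    """Convert (29R, 30R) to molecular fractions summing to one."""
    denom = 1.0 + r29 + r30
    return 1.0 / denom, r29 / denom, r30 / denom


def invert_ap_fp(sample: IsotopologueSample,
                 precision: IRMSPrecision = IRMSPrecision(),
                 measured_no3_atomfrac: Optional[float] = None,
                 fixed_ap: Optional[float] = None) -> PartitionResult:
    """Recover (a_p, f_p) from measured and background ratios.

    Exact inverse of :func:`isotopologue_forward`.  When both
    isotopologue excesses are below the measurement precision the
    sample is flagged below detection with f_p = 0; when the implied
    quadratic has no root in (a_bgd, 1] the isotopologue pattern is
    flagged inconsistent.  If both roots are admissible the one closer
    to the measured NO3- enrichment is taken when available, else the
    larger, flagged ambiguous.

    With ``fixed_ap`` the pool enrichment is taken as known (e.g. the
    independently measured NO3- enrichment) instead of being estimated
    from the isotopologue pattern, and f_p follows linearly from the
    more precise channel (29R excess).  This avoids the strong noise
    amplification of the two-unknown inversion when the pool is only
    weakly enriched and the 30R excess sits near instrument precision.
    """
    # background atom fraction from the background ratios (binomial:
    # 29R_b = 2a/(1-a) so a = r/(2+r))
    a_b = sample.background_r29 / (2.0 + sample.background_r29)
    _, x29, x30 = ratios_to_fractions(sample.r29, sample.r30)
    _, b29, b30 = ratios_to_fractions(sample.background_r29, sample.background_r30)
    d29 = x29 - b29
    d30 = x30 - b30
    if abs(d29) < precision.ci95_r29 and abs(d30) < precision.ci95_r30:
        return PartitionResult(a_p=None, f_p=0.0, below_detection=True)
    if fixed_ap is not None:
        if not a_b < fixed_ap <= 1.0:
            raise ValueError("fixed_ap must lie in (a_bgd, 1]")
        _, p29, _ = _binomial_fractions(fixed_ap)
        f_p = d29 / (p29 - b29)
        if not 0.0 <= f_p <= 1.0 + 1e-12:
            return PartitionResult(a_p=fixed_ap, f_p=min(max(f_p, 0.0), 1.0),
                                   inconsistent=True)
        return PartitionResult(a_p=fixed_ap, f_p=min(f_p, 1.0))
    if abs(d29) < 1e-300:
        return PartitionResult(a_p=None, f_p=0.0, inconsistent=True)
    q = d30 / d29
    # (1+2q) a^2 - 2q a + (2q a_b (1-a_b) - a_b^2) = 0
    A = 1.0 + 2.0 * q
    B = -2.0 * q
    C = 2.0 * q * a_b * (1.0 - a_b) - a_b * a_b
    roots = []
    if abs(A) < 1e-300:
        if abs(B) > 1e-300:
            roots = [-C / B]
    else:
        disc = B * B - 4.0 * A * C
        if disc >= 0.0:
            sq = math.sqrt(disc)
            roots = [(-B - sq) / (2 * A), (-B + sq) / (2 * A)]
    admissible = [r for r in roots if a_b < r <= 1.0]
    if not admissible:
        return PartitionResult(a_p=None, f_p=0.0, inconsistent=True)
    ambiguous = False
    if len(set(np.round(admissible, 15))) > 1:
        if measured_no3_atomfrac is not None:
            a_p = min(admissible, key=lambda r: abs(r - measured_no3_atomfrac))
        else:
            a_p = max(admissible)
            ambiguous = True
    else:
        a_p = admissible[0]
    f_p = d30 / (a_p * a_p - a_b * a_b)
    if not 0.0 <= f_p <= 1.0 + 1e-12:
        return PartitionResult(a_p=a_p, f_p=min(max(f_p, 0.0), 1.0),
                               inconsistent=True)
    return PartitionResult(a_p=a_p, f_p=min(f_p, 1.0), ambiguous_root=ambiguous)


def concentration_to_mass(delta_conc_ppm: float, geometry: MicrocosmGeometry,
                          species: str = "N2O-N") -> float:
    """Convert a headspace mixing-ratio change (ppmv) to ug per g soil.

    Ideal gas with temperature/pressure correction; N2O and N2 count
    28 g N per mole of gas, CO2 counts 12 g C.
    """
    key = {"N2O-N": "N2O-N", "N2O": "N2O-N", "N2": "N2", "CO2-C": "CO2-C",
           "CO2": "CO2-C"}.get(species)
    if key is None:
        raise ValueError(f"unknown species {species!r}")
    mol = delta_conc_ppm * 1e-6 * geometry.headspace_mol
    return mol * MOLAR_MASS_N_PER_MOL[key] * 1e6 / geometry.soil_mass_g


def flux_from_timeseries(times_days: Sequence[float], concs_ppm: Sequence[float],
                         geometry: MicrocosmGeometry,
                         species: str = "N2O-N") -> float:
    """Flux (ug/g/day) from the slope of concentration over one closure."""
    t = np.asarray(times_days, dtype=float)
    c = np.asarray(concs_ppm, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two points per closure period")
    slope = np.polyfit(t, c, 1)[0]
    return concentration_to_mass(float(slope), geometry, species)


def partition_n2o(n2o_total: float, result: PartitionResult) -> Tuple[float, float]:
    """Split an N2O mass into denitrification- and nitrification-derived parts.

    ``result.f_p`` is applied as the pool-derived share of the supplied
    N2O mass; the caller chooses whether that mass is total-headspace or
    emitted (background-subtracted) N2O, matching the share that f_p
    refers to.  N2O_n is computed by difference so mass is conserved.
    """
    if not 0.0 <= result.f_p <= 1.0:
        raise ValueError("f_p must be in [0, 1]")
    if n2o_total < 0:
        raise ValueError("N2O mass must be >= 0")
    n2o_d = n2o_total * result.f_p
    return n2o_d, n2o_total - n2o_d


def cumulative_emissions(per_closure_masses: Sequence[float],
                         closures: Sequence[Tuple[float, float]]) -> float:
    """Sum per-closure accumulated masses over non-overlapping closures.

    Each closure starts from ambient background after headspace
    re-equilibration, so cumulative emission is a plain sum.
    """
    closures = list(closures)
    if len(closures) != len(per_closure_masses):
        raise ValueError("one closure interval per mass required")
    for (s0, e0), (s1, _) in zip(closures, closures[1:]):
        if e0 > s1 + 1e-12 or s0 >= e0:
            raise ValueError("closure periods must be ordered and non-overlapping")
    if closures and closures[-1][0] >= closures[-1][1]:
        raise ValueError("closure periods must be ordered and non-overlapping")
    return float(np.sum(per_closure_masses))


def product_ratio(n2o_d: float, n2: float) -> float:
    """Product ratio of denitrification, 100 * N2O_d / (N2O_d + N2), percent."""
    if n2o_d < 0 or n2 < 0:
        raise ValueError("masses must be >= 0")
    denom = n2o_d + n2
    if denom <= 0:
        raise ValueError("product ratio undefined: no denitrification products")
    return 100.0 * n2o_d / denom


def detection_limit(precision: IRMSPrecision = IRMSPrecision(),
                    a_p: float = 0.5,
                    a_bgd: float = ATMOSPHERIC_N15,
                    geometry: MicrocosmGeometry = MicrocosmGeometry(),
                    criterion: float = 1.0) -> float:
    """Method detection limit for N2, in ug N2-N per g soil.

    The smallest emitted N2 mass whose isotopologue signal is
    distinguishable from background at the stated ratio precision: the
    combined signal-to-noise of the two channels,

        sqrt[ ((29R - 29R_b)/ci29)^2 + ((30R - 30R_b)/ci30)^2 ],

    must reach ``criterion``.  The threshold-crossing f_p is found by
    root bracketing on the exact forward model.  Monotone non-increasing
    in ``a_p`` (low enrichment loads the weak 30R channel) and linear in
    ``criterion`` at measurement scale.
    """
    if a_p <= a_bgd:
        raise ValueError("a_p must exceed the background atom fraction")
    from scipy.optimize import brentq

    r29_b, r30_b = isotopologue_forward(0.0, 0.5, a_bgd)

    def snr_excess(f_p):
        r29, r30 = isotopologue_forward(f_p, a_p)
        return math.hypot((r29 - r29_b) / precision.ci95_r29,
                          (r30 - r30_b) / precision.ci95_r30) - criterion

    hi = 0.5
    while snr_excess(hi) < 0:            # pathological precisions only
        hi = 1.0 - (1.0 - hi) / 2.0
    f_p = brentq(snr_excess, 0.0, hi, xtol=1e-18, rtol=8.9e-16)
    # emitted moles n relate to f_p via n / (n + n_background)
    n_bg = geometry.headspace_n2_mol
    n_emitted = f_p / (1.0 - f_p) * n_bg
    return n_emitted * 28.0 * 1e6 / geometry.soil_mass_g


def hybrid_consistency_check(result: PartitionResult,
                             measured_no3_atomfrac: float,
                             tolerance: float = 0.05) -> bool:
    """Flag a sample whose recovered a_p disagrees with the measured
    NO3- enrichment (a diagnostic for hybrid N2/N2O formation, which
    violates the single-pool random-pairing assumption).

    Returns True when the sample is hybrid-suspect.
    """
    if result.a_p is None:
        return False
    return abs(result.a_p - measured_no3_atomfrac) > tolerance


GAS_RECORD_COLUMNS = [
    "microcosm", "soil", "treatment", "label", "closure_start_h",
    "closure_end_h", "n2o_ppm", "co2_ppm", "r29", "r30",
    "bgd_r29", "bgd_r30", "n2o_r29", "n2o_r30", "n2o_bgd_r29", "n2o_bgd_r30",
    "ambient_n2o_ppm", "ambient_co2_ppm",
]


def process_gas_records(records: pd.DataFrame,
                        geometry: MicrocosmGeometry = MicrocosmGeometry(),
                        precision: IRMSPrecision = IRMSPrecision(),
                        measured_no3_atomfrac: Optional[float] = None,
                        average_replicates: bool = False,
                        fixed_ap=None) -> pd.DataFrame:
    """Per-microcosm partitioned emissions from a table of gas records.

    Expects one row per microcosm and closure period with the columns
    of ``GAS_RECORD_COLUMNS``.  N2 is quantified from the N2
    isotopologue ratios and the headspace N2 inventory; N2O is
    converted from its concentration increase over ambient and split
    into denitrification- and nitrification-derived parts using the
    N2O isotopologue ratios.  Returns one row per microcosm with
    closure-summed (cumulative) masses in ug per g soil.

    With ``average_replicates=True`` the measured ratios and
    concentrations are first averaged over replicate microcosms within
    each (soil, treatment, closure) cell and one row per soil/treatment
    is returned.  Averaging before the nonlinear inversion reduces the
    noise amplification that otherwise biases f_p upward when the
    denitrifying pool is weakly enriched and the 30R excess sits close
    to the instrument precision.

    ``fixed_ap`` (a float, or a mapping soil -> float) supplies an
    independently measured enrichment of the denitrifying NO3- pool;
    see :func:`invert_ap_fp`.
    """
    missing = [c for c in ("microcosm", "n2o_ppm", "r29", "r30",
                           "bgd_r29", "bgd_r30") if c not in records.columns]
    if missing:
        raise ValueError(f"gas record table is missing columns: {missing}")
    if average_replicates:
        keys = [c for c in ("soil", "treatment") if c in records.columns]
        if not keys:
            raise ValueError("average_replicates requires soil/treatment columns")
        group_cols = keys + ["closure_start_h", "closure_end_h"]
        num_cols = [c for c in records.columns
                    if c not in group_cols + ["microcosm", "label"]
                    and pd.api.types.is_numeric_dtype(records[c])]
        records = (records.groupby(group_cols, as_index=False)[num_cols]
                   .mean())
        records["microcosm"] = [
            "-".join(str(r[k]) for k in keys) + "-mean"
            for _, r in records.iterrows()]
        for k in keys:
            records[k] = records[k].astype(str)
    out_rows = []
    for microcosm, grp in records.groupby("microcosm", sort=True):
        soil = str(grp["soil"].iloc[0]) if "soil" in grp else ""
        if isinstance(fixed_ap, dict):
            ap_known = fixed_ap.get(soil)
        else:
            ap_known = fixed_ap
        n2_masses, n2o_tot_masses, n2o_d_masses, co2_masses = [], [], [], []
        closures = []
        for _, row in grp.sort_values("closure_start_h").iterrows():
            closures.append((row["closure_start_h"], row["closure_end_h"]))
            # N2 from its isotopologue excess
            n2_sample = IsotopologueSample(
                r29=row["r29"], r30=row["r30"],
                background_r29=row["bgd_r29"], background_r30=row["bgd_r30"],
                microcosm=str(microcosm))
            res_n2 = invert_ap_fp(n2_sample, precision, measured_no3_atomfrac,
                                  fixed_ap=ap_known)
            n_bg = geometry.headspace_n2_mol
            n2_mass = (res_n2.f_p / (1.0 - res_n2.f_p) * n_bg * 28.0 * 1e6
                       / geometry.soil_mass_g) if res_n2.f_p < 1.0 else np.inf
            n2_masses.append(n2_mass)
            # emitted N2O over ambient
            ambient = row.get("ambient_n2o_ppm", 0.33)
            total_ppm = row["n2o_ppm"]
            emitted_ppm = max(total_ppm - ambient, 0.0)
            n2o_emitted = concentration_to_mass(emitted_ppm, geometry, "N2O-N")
            n2o_tot_masses.append(n2o_emitted)
            # pool-derived fraction of total headspace N2O, rescaled to
            # the emitted share (ambient N2O carries none of the label)
            if "n2o_r29" in row and not pd.isna(row["n2o_r29"]):
                n2o_sample = IsotopologueSample(
                    r29=row["n2o_r29"], r30=row["n2o_r30"],
                    background_r29=row["n2o_bgd_r29"],
                    background_r30=row["n2o_bgd_r30"],
                    microcosm=str(microcosm))
                res_n2o = invert_ap_fp(n2o_sample, precision,
                                       measured_no3_atomfrac,
                                       fixed_ap=ap_known)
                share_emitted = emitted_ppm / total_ppm if total_ppm > 0 else 0.0
                f_of_emitted = (res_n2o.f_p / share_emitted
                                if share_emitted > 0 else 0.0)
                f_of_emitted = min(max(f_of_emitted, 0.0), 1.0)
                n2o_d, _ = partition_n2o(
                    n2o_emitted, PartitionResult(a_p=res_n2o.a_p,
                                                 f_p=f_of_emitted))
            else:
                n2o_d = 0.0
            n2o_d_masses.append(n2o_d)
            if "co2_ppm" in row and not pd.isna(row["co2_ppm"]):
                amb_co2 = row.get("ambient_co2_ppm", 420.0)
                co2_masses.append(concentration_to_mass(
                    max(row["co2_ppm"] - amb_co2, 0.0), geometry, "CO2-C"))
        n2 = cumulative_emissions(n2_masses, closures)
        n2o_total = cumulative_emissions(n2o_tot_masses, closures)
        n2o_d = cumulative_emissions(n2o_d_masses, closures)
        co2 = float(np.sum(co2_masses)) if co2_masses else 0.0
        pe = PartitionedEmissions(n2=n2, n2o_total=n2o_total, n2o_d=n2o_d,
                                  n2o_n=n2o_total - n2o_d, co2=co2,
                                  microcosm=str(microcosm))
        out_rows.append({
            "microcosm": pe.microcosm,
            "soil": grp["soil"].iloc[0] if "soil" in grp else "",
            "treatment": grp["treatment"].iloc[0] if "treatment" in grp else "",
            "n2_ug_n_g": pe.n2,
            "n2o_total_ug_n_g": pe.n2o_total,
            "n2o_d_ug_n_g": pe.n2o_d,
            "n2o_n_ug_n_g": pe.n2o_n,
            "denitrification_ug_n_g": pe.denitrification,
            "product_ratio_pct": pe.product_ratio_pct,
            "co2_ug_c_g": pe.co2,
        })
    return pd.DataFrame(out_rows)
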