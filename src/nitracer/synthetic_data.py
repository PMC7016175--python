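"""Seeded generator of a complete virtual microcosm experiment.

Emulates a paired-labelling soil incubation: two contrasting soils
(one slow-cycling, horticultural-like; one fast-cycling, pasture-like),
fertilized with 35 ug N/g as NH4NO3 with or without the nitrification
inhibitor DMPP, each under four 15N label combinations --

  a. 15NH4NO3, NH4+ labelled at 10 atom%
  b. NH415NO3, NO3- labelled at 10 atom%
  c. NH415NO3, NO3- labelled at 60 atom% (for N2/N2O quantification)
  d. unlabelled (biomass / ancillary measurements)

-- with four replicates, destructive sampling for mineral N and its
enrichment, and two 24 h headspace closures for gas sampling.  The
generator simulates the tracing model forward for the ground truth,
adds measurement noise, and emits the same tabular schemas the
estimation modules consume, plus a truth bundle for recovery checks.

DMPP is represented as multiplicative modifiers on the true rate
constants (its dominant effect: a strong reduction of autotrophic
nitrification, with secondary stimulation of mineralization/
immobilization turnover in the slow soil).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .gasflux import (
    IRMSPrecision,
    MicrocosmGeometry,
    PartitionedEmissions,
    concentration_to_mass,
    isotopologue_forward,
    product_ratio,
)
from .tracing_model import (
    NATURAL_ABUNDANCE,
    PoolState,
    TransformationSet,
    average_gross_rates,
    simulate,
)

__all__ = ["NoiseModel", "SoilTruth", "ExperimentDesign",
           "default_design", "generate_experiment", "truth_table",
           "initial_state"]

#: 30 minutes, in days: the first destructive sampling
T_FIRST = 0.5 / 24.0
#: default destructive sampling schedule (days); the two end members are
#: the study schedule, the intermediate times make all ten fluxes
#: identifiable from two observed pools
DEFAULT_SAMPLING_DAYS = (T_FIRST, 0.25, 0.5, 1.0, 2.0)
PAPER_FAITHFUL_SAMPLING_DAYS = (T_FIRST, 2.0)

AMBIENT_N2O_PPM = 0.33
AMBIENT_CO2_PPM = 420.0

LABEL_COMBOS = {
    "a": ("nh4", 0.10),
    "b": ("no3", 0.10),
    "c": ("no3", 0.60),
    "d": (None, 0.0),
}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings for the virtual instruments."""

    concentration_cv: float = 0.05        # colorimetric mineral N
    enrichment_sd_atomfrac: float = 0.001  # diffusion/IRMS, 0.1 atom%
    gas_concentration_cv: float = 0.03    # GC for N2O / CO2
    irms: IRMSPrecision = field(default_factory=IRMSPrecision)

    def __post_init__(self):
        if min(self.concentration_cv, self.enrichment_sd_atomfrac,
               self.gas_concentration_cv) < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class SoilTruth:
    """Ground truth for one soil: kinetics, native pools, emissions.

    Emission truths are cumulative 48 h masses (ug/g soil) per
    treatment, split across the two closures by ``closure_split``.
    """

    name: str
    k: Dict[str, float]
    km: Dict[str, float]
    native_nh4: float
    native_no3: float
    nlab0: float
    nrec0: float
    nh4ads0: float
    dmpp_modifiers: Dict[str, float]
    emissions: Dict[str, Dict[str, float]]  # treatment -> {n2, n2o_d, n2o_n, co2}
    closure_split: Tuple[float, float] = (0.45, 0.55)

    def transformations(self, treatment: str) -> TransformationSet:
        k = dict(self.k)
        if treatment == "dmpp":
            for name, m in self.dmpp_modifiers.items():
                k[name] = k[name] * m
        return TransformationSet.from_constants(k, km=self.km)


def _sandy_cl() -> SoilTruth:
    """Slow-cycling horticultural regime: low mineralization, moderate
    autotrophic nitrification, strong NO3- immobilization."""
    return SoilTruth(
        name="sandy_cl",
        k={"M_Nrec": 0.12, "I_NH4_Nrec": 0.012, "M_Nlab": 0.0067,
           "I_NH4_Nlab": 0.06, "O_Nrec": 0.38, "I_NO3": 9.48,
           "O_NH4": 10.0, "D_NO3": 0.026, "A_NH4": 0.07, "R_NH4a": 0.08},
        km={"O_NH4": 10.0},
        native_nh4=0.0, native_no3=53.4,
        nlab0=15.0, nrec0=500.0, nh4ads0=5.0,
        dmpp_modifiers={"O_NH4": 0.37, "I_NO3": 0.69, "M_Nrec": 8.6,
                        "I_NH4_Nrec": 5.0, "M_Nlab": 2.7, "I_NH4_Nlab": 3.2,
                        "D_NO3": 5.3, "R_NH4a": 8.5, "A_NH4": 0.74},
        emissions={
            "fertilizer": {"n2": 0.47, "n2o_d": 0.26, "n2o_n": 0.02,
                           "co2": 6.55},
            "dmpp": {"n2": 0.46, "n2o_d": 0.14, "n2o_n": 0.02, "co2": 5.99},
        },
    )


def _loam() -> SoilTruth:
    """Fast-cycling pasture regime: high mineralization dominated by the
    labile pool, high autotrophic nitrification, weak immobilization."""
    return SoilTruth(
        name="loam",
        k={"M_Nrec": 2.59, "I_NH4_Nrec": 2e-4, "M_Nlab": 0.039,
           "I_NH4_Nlab": 2e-4, "O_Nrec": 0.0, "I_NO3": 0.017,
           "O_NH4": 30.0, "D_NO3": 2.14, "A_NH4": 0.0, "R_NH4a": 0.0},
        km={"O_NH4": 5.0},
        native_nh4=0.7, native_no3=117.7,
        nlab0=150.0, nrec0=3000.0, nh4ads0=5.0,
        dmpp_modifiers={"O_NH4": 0.94, "M_Nlab": 0.93},
        emissions={
            "fertilizer": {"n2": 0.87, "n2o_d": 2.21, "n2o_n": 0.15,
                           "co2": 44.66},
            "dmpp": {"n2": 1.20, "n2o_d": 1.63, "n2o_n": 0.17, "co2": 46.27},
        },
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """The full factorial design of the virtual incubation."""

    soils: Tuple[SoilTruth, ...] = (_sandy_cl(), _loam())
    treatments: Tuple[str, ...] = ("fertilizer", "dmpp")
    label_combos: Tuple[str, ...] = ("a", "b", "c", "d")
    replicates: int = 4
    sampling_days: Tuple[float, ...] = DEFAULT_SAMPLING_DAYS
    closures_h: Tuple[Tuple[float, float], ...] = ((0.0, 24.0), (24.0, 48.0))
    fertilizer_dose: float = 35.0          # ug N/g, split NH4:NO3 1:1
    noise: NoiseModel = field(default_factory=NoiseModel)
    geometry: MicrocosmGeometry = field(default_factory=MicrocosmGeometry)

    def __post_init__(self):
        if self.fertilizer_dose <= 0:
            raise ValueError("fertilizer dose must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        required = {round(T_FIRST, 9), 2.0}
        if not required.issubset({round(float(t), 9)
                                  for t in self.sampling_days}):
            raise ValueError(
                "sampling schedule must include the 30 min and 48 h times")


def default_design(paper_faithful_times: bool = False,
                   noise: Optional[NoiseModel] = None) -> ExperimentDesign:
    kwargs = {}
    if paper_faithful_times:
        kwargs["sampling_days"] = PAPER_FAITHFUL_SAMPLING_DAYS
    if noise is not None:
        kwargs["noise"] = noise
    return ExperimentDesign(**kwargs)


def initial_state(soil: SoilTruth, combo: str,
                  dose: float = 35.0) -> PoolState:
    """Post-fertilization initial pools for one label combination.

    The dose is split equally between NH4+ and NO3-; the labelled half
    enters at the combo's atom fraction, everything else at natural
    abundance.
    """
    pool, atom_frac = LABEL_COMBOS[combo]
    half = dose / 2.0
    nh4 = soil.native_nh4 + half
    no3 = soil.native_no3 + half
    f_nh4 = f_no3 = NATURAL_ABUNDANCE
    if pool == "nh4":
        f_nh4 = (half * atom_frac + soil.native_nh4 * NATURAL_ABUNDANCE) / nh4
    elif pool == "no3":
        f_no3 = (half * atom_frac + soil.native_no3 * NATURAL_ABUNDANCE) / no3
    return PoolState(nh4=nh4, no3=no3, nlab=soil.nlab0, nrec=soil.nrec0,
                     nh4ads=soil.nh4ads0, f_nh4=f_nh4, f_no3=f_no3)


def _simulate_combo(soil: SoilTruth, treatment: str, combo: str,
                    design: ExperimentDesign, grid: np.ndarray):
    ts = soil.transformations(treatment)
    init = initial_state(soil, combo, design.fertilizer_dose)
    return ts, init, simulate(ts, init, grid)


def _dense_grid(design: ExperimentDesign) -> np.ndarray:
    extra = np.linspace(0.0, 2.0, 241)
    return np.unique(np.concatenate([extra, np.asarray(design.sampling_days)]))


def generate_experiment(design: ExperimentDesign = None,
                        seed: int = 0) -> Dict[str, object]:
    """Generate the full virtual experiment.

    Returns a dict with
      - ``observations``: destructive-sampling table (label combos a, b)
      - ``gas_records``: headspace gas table (label combo c)
      - ``truth``: per-soil/treatment true rate tables, true emissions
        and the true (a_p, f_p) per closure.
    Reproducible for a fixed seed.
    """
    if design is None:
        design = ExperimentDesign()
    rng = np.random.default_rng([int(seed) % (2**31), 2025])
    noise = design.noise
    geom = design.geometry
    obs_rows: List[dict] = []
    gas_rows: List[dict] = []
    truth: Dict[str, dict] = {}

    grid = _dense_grid(design)
    t_idx = {round(t, 9): np.searchsorted(np.round(grid, 9), round(t, 9))
             for t in design.sampling_days}

    for soil in design.soils:
        for treatment in design.treatments:
            key = f"{soil.name}/{treatment}"
            # --- destructive sampling, combos a and b ---------------------
            trajs = {}
            for combo in ("a", "b"):
                if combo not in design.label_combos:
                    continue
                ts, init, traj = _simulate_combo(soil, treatment, combo,
                                                 design, grid)
                trajs[combo] = (ts, init, traj)
                pool, atom_frac = LABEL_COMBOS[combo]
                for t in design.sampling_days:
                    state = traj.states[t_idx[round(t, 9)]]
                    for rep in range(design.replicates):
                        nh4 = state.nh4 * (1 + noise.concentration_cv
                                           * rng.standard_normal())
                        no3 = state.no3 * (1 + noise.concentration_cv
                                           * rng.standard_normal())
                        f_nh4 = (state.f_nh4 + noise.enrichment_sd_atomfrac
                                 * rng.standard_normal())
                        f_no3 = (state.f_no3 + noise.enrichment_sd_atomfrac
                                 * rng.standard_normal())
                        obs_rows.append({
                            "soil": soil.name, "treatment": treatment,
                            "label": pool, "label_atom_pct": atom_frac * 100,
                            "replicate": rep, "time_days": t,
                            "nh4_ug_n_g": max(nh4, 0.0),
                            "no3_ug_n_g": max(no3, 0.0),
                            "nh4_atom_pct": np.clip(f_nh4, 0.003, 1.0) * 100,
                            "no3_atom_pct": np.clip(f_no3, 0.003, 1.0) * 100,
                        })
            # --- gas sampling, combo c ------------------------------------
            ts_c, init_c, traj_c = _simulate_combo(soil, treatment, "c",
                                                   design, grid)
            emis = soil.emissions[treatment]
            closure_truth = []
            for ci, (h0, h1) in enumerate(design.closures_h):
                d0, d1 = h0 / 24.0, h1 / 24.0
                sel = (grid >= d0) & (grid <= d1)
                f_no3_series = np.array([s.f_no3 for s in traj_c.states])[sel]
                a_p = float(np.trapezoid(f_no3_series, grid[sel])
                            / (grid[sel][-1] - grid[sel][0]))
                split = soil.closure_split[ci]
                n2_mass = emis["n2"] * split
                n2o_d_mass = emis["n2o_d"] * split
                n2o_n_mass = emis["n2o_n"] * split
                co2_mass = emis["co2"] * split
                # true pool-derived fraction of total headspace N2
                n2_mol = n2_mass * geom.soil_mass_g * 1e-6 / 28.0
                fp_n2 = n2_mol / (n2_mol + geom.headspace_n2_mol)
                # true pool-derived fraction of total headspace N2O
                amb_n2o_mass = concentration_to_mass(AMBIENT_N2O_PPM, geom)
                n2o_emitted = n2o_d_mass + n2o_n_mass
                fp_n2o = n2o_d_mass / (n2o_emitted + amb_n2o_mass)
                closure_truth.append({"closure": ci, "a_p": a_p,
                                      "f_p_n2": fp_n2, "f_p_n2o": fp_n2o,
                                      "n2": n2_mass, "n2o_d": n2o_d_mass,
                                      "n2o_n": n2o_n_mass})
                bgd_r29, bgd_r30 = isotopologue_forward(0.0, 0.5,
                                                        NATURAL_ABUNDANCE)
                r29_true, r30_true = isotopologue_forward(fp_n2, a_p)
                n2o_r29_true, n2o_r30_true = isotopologue_forward(fp_n2o, a_p)
                emitted_ppm = (n2o_emitted / concentration_to_mass(1.0, geom))
                co2_ppm = co2_mass / concentration_to_mass(1.0, geom, "CO2-C")
                for rep in range(design.replicates):
                    r29 = r29_true + noise.irms.sd_r29 * rng.standard_normal()
                    r30 = r30_true + noise.irms.sd_r30 * rng.standard_normal()
                    nr29 = (n2o_r29_true
                            + noise.irms.sd_r29 * rng.standard_normal())
                    nr30 = (n2o_r30_true
                            + noise.irms.sd_r30 * rng.standard_normal())
                    ppm = (AMBIENT_N2O_PPM + emitted_ppm
                           * (1 + noise.gas_concentration_cv
                              * rng.standard_normal()))
                    cppm = (AMBIENT_CO2_PPM + co2_ppm
                            * (1 + noise.gas_concentration_cv
                               * rng.standard_normal()))
                    gas_rows.append({
                        "microcosm": f"{soil.name}-{treatment}-c{rep}",
                        "soil": soil.name, "treatment": treatment,
                        "label": "c", "closure_start_h": h0,
                        "closure_end_h": h1,
                        "n2o_ppm": ppm, "co2_ppm": cppm,
                        "r29": r29, "r30": r30,
                        "bgd_r29": bgd_r29, "bgd_r30": bgd_r30,
                        "n2o_r29": nr29, "n2o_r30": nr30,
                        "n2o_bgd_r29": bgd_r29, "n2o_bgd_r30": bgd_r30,
                        "ambient_n2o_ppm": AMBIENT_N2O_PPM,
                        "ambient_co2_ppm": AMBIENT_CO2_PPM,
                    })
            rate_truth = average_gross_rates(
                ts_c, traj_c, (0.0, 2.0))
            truth[key] = {
                "rate_table": rate_truth,
                "kinetics": soil.transformations(treatment).metadata(),
                "init": {c: initial_state(soil, c, design.fertilizer_dose)
                         for c in design.label_combos},
                "emissions": PartitionedEmissions(
                    n2=emis["n2"],
                    n2o_total=emis["n2o_d"] + emis["n2o_n"],
                    n2o_d=emis["n2o_d"], n2o_n=emis["n2o_n"],
                    co2=emis["co2"], microcosm=key),
                "closures": closure_truth,
            }
    return {
        "observations": pd.DataFrame(obs_rows),
        "gas_records": pd.DataFrame(gas_rows),
        "truth": truth,
        "seed": int(seed),
    }


def truth_table(design: ExperimentDesign = None
                ) -> Dict[str, Dict[str, object]]:
    """Exact (noise-free) truth per soil x treatment.

    Rate tables come from a dense forward integration of the generating
    model; emissions are the design's stated cumulative masses.  The
    truth product ratio is computed with the same arithmetic as the
    estimation path.
    """
    if design is None:
        design = ExperimentDesign()
    grid = _dense_grid(design)
    out: Dict[str, Dict[str, object]] = {}
    for soil in design.soils:
        for treatment in design.treatments:
            ts, init, traj = _simulate_combo(soil, treatment, "d",
                                             design, grid)
            table = average_gross_rates(ts, traj, (0.0, 2.0))
            emis = soil.emissions[treatment]
            pe = PartitionedEmissions(
                n2=emis["n2"], n2o_total=emis["n2o_d"] + emis["n2o_n"],
                n2o_d=emis["n2o_d"], n2o_n=emis["n2o_n"], co2=emis["co2"],
                microcosm=f"{soil.name}/{treatment}")
            out[f"{soil.name}/{treatment}"] = {
                "rate_table": table,
                "emissions": pe,
                "product_ratio_pct": (product_ratio(pe.n2o_d, pe.n2)
                                      if pe.n2o_d + pe.n2 > 0 else None),
            }
    return out
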