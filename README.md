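# nitracer

Gross nitrogen transformation rates and N₂O/N₂ source partitioning for
soil ¹⁵N microcosm experiments.

Fertilized soils emit the greenhouse gas N₂O through several concurrent
pathways. Untangling them requires two measurements that net pool
changes cannot provide: the *gross* (one-way) rates of the N
transformations feeding and consuming the mineral N pools, and the
split of emitted N₂O into nitrification- and denitrification-derived
fractions together with the N₂ that complete denitrification produces.
`nitracer` implements the computational core of such a study for soil
scientists and biogeochemists: a ¹⁵N tracing model with MCMC parameter
estimation, and the ¹⁵N gas-flux method.

## The models

**Tracing model.** Five N pools — NH₄⁺, NO₃⁻, labile organic N
(N_lab), recalcitrant organic N (N_rec), and adsorbed NH₄⁺ — are
linked by ten gross transformations (mineralization *M_Nrec*, *M_Nlab*;
NH₄⁺ immobilization *I_NH4_Nrec*, *I_NH4_Nlab*; autotrophic and
heterotrophic nitrification *O_NH4*, *O_Nrec*; NO₃⁻ immobilization
*I_NO3*; DNRA *D_NO3*; NH₄⁺ adsorption/release *A_NH4*, *R_NH4a*),
each following zero-order, first-order or Michaelis–Menten kinetics.
Every flux carries ¹⁵N at its source pool's current atom fraction, so
paired labelling (¹⁵NH₄NO₃ vs NH₄¹⁵NO₃) makes the one-way rates
identifiable from the dilution/enrichment dynamics. Parameters are
estimated by random-walk Metropolis on log-transformed rate constants;
reported rates are the time-averages (1/T)∫r(t)dt over the incubation.

**Gas-flux method.** After labelling NO₃⁻ at 60 atom%, denitrified N₂
(and N₂O) is binomially distributed over the masses 28/29/30, so the
measured ion-current ratios ²⁹R and ³⁰R of a headspace sample — a
two-source mixture of pool-derived gas and atmospheric background —
determine both the enrichment *a_p* of the denitrifying NO₃⁻ pool and
the pool-derived fraction *f_p*. Multiplying headspace inventories by
*f_p* yields N₂ and N₂O_d; N₂O_n follows by difference, and the product
ratio N₂O_d/(N₂O_d+N₂) quantifies how far denitrification proceeds to
N₂. Detection limits follow from the IRMS ratio precisions.

A seeded synthetic-experiment generator reproduces the full design of
the study the package models (2 soils × ±nitrification inhibitor (DMPP)
× 4 label combinations × 4 replicates, 35 µg N g⁻¹ fertilizer, 48 h
incubation, two 24 h closures) with known ground truth, so the entire
pipeline is testable end to end.

## Worked example

```python
import numpy as np
from nitracer import (default_design, generate_experiment,
                      process_gas_records, MCMCConfig, run_mcmc,
                      posterior_summary)
from nitracer.synthetic_data import initial_state
from nitracer.inference import observations_from_frame, coarse_estimate

design = default_design()
data = generate_experiment(design, seed=3)

# --- gas side: partition emissions from the 60 atom% treatment -------
emissions = process_gas_records(data["gas_records"],
                                geometry=design.geometry,
                                average_replicates=True)
row = emissions[(emissions.soil == "sandy_cl")
                & (emissions.treatment == "fertilizer")].iloc[0]
print(f"N2 {row.n2_ug_n_g:.2f}, N2O_d {row.n2o_d_ug_n_g:.2f}, "
      f"product ratio {row.product_ratio_pct:.0f}%")

# --- tracing side: fit the ten rate constants by MCMC ----------------
soil = design.soils[0]
states = {"nh4": initial_state(soil, "a"), "no3": initial_state(soil, "b")}
df = data["observations"]
obs = observations_from_frame(df[(df.soil == "sandy_cl")
                                 & (df.treatment == "fertilizer")])
template = soil.transformations("fertilizer")
start = coarse_estimate(template, states, obs)
chain = run_mcmc(obs, MCMCConfig(n_iterations=50_000, seed=3),
                 template, states, start=start)
s = posterior_summary(chain)
lo, hi = s.interval["O_NH4"]
print(f"O_NH4 Vmax {s.mean['O_NH4']:.2f} [{lo:.2f}, {hi:.2f}] "
      f"(truth {template['O_NH4'].k})")
```

prints

```
N2 0.52, N2O_d 0.26, product ratio 34%
O_NH4 Vmax 9.36 [8.74, 9.97] (truth 10.0)
```

i.e. the partitioned emissions recover the generator's truth (N₂ 0.47,
N₂O_d 0.26 µg N g⁻¹, product ratio 36%) within replicate noise, and
the posterior of the autotrophic-nitrification capacity sits within a
few percent of the generating value on this seed (calibration across
many seeds — 95% intervals of the gross *rates* covering truth ~94% of
the time — is measured by the test suite's recovery study).

There is also a CLI: `nitracer synth --seed 1`, `nitracer gasflux`,
`nitracer report`, or `nitracer all --seed 1 --out run_out` for the
whole synthetic pipeline.

## Layout

- `nitracer.tracing_model` — pools, kinetic laws, forward simulation,
  time-averaged rate tables
- `nitracer.inference` — misfit likelihood, Metropolis sampler,
  posterior summaries, 95%-CI overlap tests
- `nitracer.gasflux` — isotopologue mixing/inversion, flux conversion,
  N₂O partitioning, cumulative emissions, detection limits
- `nitracer.synthetic_data` — the virtual experiment generator
- `nitracer.reporting_stats` — effect sizes, fumigation-extraction
  biomass, Benjamini–Hochberg adjustment, report tables
- `nitracer.cli_io` — the `nitracer` command
- `docs/methods.md` — model assumptions, defaults, and limitations
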