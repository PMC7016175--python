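# Methods

## The tracing model

The model tracks five nitrogen pools per gram of dry soil — NH₄⁺, NO₃⁻,
labile organic N (N_lab), recalcitrant organic N (N_rec) and
exchangeably adsorbed NH₄⁺ — each as a (total N, ¹⁵N) pair, giving a
ten-dimensional state. Ten gross transformations connect the pools
(see `tracing_model` for the full wiring). Each flux removes N from its
source pool at the source's current ¹⁵N atom fraction and delivers it
unchanged to the sink:

- no isotopic fractionation in any flux (the standard tracing-model
  assumption; no fractionation factors are available for these soils);
- no gaseous sink inside the model — denitrification losses over the
  48 h incubation are ≲1 µg N g⁻¹ against mineral pools of tens of
  µg N g⁻¹ and are handled separately by the gas-flux module;
- consequently both total N and total ¹⁵N are exact linear invariants,
  which the test suite verifies to relative 1e-6 on random kinetics.

**Kinetic-law assignment.** The data do not fix which law each
transformation follows, so the assignment is a configurable default,
recorded in every run manifest: zero-order for M_Nrec, O_Nrec, I_NO3,
D_NO3 and R_NH4a (substrate pools far from exhaustion, or processes
limited by something other than substrate), first-order for M_Nlab,
I_NH4_Nrec, I_NH4_Nlab and A_NH4, and Michaelis–Menten for autotrophic
nitrification O_NH4 (an enzymatic step that saturates at high NH₄⁺).
This mirrors common practice with compartmental ¹⁵N tracing tools.
Zero-order laws taper linearly to zero below 0.01 µg N g⁻¹ so an
emptying pool cannot drive the ODE negative.

**Integration.** Public trajectories use LSODA (stiff-capable) at
rtol 1e-8 / atol 1e-10 on a 97-point output grid over the 2-day
incubation. The MCMC likelihood uses a compiled fixed-step RK4
(sub-step 1/64 day); on the default design it agrees with LSODA to
1.6e-7 in state, far below measurement noise. Average gross rates are
trapezoidal means of the instantaneous rates over the reporting
interval; a 2000-point quadrature oracle in the tests bounds the grid
error below 0.1%.

## Inference

Both labelling treatments (¹⁵NH₄NO₃ and NH₄¹⁵NO₃ at 10 atom%) are
simulated with identical kinetics, differing only in initial
enrichment; the Gaussian misfit sums over NH₄⁺ and NO₃⁻ concentrations
and their atom fractions at every sampling time in both treatments.
Replicate means enter with sd/√n. The per-variable noise sd is the
replicate sd *pooled across time points and treatments* (floored at
1e-3 units): per-time sds from four replicates are so noisy that the
posterior becomes overconfident and undercovers. Pooling restored
nominal coverage in the seeded recovery study.

The sampler is random-walk Metropolis on log-transformed rate
constants (positive, spanning orders of magnitude between soils) under
uniform priors on the natural scale — the log-scale walk carries the
corresponding Jacobian term, which the prior-recovery test would catch
if omitted. A single global proposal scale is adapted toward 0.3
acceptance during burn-in only (default burn-in 20% of a 5×10⁴ chain),
so the retained chain is a valid Metropolis chain. Chains are
bit-reproducible from the config seed. Default prior uppers are 10× a
coarse least-squares estimate (floored at 1 day⁻¹-equivalent), which
also centres the chain start.

Identifiability: with only the study's two destructive sampling times
(30 min, 48 h) the ten-flux model is under-determined; the default
synthetic design therefore adds samplings at 6, 12 and 24 h, under
which a noise-free least-squares fit recovers all ten constants to
<0.1% and the 20-seed posterior study covers the true rates at ~94%.
Real two-time-point data will produce wide posteriors for the weakly
constrained organic-pool fluxes; the machinery reports them honestly
rather than failing. Significance calls between rates use disjointness
of the central 95% intervals, with touching endpoints counting as
overlap.

## The gas-flux method

Random isotope pairing makes pool-derived N₂ binomial in the pool
enrichment a_p; a headspace sample is a two-source mixture with
background air (a_b = 0.003663 unless a treatment-specific background
is supplied). The measured (²⁹R, ³⁰R) are converted to molecular
fractions, the excess ratio Δ³⁰/Δ²⁹ yields a quadratic in a_p whose
root in (a_b, 1] is taken (ties broken toward a measured NO₃⁻
enrichment when available, else the larger root, flagged), and
f_p = Δ³⁰/(a_p²−a_b²). The inversion is the exact inverse of the
forward model (round-trip < 1e-10 over a 50×50 grid). Samples whose
excesses fall below the IRMS precisions (95%-CI half-widths 4.4×10⁻⁷
for ²⁹R, 6.0×10⁻⁷ for ³⁰R) are flagged below detection.

N₂ mass is f_p/(1−f_p) times the headspace N₂ inventory (ideal gas,
78.08% N₂, default geometry: 50 ml tube, 8 g soil at 1 g cm⁻³, 25 °C,
101.325 kPa). N₂O is converted from its concentration increase over
ambient; its own isotopologue ratios give the pool-derived fraction of
total headspace N₂O, rescaled by the emitted share after ambient
subtraction; N₂O_n is the difference, so partitioning conserves mass
exactly. Cumulative emissions sum the two 24 h closures (the headspace
re-equilibrates between them). The product ratio is
100·N₂O_d/(N₂O_d+N₂), reported rounded half-up like all table
percentages (unrounded values are retained in machine output).

**Detection limit.** The MDL is the smallest emitted N₂ mass whose
isotopologue signal is distinguishable from background: the combined
signal-to-noise √[(Δ²⁹R/ci₂₉)² + (Δ³⁰R/ci₃₀)²] must reach the
criterion multiplier (default 1). The combined criterion — rather than
the single most sensitive channel — is used because it is monotone
non-increasing in a_p over the whole range (the ²⁹R sensitivity alone
peaks at 50 atom% and falls beyond it). The threshold crossing is
found by bracketing on the exact forward model. With the default
geometry this gives 0.0039 µg N₂-N g⁻¹ at a_p = 50 atom% and
0.0065 µg N₂-N g⁻¹ at 20 atom% — the expected ordering and order of
magnitude; exact published MDL values depend on derivation details
that are not available, so only ordering and envelope are asserted.

**A near-detection caveat.** In the fast-cycling soil the large native
NO₃⁻ pool dilutes even a 60 atom% label to a_p ≈ 0.08, where the ³⁰R
excess sits near instrument precision and the free two-unknown
inversion amplifies noise into a strong upward bias of f_p (≈ +50% for
N₂ in the synthetic study). Two standard remedies are implemented and
used by the validation studies: averaging replicate ratios before the
nonlinear inversion, and fixing a_p at the independently measured NO₃⁻
enrichment, which makes f_p a linear single-channel estimate. The
free inversion remains the default and is exact in the well-posed
regime; the bias is a property of the method near its detection limit,
not of the implementation.

## The synthetic generator

The generator emulates the full factorial design: 2 soils × 2
treatments × 4 ¹⁵N label combinations × 4 replicates, 35 µg N g⁻¹
NH₄NO₃ split equally between the pools, destructive sampling at 30 min
and 48 h (plus 6/12/24 h by default; a paper-faithful mode restricts
to the two study times), and two 24 h closures. Soil truths are
anchored to the two published regimes: a slow horticultural soil (low
mineralization, O_NH4 averaging ≈ 5 µg N g⁻¹ d⁻¹, strong NO₃⁻
immobilization) and a fast pasture soil (M_tot ≈ 8, O_NH4 average
≈ 18, negligible immobilization). Native mineral pools are
back-computed from the published 30-min concentrations minus the
fertilizer halves; the unmeasured organic and adsorbed pools are model
parameters (slow soil: N_lab 15, N_rec 500; fast soil: 150/3000;
adsorbed 5 µg N g⁻¹). The inhibitor treatment applies multiplicative
modifiers to the true constants, dominated by O_NH4 × 0.37 in the slow
soil and × 0.94 in the fast soil, with the published secondary
stimulation of mineralization/immobilization turnover in the slow soil.

Noise defaults: 5% CV on mineral N concentrations, 0.1 atom% sd on
enrichments, 3% CV on gas concentrations, and IRMS ratio sds derived
from the 95%-CI precisions (CI/1.96). Emission truths are the
published cumulative masses, adjusted minimally for internal
consistency (the printed sandy-soil table has N₂O_d 0.26 exceeding
total N₂O 0.24; the generator uses N₂O 0.28 = 0.26 + 0.02 so that both
the 36% product ratio and the >90% denitrification share hold).
Closures split emissions 45/55. True a_p per closure is the simulated
NO₃⁻ enrichment of the 60 atom% treatment, keeping the gas truth
consistent with the tracing truth.

What the generator does **not** emulate: spatial heterogeneity and
microsite enrichment (real denitrification may see a locally higher
a_p than the bulk pool), inhibitor diffusion/sorption kinetics,
drifting ambient backgrounds, autocorrelated instrument error, and
replicate-to-replicate differences in soil packing. Passing recovery
tests therefore demonstrate correctness of the estimation machinery
under the stated noise model, not robustness to these field realities.

## Problem sizes and numerical choices

The recovery study uses 20 seeded repetitions of the slow-soil
fertilizer arm with 5×10⁴-iteration chains (the package's standard
test-scale chain; production fits can configure upward), thinned to
200 draws for rate intervals; it runs in ≈3 minutes on one core.
Sampler correctness uses 10⁵ draws against a flat likelihood with a
KS test at the 0.01 level. Tolerances: conservation 1e-6 relative;
round trip 1e-10; analytic two-pool solution 1e-6; quadrature oracle
0.1%. Degenerate inputs: empty pools yield zero rates; zero
denominators in derived percentages are reported as undefined rather
than NaN-propagated; a stalled sampler (no acceptance over 10×dim
steps) raises with diagnostics instead of returning a frozen chain.

## Known limitations

- Average ± sd reported from chains is the posterior sd; the SE of the
  posterior mean (via autocorrelation-adjusted ESS) is reported
  alongside because the convention in published tables is ambiguous.
- The ten-flux model is only locally identified by two-time-point
  designs; the package does not do model selection between kinetic
  assignments (deliberate non-goal).
- N₂O partitioning assumes the same two-source random-pairing logic as
  N₂ for the N₂O isotopologues; site-preference (isotopomer) analysis
  is out of scope.
- Hybrid N₂/N₂O formation is only diagnosed (a_p vs measured NO₃⁻
  enrichment mismatch), not modelled.
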