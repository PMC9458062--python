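# Methods

## Scope and model

The package implements the standard preclinical internal-dosimetry
chain for a beta-emitting radiopharmaceutical:

1. **Biokinetics.** Each region (organ, tumor, blood, or cell
   compartment) is modelled independently as a sum of 1–3 decaying
   exponentials in percent injected activity (%IA). No inter-organ
   transfer is modelled; this matches the serial-sacrifice study
   design the package targets, where each region's time–activity curve
   is fitted on its own. The biological (decay-corrected, `q`) and
   effective (`A`) representations differ only by the physical decay
   constant λR added to every rate; coefficients are shared, and
   q(t) = A(t)·e^(λR·t) holds identically.
2. **Cumulated activity.** N = ∫₀^∞ A(t) dt, evaluated in closed form
   (Σ cᵢ/λᵢ with the %IA→fraction and hour→second factors applied at
   this single boundary, giving MBq·s). An adaptive-quadrature oracle
   (`integrate_quadrature`) exists solely to cross-check the closed
   form; it integrates to 40 terminal half-lives by default, where the
   omitted tail is below 1e-10 of the total. Integrating a biological
   model is rejected: without λR the integral measures residence of a
   stable tracer, not nuclear transformations.
3. **Organ dosimetry.** D = Σ N·DF/1000 with dose factors in
   mGy/MBq·s keyed by (source, target, geometry); exact-key lookup,
   missing keys are errors rather than silent zeros. Dose is linear in
   administered activity, so extrapolation to another injected
   activity is a ratio (`scale_dose`).
4. **Cellular dosimetry.** Nucleus dose from the two single-cell
   source compartments, D_N = N_CS·S(N←CS) + N_Cy·S(N←Cy), with
   cellular S values in Gy/Bq·s keyed by nuclide, cell/nucleus radii
   and compartment.

## Radionuclide constants

¹³¹I is bundled with T½ = 192.6 h (8.0252 d), λR = 0.003599 h⁻¹. The
reference study prints effective and biological blood rates differing
by ≈ 0.004 h⁻¹ (1.524 − 1.520 and 0.033 − 0.029), which this value
reproduces; the study itself never states the half-life it used.
Internal canonical units are hours and h⁻¹ throughout; seconds appear
only in reported cumulated activities.

## Fitting

`MultiExponentialDecay` minimises the (optionally inverse-variance
weighted) sum of squared residuals. Initialisation is classical curve
peeling — fit the terminal log-linear segment, subtract, repeat for
faster phases — followed by `scipy.optimize.least_squares` (trf,
bounds cᵢ ≥ 0; rates optimised in log space, bounded to ±8 decades
around the reciprocal data span) with 5 deterministic multi-starts
(jittered peel estimates, seeded). Term-count selection under
`n_terms="auto"` uses AICc with a Gaussian likelihood. Unweighted
fitting is the default since serial-sacrifice means are homoscedastic
on no stated grounds; inverse-variance weighting is available when
per-time standard deviations exist. Data tagged decay-corrected are
fitted in the q domain, raw data in the A domain, and conversion
happens on the fitted model — samples are never pre-multiplied by
e^(λR·t), which would distort the noise structure. Coefficients are
not constrained to sum to 100 %IA at t = 0 (the blood model happens
to; organ curves need not); an optional `constrain_sum` flag provides
the constraint when wanted. Reported half-lives are rounded to
2 significant figures only in the report layer.

The reference blood model carries an internal inconsistency in its
published form: the decay-corrected formula prints a slow-phase
amplitude of 0.260 while the surrounding narrative (and the effective
model) say 10.2% of the activity. The package adopts the narrative
pair (89.8, 10.2) for both representations, which keeps
q(t) = A(t)·e^(λR·t) self-consistent; no guess is made about which
printing is the typo.

## Sampled (cellular) curves

Measured per-cell uptake rises to a peak (~3 h) and then falls, so it
is not a monotone sum of decaying exponentials from t = 0. These
curves are integrated with the trapezoid rule from (0, 0) — no
instantaneous uptake — through the last sample, plus a closed-form
tail: either a single exponential through the last two samples
(`exp_fit`, default) or physical decay of the last value
(`physical_decay`, an upper bound; also the fallback when the last two
samples do not decrease, since no washout rate is then identifiable).
How the original study integrated its 3-point curves is not stated, so
published per-cell cumulated activities are treated as inputs
downstream, never as targets of this integrator.

## Dose-factor and S-value fixtures

Genuine dose factors come from radiation-transport codes and were not
published; users supply them via the documented CSV schemas. For
testing, the package back-derives self-dose fixtures as DF = D/N from
published (cumulated activity, dose) pairs. These fixtures are
**circular**: pushing the same N through them necessarily reproduces
the published doses, which validates pipeline wiring, unit handling
(MBq·s vs Bq·s, mGy vs Gy) and nothing about transport physics. At the
cell level, the two lines sharing a stated geometry (LoVo, SW620)
yield back-derived surface S values differing by ~4% — an artifact of
the 2-decimal rounding of the printed doses, since a true S value
depends only on nuclide and geometry. The fixture therefore carries
line-specific rows (optional `cell_line` key in the S-value schema);
cross-line comparisons must tolerate ±0.005 Gy (half a printed digit).
Only self-dose is exercised by the fixtures (one source per target);
the data model supports cross-organ contributions but ships no fixture
for them.

The tumor-dose extrapolation 3.55 Gy × 74/5 = 52.54 Gy is reported at
full precision; the study prints 52 Gy without stating its rounding
rule, so consistency checks assert ≥ 52.

## Synthetic data

`simulate_biodistribution` emulates a serial-sacrifice biodistribution
study: default grid 0.5, 1, 3, 5, 24, 48, 92, 144 h, 3 animals per
time point, 5 MBq administered — the reference study's design. Noise
is multiplicative lognormal, mean-unbiased (ε ~ N(−σ²/2, σ²),
σ² = ln(1 + CV²), default CV 10%): simulated activities stay positive
across the two orders of magnitude %IA spans, and sample means are
unbiased for the model value (verified at 10⁴ replicates). Per-region
random streams are sub-seeded from the global seed via CRC32 of the
region name, so adding a region leaves other regions' draws untouched.
What the generator does **not** emulate: animal-level covariance
across organs (whole-body activity balance), inter-animal kinetic
variability, weighing/counting systematics, and blood-to-organ
spillover. Passing recovery tests therefore show the estimator chain
is correct and adequately powered under idealised independent
lognormal noise — not that real biodistribution data meet those
assumptions.

`simulate_cell_uptake` produces the rise-then-fall per-cell shape
a(t) = A·(1 − e^(−k_in·t))·e^(−k_out·max(0, t − t_peak)), scaled so
the peak equals a stated percentage of the exposure activity
(defaults: peak at 3 h, exposure 1.44 Bq/cell, internalized fraction
0.056 of membrane — the measured cytoplasm/membrane ratio at peak).

## Verification set-points

* Noise-free closure: simulate (CV 0) → fit → integrate → dose
  recovers ground truth to 1e-6 relative.
* Analytic vs quadrature N: 1e-8 relative over 1000 random models
  (coefficients ∈ [0.1, 100] %IA, rates ∈ [1e-3, 10] h⁻¹).
* Monte-Carlo recovery under the default design (n = 3, 8 time
  points, CV 10%, 50 replicate studies): median relative error of
  recovered rates, cumulated activity and dose below 25%; with n = 30
  the median error is strictly smaller. These sizes run in seconds.

## Known limitations

* No physiologically based compartmental transfer, no voxel/image
  dosimetry, no computation of DF/S values from emission spectra, no
  decay chains, no human extrapolation from mouse kinetics.
* Unit round trips through `convert_units` are exact to one unit in
  the last place, not bit-exact (binary floating point cannot
  represent decimal scale factors exactly).
* Asymptotic parameter standard errors come from the Jacobian at the
  optimum and are unreliable when phases are poorly separated.
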