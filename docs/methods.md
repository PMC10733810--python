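# Methods

`csfclear` implements the computational chain of a sleep-deprivation cohort
study linking overnight changes in plasma neurodegeneration biomarkers to
two imaging-derived clearance proxies: population pharmacokinetics of an
intrathecally injected MRI contrast tracer (CSF-to-blood clearance, a proxy
of meningeal-lymphatic function) and reference-normalized T1 tracer
enrichment per brain region (a proxy of glymphatic function).

## Tracer pharmacokinetics

**Structural model.** After an intrathecal dose D the tracer leaves a CSF
depot by first-order absorption (rate `ka`, lag `tlag`) into a central
plasma compartment (volume `vc`) with first-order elimination (clearance
`cl`) and distribution to one peripheral compartment (inter-compartmental
clearance `q`, volume `vp`). With micro-rates `k10 = cl/vc`, `k12 = q/vc`,
`k21 = q/vp` and disposition eigenvalues α, β
(α + β = k10 + k12 + k21, αβ = k10·k21), the plasma concentration for
τ = t − tlag > 0 is the tri-exponential

    C(τ) = (ka·D/vc) · [ (k21−α) e^{−ατ} / ((ka−α)(β−α))
                       + (k21−β) e^{−βτ} / ((ka−β)(α−β))
                       + (k21−ka) e^{−ka·τ} / ((α−ka)(β−ka)) ]

and 0 for t ≤ tlag. Because the dose is extravascular and the bioavailable
fraction is not estimable, all volumes and clearances are apparent
(F-scaled). Coincident rate constants (ka = α, ka = β, α = β) are a
measure-zero case handled by a 1e-9 relative nudge of the offending rate
rather than by the analytic limit forms; the closed form agrees with a
stiff-ODE solution of the three-state system to <1e-6 everywhere tested.

**Derived clearance metrics** (the meningeal-lymphatic proxies): absorption
half-life T½,abs = ln2/ka; AUC(0→∞) = D/cl (exact under linear kinetics
with complete absorption); Cmax and Tmax located by bracketed root-finding
on the analytic time derivative over (tlag, ∞). An independent trapezoidal
AUC with log-linear tail extrapolation (`auc_trapezoid`) serves as a
numerical cross-check, not as the estimator.

**Units.** Time in hours, dose in mmol, volumes in litres; concentrations
are therefore mmol/L per administered dose and AUC is mmol·h/L. Group
summaries for this design are conventionally reported without units for
AUC/Cmax, so only shape-level and recovery-level comparisons are
meaningful; this package never compares raw AUC/Cmax magnitudes to
externally reported ones.

**Population estimation.** Log-normal inter-individual variability (IIV) on
`ka`, `cl`, `vc` only — a cohort of a few dozen subjects with ~7 samples
each cannot support random effects on all six parameters — with `tlag`,
`q`, `vp` as typical values, and proportional residual error
y = f·(1 + σε). The marginal likelihood is a Laplace approximation: for
each subject the 3-dimensional random-effect mode is found by a vectorized
damped Newton iteration with Gauss-Newton curvature (FOCE-I-style), and
−2 log L sums the joint density at the mode plus half the log-determinant
of the curvature. Numerical safeguards that proved necessary in testing:

* warm-started inner solves fall back to η = 0 whenever the warm start ends
  worse than the prior mode (a stale warm start must never poison the
  objective);
* predicted concentrations are floored at 1e-8·max(y) inside the
  proportional-error density so pre-lag samples cannot produce infinities;
* the outer optimization (L-BFGS-B on log-transformed parameters, bounds on
  all ten, Nelder-Mead polish on failure) is multi-started over
  ka × {1, ½, 2} plus a pooled-curve start, because the depot model's
  flip-flop ambiguity (absorption vs disposition rates) creates separated
  likelihood basins. Typical values are initialized from the elementwise
  median of quick per-subject fits — robust to the occasional wild
  individual fit — rather than from a fit to the pooled mean curve, which
  systematically distorts the curve shape.

Standard errors of the typical values, when requested, come from a
finite-difference Hessian of −2 log L with delta-method transformation to
the natural scale. Single-subject fits (`fit_individual`) are weighted
least squares on the proportional-error scale with five seeded multi-starts
(best objective wins; ties broken by the smaller parameter-vector norm) and
reproduce noise-free curves to ~1e-14 relative.

## Tracer enrichment

The T1-weighted greyscale is rescaled by the scanner between acquisitions,
so each ROI signal is divided by the same scan's reference-ROI signal
(posterior orbit, tracer-free): the *normalized T1 signal unit*. Tracer
enrichment is the percent increase of the normalized unit over the
pre-injection baseline (t = 0), summarized in five bins. The bin windows —
observations in [0, 4) h and [4, 8] h, nearest-observation windows of
±6 h around 24 h and 48 h, ±72 h around 4 weeks (672 h) — are this
package's convention; the usual figure presentation labels these bins
without stating assignment rules. Missing bins are reported as missing, never imputed, and
no interpolation across scan times is performed. Normalization exactness:
multiplicative per-scan drift cancels to floating tolerance (bit-exactly
for power-of-two rescalings; IEEE-754 rounding admits ~1-ulp differences
for arbitrary factors).

## Biomarker statistics

* **Overnight change**: mean Day-2 minus mean Day-1 concentration per
  subject and biomarker, using all draws of each day without time-of-day
  matching; combinations missing a day are dropped with a warning.
* **Random-intercept linear mixed models**, fitted by profiled maximum
  likelihood (Woodbury identities per subject; Nelder-Mead over the one or
  two log-variance parameters). Residual variance can be stratified by
  follow-up day; by default the stratified model is adopted only when a
  likelihood-ratio test at α = 0.05 favours it. Fixed-effect inference is
  Wald z, two-tailed; with the ~200 observations of this design z vs t is
  immaterial. The implementation matches `statsmodels` MixedLM (ML) to
  ~1e-5 on shared models and degenerates to OLS when the intercept variance
  hits zero.
* **Day-2 group comparison adjusted for Day 1**: a constrained-baseline
  model (common Day-1 mean, day effect, group-specific additional day
  effect). The group-specific day coefficient *is* the adjusted Day-2
  contrast. This uses every observation rather than per-subject baseline
  subtraction.
* **Group × day interaction**: the full factorial fixed-effect model.
* **FP1 regression** of concentration on clock time: one power from
  {−2, −1, −0.5, 0 (= ln), 0.5, 1, 2, 3} chosen by maximum likelihood, with
  cluster-robust (sandwich) standard errors over subjects because draws of
  the same subject are correlated; 95% prediction bands from the robust
  covariance. With the power fixed at 1 this is exactly ordinary linear
  regression.
* **Pearson panels**: one point per subject (repeated draws never enter a
  correlation twice), computed separately per intervention group, two-tailed
  t-based p with n−2 df; validated against a permutation oracle.
* All p-values are unadjusted for multiplicity; 0.05 two-tailed is a
  reporting threshold, never a data filter. For the Aβ42/Aβ40 ratio the
  report carries both the mean of per-subject ratios and the ratio of group
  means, labelled, since either convention is defensible.

## Synthetic cohort

No subject-level data are deposited for this design, so a seeded generator
(single `numpy` PCG64 stream; bit-reproducible per seed) emulates the
study: 21 free-sleep and 7 sleep-deprived subjects; covariates drawn around
the reported group descriptives; a 0.5 mmol intrathecal dose with blood
samples at 0, 2, 4, 6, 8, 24, 32, 48 h; MRI at 0, 2, 6, 24, 48, 672 h;
four biomarker draws per study day. Defaults that matter:

* **PK typicals** ka = 0.198 h⁻¹ (T½,abs 3.5 h), tlag = 0.8 h, cl = 1.6,
  vc = 17, q = 2.0, vp = 10 — chosen to give Tmax ≈ 7 h with a terminal
  half-life (~13 h) the 48-h sampling window can actually support. A deeper
  peripheral compartment reproduces Tmax equally well but makes ka
  genuinely non-identifiable at this schedule (the MLE sits ~40% off with a
  decisively better likelihood), so it was rejected at design time. IIV 20%
  on ka/cl/vc, 10% proportional error.
* **Biomarker means** (pg/mL) follow the reported group summaries: Day-1
  means shared between groups; the deprivation group's Day-2 Aβ40 and Aβ42
  reduced (91.6→79.6, 6.3→5.5); P-Tau181, GFAP and NfL carry no day effect.
  Between-subject SDs are back-computed from the reported standard errors
  (SE·√n); within-day SDs and the per-subject overnight-change SD
  (`overnight_sd`) are plausibility choices. These defaults are
  configuration for realism, not truth claims.
* **Overnight heterogeneity.** `overnight_sd` is a per-subject random Day-2
  effect. It is what the correlation links attach to (a pure random
  intercept cancels in Day 2 − Day 1). It also lies outside the
  random-intercept model class, so the null generator used for
  type-I-error calibration zeroes it along with all group effects and
  links: in a null world nothing happens overnight, and the calibration
  then measures the test's true size (0.05 ± 0.02 over 500 replicates).
* **Cross-links.** The AUC↔ΔAβ link (sleep group) and the cortical
  24-h-enrichment↔ΔP-Tau181 link (deprivation group) are induced through
  shared latent Gaussian factors. The latent correlation is calibrated
  analytically so the *measured* quantities hit the target r in
  expectation: the lognormal factor a/√(e^{a²}−1) for AUC = D/cl (lognormal
  in −log cl), and attenuation factors σ_signal/√(σ_signal² + σ_noise²)
  for the sampling noise in measured overnight change and the per-scan
  noise in measured enrichment. Verified to within 0.03 at n = 2000.
* **Scanner drift.** Every scan of a subject gets one multiplicative
  log-normal greyscale factor applied to all its ROIs including the
  reference, so the normalization step is genuinely exercised.

What the generator does **not** emulate: circadian secretion dynamics
within a day (day-level means only), assay batch effects, correlated
Aβ40/Aβ42 measurement errors, dropout/missingness patterns, non-normal
biomarker noise (additive Gaussian truncated at zero is used; at the
reported coefficients of variation the normal/log-normal distinction is
immaterial), and any structural mechanism behind the correlation links
(such designs report correlations, not mechanisms). Passing
recovery tests on these cohorts therefore demonstrates correctness of the
estimators under the stated model, not robustness to real-data pathology.

## Pipeline

`run()` validates the four input TSVs (schema errors name file, column and
rows; unknown columns warn), fits the population PK model, computes
enrichment, appends per-draw Aβ42/Aβ40 ratio rows, and assembles the
report: Day-2 summary with adjusted contrasts and interactions per
biomarker, clearance-parameter group summaries, per-region enrichment
summaries, FP1 daytime-course fits, and Pearson panels of {AUC, T½,abs,
four regional 24-h enrichments} × {six biomarkers} × {two groups}. T½,abs
replaces lag time as the second PK index because lag time carries no IIV
in this model and is therefore constant across subjects. Reports store
unrounded values plus display-rounded twins (1 dp concentrations, 3 dp
ratios) and full provenance (config hash, seed, version); two runs with
the same seed produce byte-identical JSON.

## Problem sizes and calibration designs

Simulation-based checks use sizes chosen to make their Monte-Carlo error
small relative to the tolerance being asserted: population-PK recovery at
n = 100 subjects × 8 draws × 3 seeds (bias assessed as the mean across
seeds — a single replicate conflates bias with estimator scatter, which is
~2% SE for cl and ~6% for ka at this design); type-I calibration over 500
null cohorts (binomial SE ≈ 0.01); FP1 selection over 200 replicates of
n = 112 draws from 90 + 10·ln t + N(0, 2) with t uniform on [1, 24] h — an
a-priori signal-to-noise calculation gives a ≥7σ likelihood gap to the
nearest competing power, so selection failures indicate machinery bugs,
not noise; link calibration at n = 2000 (SE of r ≈ 0.008).

## Known limitations

* Population PK models for this tracer are described in the literature only
  at the level of their compartment structure; the realization used here
  (one depot, two disposition compartments, IIV on ka/cl/vc) is one
  consistent choice, not a claim about any previously fitted model.
* Empirical-Bayes AUC estimates are shrunk toward the typical value, so
  correlation panels computed from fitted (rather than true) parameters are
  mildly attenuated relative to the configured link targets.
* The Wald z inference of the mixed models is anticonservative when
  subject-level day-2 heterogeneity is present but unmodelled — visible in
  effect cohorts with `overnight_sd` > 0 — which is a limit of the
  random-intercept model class itself, not a bug; the calibration suite
  quantifies the test's size only under the within-class null.
* `fit_population` assumes a common dose per subject mapping and at least
  five usable post-injection samples per subject; richer designs (covariate
  effects on PK, full Bayesian posteriors) are out of scope.

## Appendix: cohort configuration reference

`CohortConfig` round-trips through YAML (`simulate --config cohort.yaml`).
Every field, with its default:

| field | default | meaning |
|---|---|---|
| `n_sleep`, `n_deprived` | 21, 7 | group sizes |
| `seed` | 0 | PCG64 seed for every random draw |
| `pk_typical` | ka 0.198, tlag 0.8, cl 1.6, vc 17, q 2.0, vp 10, dose 0.5 | typical PK parameters (h, L, L/h, mmol) |
| `pk_iiv_sd` | 0.2 each for ka, cl, vc | SD of log-normal inter-individual effects |
| `sigma_prop` | 0.1 | proportional residual error of plasma tracer samples |
| `biomarker_day_means` | per biomarker x group x day table | mean concentrations, pg/mL |
| `between_subject_sd` | AB40 8.0, AB42 0.45, PTAU181 2.2, GFAP 10.5, NFL 0.9 | subject random-intercept SD, pg/mL |
| `within_subject_sd` | AB40 3.0, AB42 0.2, PTAU181 0.5, GFAP 3.0, NFL 0.4 | per-draw noise SD, pg/mL |
| `overnight_sd` | AB40 5.0, AB42 0.35, PTAU181 0.8, GFAP 4.0, NFL 0.5 | per-subject overnight-change SD, pg/mL |
| `link_auc_dab` | 0.7 | target Pearson r, AUC vs overnight dAβ (sleep group) |
| `link_cortex_dptau` | 0.7 | target Pearson r, 24 h cortical enrichment vs dP-Tau181 (deprivation group) |
| `enrichment_profiles` | per region x group x bin table | mean percent change from baseline |
| `enrichment_subject_sd` | 4.0 | per-subject/region enrichment shift, percentage points |
| `enrichment_meas_sd` | 1.5 | per-scan enrichment noise, percentage points |
| `scanner_drift_sd` | 0.1 | SD of the log multiplicative per-scan greyscale factor |
| `reference_signal` | 1000 | reference-orbit ROI greyscale level |
| `baseline_ratio` | cortex 1.2, white matter 1.5, dura 0.9, CSF 0.4 | baseline normalized unit per region |
| `blood_times` | 0, 2, 4, 6, 8, 24, 32, 48 h | plasma tracer sampling schedule (post-injection) |
| `mri_times` | 0, 2, 6, 24, 48, 672 h | MRI scan schedule (post-injection) |
| `clock_times` | Day 1: 9, 12, 15, 18 h; Day 2: 7, 9, 11, 13 h | biomarker draw clock times |
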