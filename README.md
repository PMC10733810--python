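# csfclear

Analysis toolkit for cohort studies of sleep, CSF clearance and plasma
neurodegeneration biomarkers. The scientific question it serves: when one
night of total sleep deprivation changes plasma concentrations of Aβ40,
Aβ42, P-Tau181, GFAP or NfL, is that change explained by the capacity of
the meningeal-lymphatic route (how fast an intrathecally injected CSF
tracer reaches blood) or by glymphatic function (how strongly the tracer
enriches brain tissue on MRI)?

The package is aimed at pharmacometricians and biostatisticians working
with intrathecal contrast-enhanced MRI designs. It provides:

* **`csfclear.pk`** — a depot + two-compartment model of tracer plasma
  kinetics: closed-form tri-exponential concentration
  C(τ) ∝ Σᵢ Aᵢ e^(−λᵢτ) with first-order absorption `ka`, lag `tlag`,
  central elimination `cl/vc` and peripheral distribution `q`, `vp`;
  derived clearance metrics T½,abs = ln2/ka, AUC = D/cl, Cmax, Tmax;
  single-subject weighted least squares; and a nonlinear mixed-effects
  population fit (log-normal IIV on ka/cl/vc, proportional error, Laplace
  approximation, empirical-Bayes per-subject estimates).
* **`csfclear.enrichment`** — normalized T1 signal units (ROI signal
  divided by the same scan's reference-orbit signal, cancelling scanner
  greyscale rescaling), percent change from the pre-injection baseline,
  and binning into 0–4 h, 4–8 h, 24 h, 48 h and 4 weeks.
* **`csfclear.stats`** — per-subject overnight change (mean Day 2 − mean
  Day 1); random-intercept linear mixed models by maximum likelihood with
  optionally day-stratified residual variances; the Day-1-adjusted Day-2
  group contrast; group×day interaction; degree-one fractional-polynomial
  (FP1) time-of-day regression with cluster-robust standard errors; and
  per-group Pearson correlation panels.
* **`csfclear.cohort`** — a seeded synthetic-cohort generator reproducing
  the study design (21 sleep / 7 sleep-deprived subjects, sampling
  schedules, group×day mean structure, scanner drift, calibrated
  correlation links) with ground truth for recovery testing.
* **`csfclear.pipeline` / CLI** — end-to-end orchestration with schema
  validation and a reproducible JSON/CSV results bundle.

See `docs/methods.md` for the model details and design decisions.

## Worked example

Simulate the default cohort and run the whole analysis:

```python
from csfclear import run

report = run(simulate=True, seed=7)

c = report.table2_like["AB40"]["day2_contrast"]
print(c["estimate"], c["p"])          # -12.92  9.6e-31
print(report.panels["auc|AB40|sleep"])
```

With seed 7 the Day-2 comparison table (group mean ± SE, Day-1-adjusted
contrast) reads:

| biomarker | sleep | deprivation | contrast | p |
|---|---|---|---|---|
| Aβ40 (pg/mL) | 92.9 ± 2.2 | 76.6 ± 3.5 | −12.92 | 9.6e-31 |
| Aβ42 (pg/mL) | 6.3 ± 0.1 | 5.7 ± 0.2 | −0.82 | 2.2e-30 |
| Aβ42/Aβ40 | 0.068 ± 0.002 | 0.075 ± 0.003 | ~0 | 0.21 |
| P-Tau181 (pg/mL) | 3.3 ± 0.4 | 3.7 ± 0.9 | −0.45 | 0.025 |

The generator programs a Day-2 amyloid reduction in the deprivation group
and no ratio effect, and the adjusted contrasts recover exactly that
pattern. The correlation panels show the programmed group-specific links:
tracer AUC vs overnight ΔAβ40 gives r = 0.51 (p = 0.018, n = 21) in the
sleep group but is non-significant in the deprivation group (r = 0.46,
p = 0.30, n = 7), while 24-h cortical enrichment vs ΔP-Tau181 gives
r = 0.84 (p = 0.018, n = 7) in the deprivation group only. The fitted
population PK model yields sleep-group T½,abs 4.5 ± 1.0 h and Tmax 7.8 h
(generating values 3.5 h and ~7 h; n = 21 empirical-Bayes estimates).

From the shell:

```bash
csfclear run-all --out-dir results/demo --seed 7
csfclear simulate --out-dir data/ --seed 3
csfclear validate --input-dir data/
csfclear fit-pk --obs data/pk_observations.tsv --dose-mmol 0.5 \
         --out pk_fit.json --seed 3
csfclear analyze --input-dir data/ --out-dir results/from_files
```

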