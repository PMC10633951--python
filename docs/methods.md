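# Methods

`lacodose` is a Monte Carlo dose-finding simulator for intravenous
lacosamide in critically ill adults receiving continuous renal replacement
therapy (CRRT). It answers the question a prescriber faces at the bedside:
for a given CRRT prescription (modality and effluent dose), which
maintenance regimen keeps most patients inside the therapeutic window over
the first 72 hours of seizure management?

## Model

### Virtual patients

Each virtual patient is a draw of four parameters from independent
truncated normal distributions fitted to published pharmacokinetic data in
adult CRRT patients:

| parameter | mean ± SD | limits | unit |
|---|---|---|---|
| body weight | 75.40 ± 18.40 | (40, ∞) | kg |
| volume of distribution | 0.61 ± 0.12 | [0.40, 1.00] | L/kg |
| non-renal clearance CL_NR | 16.60 ± 6.09 | [3.33, 26.67] | mL/min |
| sieving/saturation coefficient SC/SA | 0.78 ± 0.08 | [0, 1] | — |

The 40-kg floor restricts the cohort to adult-sized patients; the
extraction coefficient is a fraction and bounded in [0, 1]. Sampling is by
inverse CDF on the truncated marginal, so `sd = 0` degenerates exactly to
the mean and no rejection loop is needed. One SC/SA distribution serves
both modalities because no dialysis-specific saturation coefficient has
been published for lacosamide.

Correlations among weight, Vd/kg and CL_NR are known to exist in this
population but their values are not published, so the default is
independence. A user-supplied latent correlation matrix is applied as a
Gaussian copula: correlated standard normals are mapped through Φ and then
through each truncated marginal's inverse CDF. This preserves the exact
truncated marginals (unlike truncating after correlating) at the cost of
the correlation being specified on the latent, not the observed, scale;
for the moderate correlations plausible here the two differ by little.
Total Vd is always `vd_per_kg × weight` at use time — it is never sampled
separately from weight.

### CRRT clearance

Extracorporeal clearance follows standard transmembrane-clearance
equations with all flows in L/h:

* CVVHD (diffusive): `CL_HD = SA · Qd`
* pre-dilution CVVH (convective):
  `CL_HF = SC · Quf · Qp / (Qp + Qrep)`, with `Qrep = Quf` and plasma flow
  `Qp = Qblood · (1 − hematocrit)`

The effluent flow (`Qd` or `Quf`) is the prescribed effluent dose (20, 25
or 35 mL/kg/h) times the patient's weight. Defaults: blood flow
200 mL/min, hematocrit 30%. The pre-dilution factor `Qp/(Qp + Quf) < 1` is
why CVVH clears strictly less than CVVHD at the same effluent dose.
Patients are assumed anuric (native renal clearance 0); a
`renal_clearance_l_h` override exists for sensitivity analyses. Total
clearance is `CL_CRRT + CL_NR` and the elimination rate constant is
`k = CL_total / Vd`.

### Kinetics

Lacosamide is linear and one-compartment. Doses are instantaneous IV
boluses (no published infusion duration to emulate), so the
concentration–time profile is the closed-form superposition
`C(t) = Σ_i (D_i/Vd) e^{−k (t − t_i)}` over doses given before `t`.
Troughs use a pre-dose convention: a query at an exact dose time excludes
that dose. Windowed AUCs are the analytic integral of the superposition,
with the `k = 0` limit handled exactly; the analytic path is tested
against adaptive quadrature to 1e-6 relative on randomized schedules.

### Target classification

Three pharmacodynamic targets, bounds inclusive:

* trough 5–10 mg/L (maintenance-equivalent 200–400 mg/day),
* AUC per 24 h of 80.25–143 mg·h/L (standard exposure),
* AUC per 24 h of 143–231 mg·h/L (high exposure, 400–600 mg/day).

Each patient is classified below / in / above. Two evaluation conventions
are implemented:

* **exposure_summary** (default): one classification per patient on a
  72-h exposure summary — the steady-state trough
  `(D/Vd)·e^{−kτ}/(1−e^{−kτ})` for trough targets, and the mean daily AUC
  (AUC over [0, 72] divided by 3, transient superposition including any
  loading dose) for AUC targets. This convention reproduces the published
  PTA grid this package re-derives: across all 126 grid cells it agrees
  with the reference values to within 10 percentage points under
  independence, with most cells within 2–5.
* **daily_average**: the transient day-1/2/3 metrics (troughs at 24/48/72
  h; AUCs over [0,24], [24,48], [48,72]) are classified separately and the
  three daily percentage triples averaged. This reading penalises the
  pre-accumulation day-1 trough heavily (15–25 points more below-range for
  regimens without a loading dose) and does not reproduce the reference
  grid; it is retained because it is the natural transient reading and
  useful for studying accumulation.

Every PTA summary carries the per-day transient classification regardless
of mode, so the accumulation structure stays inspectable.

### Monte Carlo PTA and optimal doses

Each (prescription, regimen) cell is evaluated in a fresh cohort of
10,000 virtual patients — each dose is tested in its own patient group —
with sub-seeds derived from the master seed by SHA-256 over the scenario
labels, so results are independent of execution order and reproducible
bit-for-bit. A `share_cohort` mode reuses one cohort across the grid for
variance-reduced paired comparisons. At n = 10,000 the binomial standard
error of a PTA cell is at most 0.5 percentage points.

The optimal regimen for a scenario maximises average in-range PTA;
regimens within a 5-percentage-point tie margin of the maximum are
candidates, resolved toward the lowest total daily maintenance dose, then
fewer administrations per day, then catalog order. The 5-pp margin is the
smallest value consistent with the reference optimal-dose grid (it is what
lets 450 mg/day beat 600 mg/day at CVVHD 25 mL/kg/h despite a ~3-pp PTA
deficit) and is configurable. Because our independence model widens that
particular PTA gap to almost exactly 5 pp, the CVVHD@25 selection is
seed-sensitive: some Monte Carlo seeds return 600 mg/day instead of 450.

### Weight effect

The attainment analysis stratifies a 10,000-patient simulated cohort into
weight bins (`[40,60), [60,70], (70,80], …, (140,∞)` — boundaries chosen
so the published labels partition the axis) and computes, per bin, the
risk ratio of *not* attaining the target for patients outside the bin
versus inside it (the bin is the reference group), with Wald 95%
confidence intervals on the log scale using the exact 97.5% normal
quantile. The packaged reference count table reproduces every computable
published RR and CI to the printed precision. A patient "attains" by
default iff its day-3 metric is in range; an all-days rule is available.
Which scenario generated the reference counts is not documented, so
`run_study` defaults to CVVHD at 25 mL/kg/h with 150 mg q8h against the
trough target — the optimal regimen at the guideline-standard effluent
dose — and writes the reference-count table alongside for comparison. A
log-binomial GLM (binomial family, log link, via statsmodels) generalises
the 2×2 ratio to arbitrary covariates; on a single bin indicator it agrees
with the closed form to 1e-6 relative, and non-convergence (a known
hazard of log-link binomial models) raises with a diagnostic pointing
back to the closed form.

## What the generator does and does not emulate

The virtual cohort emulates marginal population variability in weight,
distribution volume, residual clearance and membrane transport, truncated
to physiologic ranges. It does not emulate: inter-parameter correlations
(unpublished; hook provided), within-patient time-varying PK, CRRT
downtime or filter clotting, residual native renal function, protein
binding changes, or adsorption to the filter membrane. Passing tests
therefore demonstrate fidelity to the stated population model, not
predictive accuracy for an individual patient; dosing conclusions apply
to anuric adults matching the source distributions.

## Numerical choices

* All clearance arithmetic in L/h; mL/min inputs convert on entry
  (× 60/1000). A unit-audit test checks the mL/min path agrees to 1e-12.
* Truncated-normal quantiles come from `scipy.stats.truncnorm`; sampled
  values are clipped to the open interval by one ULP so limits are never
  attained exactly.
* Classification bounds are inclusive on both ends ("within a range").
* `k = 0` is handled by exact limits (linear AUC accumulation, infinite
  steady-state trough → classified above range).
* Problem sizes: study tables use 10,000 patients per regimen (the design
  size); unit and property tests use 50–50,000 where the assertion's
  tolerance dictates.

## Known limitations

* The unpublished parameter correlations are the dominant unknown; the
  largest observed disagreement with the reference grid (≈9 pp, CVVHD at
  35 mL/kg/h, 150 mg q8h, trough) is consistent with that gap.
* The adjusted (covariate-controlled) risk ratios of the reference
  analysis cannot be reproduced because the adjustment set was never
  published; the GLM is provided for user-declared covariates instead.
* Only pre-dilution CVVH and CVVHD are modelled; post-dilution CVVH and
  CVVHDF are out of scope.
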