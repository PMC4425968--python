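# Methods

## Derived hemodynamics

All public interfaces take pressures in mmHg, cardiac output (CO) in
L·min⁻¹ and heart rate (HR) in beats·min⁻¹. Internally, resistance
converts to mmHg·s·mL⁻¹ by the exact factor 0.06 (60 s/min ÷ 1000 mL/L)
and flow converts to mL·s⁻¹ for power. Per record:

* SV = CO·1000/HR (mL); PP = sPAP − dPAP (mmHg); Ca = SV/PP (mL·mmHg⁻¹).
  The SV/PP estimator is an upper bound on true compliance (it assumes the
  proximal arteries receive the whole stroke volume) but requires no
  pressure waveform, which is the point: the package operates on tabulated
  measurements only.
* PVR = (mPAP − PCWP)/CO and TPR = mPAP/CO, in Wood units or ×0.06 in
  mmHg·s·mL⁻¹. A record with mPAP < PCWP yields negative PVR, returned
  with a warning rather than an exception — exclusion policy belongs to
  the cohort layer, not the formula layer.
* RC time = resistance (mmHg·s·mL⁻¹) × Ca (s), computed for both PVR and
  TPR. TPR-derived RC dominates PVR-derived RC, with equality exactly at
  PCWP = 0.
* RV hydraulic power uses mean flow q = CO·1000/60 mL·s⁻¹:
  W_mean = mPAP·q/7500, W_total = sPAP·q/7500, W_osc = W_total − W_mean
  (watts; 1 W = 7500 mmHg·mL·s⁻¹). The additive identity is exact by
  construction and the oscillatory fraction equals 1 − mPAP/sPAP, so the
  "wasted"-power fraction is a pure function of the pressure ratio. This
  mean-flow formulation reproduces a published RV power table from its
  cohort's group means (0.16/0.09/0.25 W and 34%/39% fractions), which is
  the package's validation of the reconstruction.
* The corrected oscillatory fraction k·W_osc/(W_mean + k·W_osc) accounts
  for systolic pressure not being constant throughout systole. The scale
  factor k is deliberately a required argument with no default: published
  analyses cite such a correction without printing the factor, and
  calibrating k so a healthy-range group-mean fraction equals 21% gives
  k ≈ 0.51 — shipped as a test, not as a constant.
* `rc_from_summary` composes SV → Ca → resistance → RC on *group-level
  summary statistics*. In PVR mode CO cancels algebraically
  (RC = 60·(mPAP − PCWP)/(HR·PP)), which is why an RC time can be
  re-derived from published healthy-volunteer reviews that report no
  usable CO. Composing group means is not the same as averaging per-record
  RC times; the cohort summaries therefore always average per-record
  values, and the summary-composition helper is reserved for published
  tables.

## Cohort selection

The classifier reproduces a standard selection tree, in order: (1) records
with incomplete or nonpositive core measurements are excluded; (2) records
with a negative diastolic pressure gradient (DPG = dPAP − PCWP < 0) are
excluded — this rule can be disabled to run the sensitivity analysis that
keeps them; (3) records with PCWP > 15 mmHg (inclusive gate at 15) are
excluded; (4) a record is NPH when every bounded parameter lies within
mean ± 2 SD of published healthy reference values (sPAP 20.81 ± 4.4,
dPAP 8.75 ± 3.01, mPAP 13.95 ± 3.27, PCWP 7.97 ± 2.85 mmHg, HR 76 ± 14
bpm, CI 4.1 ± 1.26 L·min⁻¹·m⁻²), with "outside" read as strict
inequality; (5) otherwise PAH when mPAP ≥ 25 mmHg, PCWP ≤ 15 mmHg and
PVR > 3 Wood units (each clause toggleable, since hemodynamic definitions
get revised); (6) otherwise OTHER. The cardiac-index bound requires body
surface area, which minimal datasets lack: by default the CI criterion is
skipped and the result annotated `CI-unchecked`; a strict mode demotes
such records from NPH instead. Every EXCLUDED/OTHER outcome lists the
rules that fired with the offending values, so exclusion tallies are
auditable record by record, and the labels partition the cohort exactly.

## Inverse compliance model and inference

The headline model is Ca = a/(b + R) + ε with R the resistance in Wood
units. Both groups enter one fit; an indicator for the PAH group frees the
parameters per group, either sharing the numerator (parameters a, b_NPH,
b_PAH) or not (a and b per group). Fitting is trust-region nonlinear least
squares with the offset bounded b > −min(R) + 10⁻³ so the fitted curve
stays finite on the observed range. Starts combine a moment-style guess
a₀ = median(y)·(median(x)+1) with a coarse grid b₀ ∈ {0.1, 0.5, 1, 1.5, 2},
keeping the best start; convergence is a relative cost change below 10⁻¹⁰
within a 200-iteration budget (both configurable), and non-convergence
raises with the last iterate attached. Reported inference: residual
standard error √(RSS/(n − p)), and Wald standard errors / two-sided t
p-values from the Jacobian at the solution (n − p df).

Model selection compares candidates — the shared- and free-numerator
inverse forms plus a/R + c and a·e^(−bR) + c, a minimal zoo spanning the
inverse and exponential families — by smaller residual standard error,
breaking exact ties toward fewer parameters, then first-listed. Group
differences are tested by the extra-sum-of-squares F-test
F = ((RSS_pooled − RSS_grouped)/Δp)/(RSS_grouped/(n − p_grouped)); the
implementation cross-checks RSS against direct residual summation and
refuses non-nested or different-response inputs. Simple linear relations
(RC vs mPAP, mPAP vs sPAP, oscillatory fraction vs RC) go through ordinary
least squares with r² and a slope t-test; per-group lines plus the same
F-test machinery test whether those relations differ between groups.

## Group comparison and design statistics

The Wilcoxon rank-sum test reports the rank sum of the first sample
(midranks under ties). With n₁ + n₂ ≤ 12 and no ties the null is evaluated
exactly; otherwise a normal approximation with tie-corrected variance and
(by default) a continuity correction is used. The exact/approximate
crossover at 12 and the default continuity correction are package
decisions; both are arguments. No multiple-testing correction is applied
anywhere — cohort tables report per-row p-values as-is, mirroring how such
tables are conventionally presented — and summary statistics are
mean ± SD with the n − 1 denominator.

Power and sample size for a two-sample comparison of means follow the
normal-approximation convention of Stata's `sampsi`: two-sided, unequal
SDs and group sizes, power = Φ(δ/se − z₁₋α/₂) + Φ(−δ/se − z₁₋α/₂) with
se = √(σ₁²/n₁ + σ₂²/n₂), which equals α exactly at zero effect. A
noncentral-t (Welch df) variant sits behind `use_t=True`. Sample size is
the smallest integer n per group whose computed power reaches the target —
an integer search seeded at the closed form, so the round trip
power(sample_size(d)) ≥ target, power(n−1) < target holds by construction.
The test suite checks the analytic power against Monte-Carlo simulation of
the Welch z-test within 0.01; simulated designs use n ≥ 50 per arm so the
estimated-vs-known-SD gap of the simulated test stays well inside that
band.

## Synthetic cohort generator

The generator emulates the *statistical shape* of a catheterization
database split into an NPH and a PAH group: group marginals matching a
cohort-characteristics table, physiologic orderings, and an inverse
compliance–resistance link. Design choices, in order of consequence:

* **Moment-matched truncated marginals.** Each directly drawn field
  (mPAP, PCWP, CO, HR, age, the mPAP/sPAP ratio, DPG) is a truncated
  normal whose *truncated* mean and SD equal the spec values; the
  underlying location/scale are solved numerically. Truncation bounds
  encode the selection that defines each group (NPH fields truncated at
  the published ±2 SD healthy bounds; PAH mPAP at the defining 25 mmHg
  floor; PCWP at the study-wide 15 mmHg gate), so a selected population's
  printed moments are reproduced, not the unselected parent's.
* **Pressure closure by construction, not rejection.** sPAP = mPAP/ratio
  with ratio < 1, and dPAP = PCWP + DPG with DPG ≥ 0 drawn below
  mPAP − PCWP. Every ordering constraint (sPAP > mPAP > dPAP ≥ PCWP,
  non-negative DPG) then holds without rejecting records, which is what
  keeps the drawn marginals unbiased — rejection sampling on derived
  pressures measurably shifts the drawn means. The DPG spec's SD is
  √(sd²_dPAP − sd²_PCWP), so the implied dPAP marginal reproduces the
  table's dPAP mean and SD under an independent gradient; the high
  implied PCWP–dPAP correlation (≈0.95 in the healthy-range group) is the
  plausible signature of a population already selected for DPG ≥ 0. A
  record is replaced wholesale only when mPAP ≤ PCWP (no valid gradient),
  well under 1% of draws.
* **Compliance link and CO rescaling.** Ca is drawn from
  a/(b + PVR_Wood) + ε at the PVR implied by the drawn CO, with ε a
  truncated Gaussian (default SD 0.3 mL·mmHg⁻¹, chosen so the back-solved
  CO spread matches the emulated table's CO SD; floor Ca > 0.1). CO is
  then rescaled once so SV/PP equals the drawn Ca. A single pass is
  deliberate: iterating to exact self-consistency has no real solution in
  the healthy-range regime for compliance noise below about −0.04, so the
  fixed point does not generally exist. The price is that the record's
  final PVR differs from the drawing-basis PVR; the generator reports the
  resulting mean absolute link residual and exposes the basis PVR and
  drawn Ca in its diagnostics (on which the zero-noise link is recovered
  exactly by the model layer). Consequences: the rescaled CO is not an
  independently drawn marginal, and fits of Ca against *record-derived*
  PVR see attenuation from the basis/final PVR discrepancy — parameter
  recovery claims are therefore made on the regression-fixture generator,
  which produces (x, y, group) directly from the stated curve.
* **Selection on resistance.** The PAH spec enforces the PVR > 3 Wood
  units clause by bounding the compliance noise above at the value where
  the rescaled record's PVR would cross the floor — emulating a cohort
  selected on measured PVR without touching any drawn marginal.
* **Seeds are mandatory** (argument or spec field); identical (spec, seed)
  gives byte-identical cohorts.

Default specs: NPH n = 156 (mPAP 16.0 ± 2.3, ratio 0.66 ± 0.08,
PCWP 7.8 ± 2.3, CO 4.6 ± 1.0, HR 75.2 ± 13.2, age 53.3 ± 13.1, DPG
2.0 ± 0.69, link a = 10.4, b = 0.5) and PAH n = 717 (mPAP 41.1 ± 12.0
truncated ≥ 25, ratio 0.61 ± 0.06, PCWP 10.5 ± 2.9, CO 4.3 ± 1.3,
HR 78.5 ± 13.3, age 60.4 ± 14.6, DPG 14.9 ± 8.2, link b = 0.8,
PVR floor 3).

**What the generator does not emulate.** Only the marginal moments and the
compliance link are controlled; the full joint correlation structure of
real hemodynamics (severity gradients coupling pressures, flow and age) is
not, beyond what the closure induces. The healthy-range group's sPAP
spread comes out slightly wider than the emulated table (the price of an
independent ratio draw), so roughly 13% of NPH-spec records land outside
the ±2 SD selection bounds on derived sPAP/dPAP and classify OTHER —
the generator's classification-fidelity tests gate at ≥80% (NPH) and
≥95% (PAH). Passing tests on these cohorts demonstrates the pipeline's
correctness and calibration, not distributional realism of any specific
patient population.

## Problem sizes in tests and the acceptance script

Deterministic checks run on group means (n = 1). Stochastic checks use:
synthetic cohorts of 1000 per group for moment/classification gates and
156/717 (the emulated cohort sizes) for pipeline runs; 200 replicate fits
at noise SD 0.3 with 150/700 points per group for inverse-model recovery
and the F-test rejection rate (the acceptance script uses 100 replicates);
10,000 null simulations at n = 20 per arm for rank-sum type-I calibration;
50,000 simulated trials per design for Monte-Carlo power agreement. These
sizes give Monte-Carlo standard errors comfortably below every asserted
tolerance.

## Known limitations

* No waveform analysis: compliance is SV/PP only (no pulse-pressure-method
  estimate), there is no dicrotic-notch or time-domain RC estimation, and
  the oscillatory-power formulation assumes constant systolic pressure
  unless the caller supplies the correction factor k.
* The exact printed form of the correction factor used in published work
  is not known to the package; k ≈ 0.51 is a calibration, not a citation.
* Exact reproduction of any real cohort's fitted coefficients is out of
  reach without patient-level data; published coefficients serve as
  generating parameters whose recovery the tests verify.
* The rank-sum exact null is limited to tie-free samples; ties always
  route to the corrected normal approximation regardless of size.
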