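# rctime

Pulmonary afterload analysis for right-heart-catheterization (RHC) cohorts:
derived hemodynamics, RC-time statistics, right-ventricular (RV) power
decomposition, rule-based cohort classification, inverse
resistance–compliance modelling and study-design statistics — with a
synthetic cohort generator so the entire pipeline is testable without any
patient data.

## The problem

Pulmonary vascular resistance (PVR) alone describes only the steady
component of RV afterload. Pulmonary arterial compliance
(Ca, estimated as stroke volume over pulse pressure, SV/PP) captures the
pulsatile component, and the product

```
RC time = PVR × Ca        (PVR in mmHg·s·mL⁻¹, Ca in mL·mmHg⁻¹)
```

is the exponential time constant of diastolic pulmonary-artery pressure
decay. Whether this product is a physiologic constant — or differs between
health and pulmonary arterial hypertension (PAH) — matters, because a
variable RC time implies compliance can change independently of resistance
and shifts the fraction of RV hydraulic power that is "wasted" in
pulsation:

```
W_mean = mPAP·q / 7500,  W_total = sPAP·q / 7500,  W_osc = W_total − W_mean
oscillatory power fraction = W_osc / W_total = 1 − mPAP/sPAP
```

with q the mean flow in mL·s⁻¹ and 1 W = 7500 mmHg·mL·s⁻¹. The package
implements this analysis end to end for anyone working with tabulated RHC
measurements: derived per-record quantities, the normal-hemodynamics (NPH)
vs PAH selection tree, the inverse model Ca = a/(b + PVR) fitted by
nonlinear least squares with a PAH group indicator, nested F-tests,
Wilcoxon group comparisons, and two-sample power / sample-size
calculations.

## Worked example

```python
from rctime import hemo, rc_from_summary

p = hemo.rv_power(spap=24.4, mpap=16.0, co=4.6)
print(f"RV power (mean/osc/total): {p.w_mean:.2f} / {p.w_osc:.2f} / {p.w_total:.2f} W")
print(f"oscillatory fraction:      {100*p.osc_fraction:.0f}%")
print(f"RC time, healthy-range group means: {rc_from_summary(24.4, 9.8, 16.0, 7.8, 4.6, 75.2):.2f} s")
print(f"RC time, PAH group means:           {rc_from_summary(68.3, 25.4, 41.1, 10.5, 4.3, 78.5):.2f} s")
```

prints

```
RV power (mean/osc/total): 0.16 / 0.09 / 0.25 W
oscillatory fraction:      34%
RC time, healthy-range group means: 0.45 s
RC time, PAH group means:           0.55 s
```

— at healthy-range group means the right ventricle spends about a third of
its hydraulic power on pulsation, and the RC time composed from the two
groups' summary statistics differs by ~0.1 s, the health-vs-disease gap the
analysis is designed to detect. Fitting the inverse compliance model to a
seeded synthetic two-group dataset:

```python
from rctime import fit_inverse_model, f_test_group_difference, generate_regression_fixture

x, y, g = generate_regression_fixture(
    "inverse", [{"a": 10.4, "b": 0.5}, {"a": 10.4, "b": 0.8}],
    noise_sd=0.3, n=[150, 700], seed=42, x_range=[(0.5, 4), (1, 20)],
)
fit = fit_inverse_model(x, y, group=g)
pooled = fit_inverse_model(x, y)
ft = f_test_group_difference(pooled, fit)
print(fit.params)               # {'a': 10.42, 'b_g0': 0.51, 'b_g1': 0.82}
print(f"F({ft.df_num},{ft.df_den}) = {ft.f_statistic:.1f}, p = {ft.pvalue:.2e}")
                                # F(1,847) = 210.4, p = 9.68e-43
```

The fitted offsets b differ between the groups, i.e. the
resistance–compliance relationship — and with it the RC time — is not the
same in health and disease.

## Command line

```bash
rctime simulate --group both --seed 1 --output cohort.csv
rctime derive cohort.csv --output derived.csv
rctime classify cohort.csv --output labels.csv
rctime fit cohort.csv --output fits.json
rctime report cohort.csv --output-dir report/
```

Cohort CSVs are self-describing (units in the header:
`spap_mmHg, dpap_mmHg, mpap_mmHg, pcwp_mmHg, co_L_min, hr_bpm, bsa_m2?,
age_years?`); classification bounds and model settings come from a
YAML config (`rctime.io.RunConfig`), whose defaults embed the published
healthy reference intervals.

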