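"""Generator tests: determinism, physiologic validity, moment recovery,
and the compliance link."""

import math

import numpy as np
import pandas as pd
import pytest

from rctime.cohort import HemodynamicClassifier, screen_completeness
from rctime.errors import DomainError, SpecInfeasibleError
from rctime.hemo import derive_record
from rctime.models import fit_inverse_model
from rctime.synthetic import (
    FieldSpec,
    GroupSpec,
    generate_cohort,
    generate_regression_fixture,
    nph_spec,
    pah_spec,
)


def cohort_frame(cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mpap": [r.mpap for r in cohort],
            "ratio": [r.mpap / r.spap for r in cohort],
            "pcwp": [r.pcwp for r in cohort],
            "hr": [r.hr for r in cohort],
            "age": [r.age for r in cohort],
        }
    )


class TestSeedContract:
    def test_single_record_reproducible(self):
        a = generate_cohort(nph_spec(1), seed=3)
        b = generate_cohort(nph_spec(1), seed=3)
        assert a.records == b.records

    def test_different_seeds_differ(self):
        a = generate_cohort(nph_spec(5), seed=3)
        b = generate_cohort(nph_spec(5), seed=4)
        assert a.records != b.records

    def test_seed_required(self):
        with pytest.raises(DomainError, match="seed"):
            generate_cohort(nph_spec(5))


class TestPhysiologicValidity:
    @pytest.mark.parametrize("spec_fn, seed", [(nph_spec, 1), (pah_spec, 2)])
    def test_every_record_ordered_complete_nonnegative_dpg(self, spec_fn, seed):
        cohort = generate_cohort(spec_fn(300), seed=seed)
        for r in cohort:
            assert screen_completeness(r) is None
            assert r.spap > r.mpap > r.dpap > 0
            assert r.dpap >= r.pcwp  # DPG >= 0
            d = derive_record(r)
            assert d.ca > 0 and d.pvr_wood > 0

    def test_pah_records_satisfy_resistance_floor(self):
        cohort = generate_cohort(pah_spec(500), seed=9)
        for r in cohort:
            assert derive_record(r).pvr_wood > 3.0


class TestMomentRecovery:
    @pytest.mark.parametrize(
        "fixture_name, spec_fn",
        [("nph_cohort_1000", nph_spec), ("pah_cohort_1000", pah_spec)],
    )
    def test_drawn_marginals_within_four_se(self, fixture_name, spec_fn, request):
        cohort = request.getfixturevalue(fixture_name)
        frame = cohort_frame(cohort)
        spec = spec_fn(1000)
        for name in ("mpap", "ratio", "pcwp", "hr", "age"):
            field: FieldSpec = getattr(spec, name)
            se = field.sd / math.sqrt(len(frame))
            assert abs(frame[name].mean() - field.mean) < 4 * se, name
            # SDs recovered within a 10% band at n=1000
            assert abs(frame[name].std(ddof=1) / field.sd - 1) < 0.10, name

    def test_implied_dpap_marginal_matches_table(self, nph_cohort_1000):
        dpap = np.array([r.dpap for r in nph_cohort_1000])
        assert dpap.mean() == pytest.approx(9.8, abs=4 * 2.4 / math.sqrt(1000))
        assert dpap.std(ddof=1) == pytest.approx(2.4, rel=0.10)


class TestClassificationFidelity:
    def test_nph_cohort_mostly_classifies_nph(self, nph_cohort_1000):
        labels = HemodynamicClassifier().fit().predict(list(nph_cohort_1000))
        assert (labels == "NPH").mean() >= 0.80

    def test_pah_cohort_classifies_pah(self, pah_cohort_1000):
        labels = HemodynamicClassifier().fit().predict(list(pah_cohort_1000))
        assert (labels == "PAH").mean() >= 0.95


class TestComplianceLink:
    def test_zero_noise_link_recovered_exactly_from_basis_pvr(self):
        spec = nph_spec(200)
        spec = GroupSpec(**{**spec.__dict__, "link_noise_sd": 0.0})
        cohort = generate_cohort(spec, seed=21)
        x = cohort.diagnostics["pvr_link_basis"]
        ca = np.array([derive_record(r).ca for r in cohort])
        # records carry the drawn compliance exactly (SV/PP rescaling)
        assert np.allclose(ca, cohort.diagnostics["ca_drawn"], atol=1e-9)
        fit = fit_inverse_model(x, ca)
        assert fit.params["a"] == pytest.approx(10.4, abs=1e-5)
        assert fit.params["b"] == pytest.approx(0.5, abs=1e-5)

    def test_link_residual_reported(self, pah_cohort_1000):
        diag = pah_cohort_1000.diagnostics
        assert diag["link_residual_mean_abs"] >= 0
        assert len(diag["pvr_link_basis"]) == len(pah_cohort_1000)

    def test_end_to_end_group_difference_detected(self, small_two_group_cohort):
        # fitting the inverse law to a two-group synthetic cohort rejects
        # the pooled model: the groups' offsets genuinely differ
        from rctime.models import f_test_group_difference

        derived = [(derive_record(r), r.id.split("-")[0]) for r in small_two_group_cohort]
        x = np.array([d.pvr_wood for d, _ in derived])
        y = np.array([d.ca for d, _ in derived])
        g = np.array([lab for _, lab in derived])
        pooled = fit_inverse_model(x, y)
        grouped = fit_inverse_model(x, y, group=g)
        assert f_test_group_difference(pooled, grouped).pvalue < 0.05


class TestSpecValidation:
    def test_infeasible_moment_match_raises(self):
        # SD larger than the bound width can admit no truncated normal
        with pytest.raises(SpecInfeasibleError):
            generate_cohort(
                GroupSpec(
                    label="bad", n=10,
                    mpap=FieldSpec(16.0, 50.0, 15.0, 17.0),
                    ratio=FieldSpec(0.66, 0.08, 0.45, 0.95),
                    pcwp=FieldSpec(7.8, 2.3, 2.0, 14.0),
                    co=FieldSpec(4.6, 1.0, 1.5, math.inf),
                    hr=FieldSpec(75.0, 13.0, 40.0, 110.0),
                ),
                seed=1,
            )

    def test_negative_gradient_spec_rejected(self):
        with pytest.raises(DomainError, match="dpg"):
            GroupSpec(
                label="bad", n=10,
                mpap=FieldSpec(16.0, 2.3),
                ratio=FieldSpec(0.66, 0.08, 0.45, 0.95),
                pcwp=FieldSpec(7.8, 2.3),
                co=FieldSpec(4.6, 1.0),
                hr=FieldSpec(75.0, 13.0),
                dpg=FieldSpec(2.0, 1.0, -5.0, math.inf),
            )


class TestRegressionFixture:
    def test_seed_reproducibility(self):
        a = generate_regression_fixture("inverse", {"a": 10.4, "b": 0.5}, 0.3, 50, seed=2)
        b = generate_regression_fixture("inverse", {"a": 10.4, "b": 0.5}, 0.3, 50, seed=2)
        c = generate_regression_fixture("inverse", {"a": 10.4, "b": 0.5}, 0.3, 50, seed=3)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not np.array_equal(a[1], c[1])

    def test_noiseless_linear_fixture_on_the_line(self):
        x, y, g = generate_regression_fixture(
            "linear", {"slope": 0.47, "intercept": 4.6}, 0.0, 30, seed=6
        )
        assert g is None
        assert np.allclose(y, 0.47 * x + 4.6)

    def test_too_small_group_rejected(self):
        with pytest.raises(SpecInfeasibleError):
            generate_regression_fixture("inverse", {"a": 1, "b": 1}, 0.1, 2, seed=1)
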