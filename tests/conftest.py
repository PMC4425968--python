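import numpy as np
import pytest

from rctime.hemo import RHCRecord
from rctime.synthetic import generate_cohort, nph_spec, pah_spec

#: Group means of the emulated cohort table, reused across tests.
NPH_MEANS = dict(spap=24.4, dpap=9.8, mpap=16.0, pcwp=7.8, co=4.6, hr=75.2)
PAH_MEANS = dict(spap=68.3, dpap=25.4, mpap=41.1, pcwp=10.5, co=4.3, hr=78.5)


@pytest.fixture
def nph_mean_record() -> RHCRecord:
    return RHCRecord(id="nph-mean", bsa=1.8, **NPH_MEANS)


@pytest.fixture
def pah_mean_record() -> RHCRecord:
    return RHCRecord(id="pah-mean", **PAH_MEANS)


@pytest.fixture(scope="session")
def nph_cohort_1000():
    return generate_cohort(nph_spec(1000), seed=20240901)


@pytest.fixture(scope="session")
def pah_cohort_1000():
    return generate_cohort(pah_spec(1000), seed=20240902)


@pytest.fixture(scope="session")
def small_two_group_cohort():
    """A study-sized two-group cohort (156 NPH + 717 PAH records)."""
    rng_seed = 77
    nph = generate_cohort(nph_spec(156), seed=rng_seed)
    pah = generate_cohort(pah_spec(717), seed=rng_seed + 1)
    return list(nph) + list(pah)


def assert_close(actual, expected, atol=1e-9, rtol=0.0):
    assert np.isclose(actual, expected, atol=atol, rtol=rtol), (
        f"{actual} != {expected}"
    )
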