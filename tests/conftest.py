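import pytest

from cohortfusion import SynthConfig, generate


@pytest.fixture(scope="session")
def small_store():
    """Seeded 60-patient RA / 20-patient psoriasis store shared across tests."""
    return generate(SynthConfig(ra_n=60, psoriasis_n=20, seed=11))


@pytest.fixture(scope="session")
def medium_store():
    """100-patient RA store used for oracle-equivalence sweeps."""
    return generate(SynthConfig(ra_n=100, psoriasis_n=25, seed=5))


@pytest.fixture(scope="session")
def hw_store():
    """Large genotype cohort for Hardy-Weinberg frequency checks."""
    return generate(SynthConfig(ra_n=10000, psoriasis_n=5, seed=17,
                                visits_lambda=0.0, samples_lambda=0.0,
                                serology_fraction=0.05))
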