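import numpy as np
import pytest

from painsignal import Cohort, CohortConfig, VitalChannelSeries, generate_cohort


def make_series(values, valid=None, channel="pulse_rate") -> VitalChannelSeries:
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = ~np.isnan(values)
    return VitalChannelSeries(channel, values, np.asarray(valid, dtype=bool))


def ar1_series(n, mu=80.0, sigma=1.5, phi=0.95, seed=0, channel="pulse_rate"):
    """Plain-loop AR(1) generator, independent of the package's simulator."""
    rng = np.random.default_rng(seed)
    d = 0.0
    out = np.empty(n)
    for t in range(n):
        d = phi * d + sigma * rng.standard_normal()
        out[t] = mu + d
    return make_series(out, channel=channel)


@pytest.fixture(scope="session")
def medium_cohort() -> Cohort:
    """A reusable default-parameter cohort, large enough for distributional
    checks but quick to generate."""
    return generate_cohort(CohortConfig(n_patients=80, seed=42))


@pytest.fixture(scope="session")
def null_cohort() -> Cohort:
    """A zero-effect cohort: vitals are independent of pain by construction."""
    return generate_cohort(CohortConfig(n_patients=40, pain_effect_size=0.0, seed=43))
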