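import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fnirsdpf as f

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def paradigm_st1():
    """Shortest simulation paradigm: 10 s rest, 10 s task, 30 s rest."""
    return f.simulated_paradigm(10, "St1")


@pytest.fixture
def canonical():
    return f.HRFParams()


@pytest.fixture
def noise_free_subject(paradigm_st1):
    """A noise-free signal with known parameters and its case-1 OD split."""
    hrf = f.HRFParams(6.2, 15.5, 1.1, 0.9)
    nuisance = f.NuisanceParams(
        a0=5.0, a1=4.0, ac=0.8, ar=0.5, am=0.3,
        fc=1.1, fr=0.25, fm=0.095, noise_sd=0.0,
    )
    y = f.generate_signal(hrf, nuisance, paradigm_st1, fs=100.0)
    pair = f.split_signal(y, "case1").pair
    return y, pair, hrf, nuisance


def draw_inbox_params(rng):
    """Random generating parameters inside the C1-C12 box, with amplitudes
    bounded away from zero so the sinusoid frequencies are identifiable."""
    hrf = f.HRFParams(
        alpha1=rng.uniform(4, 8),
        alpha2=rng.uniform(12, 18),
        beta1=rng.uniform(0.7, 1.5),
        beta2=rng.uniform(0.5, 1.2),
    )
    nuisance = f.NuisanceParams(
        a0=rng.uniform(2, 10),
        a1=rng.uniform(2, 8),
        ac=rng.uniform(0.3, 1.5),
        ar=rng.uniform(0.3, 1.5),
        am=rng.uniform(0.3, 1.5),
        fc=rng.uniform(0.6, 1.4),
        fr=rng.uniform(0.21, 0.29),
        fm=rng.uniform(0.091, 0.099),
        noise_sd=0.0,
    )
    return hrf, nuisance
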