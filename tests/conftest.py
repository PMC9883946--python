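import numpy as np
import pytest

from glymflow.io import DEFAULT_FRAME_TIMES_MIN
from glymflow.synthetic import PhantomSpec, make_phantom_cohort


@pytest.fixture(scope="session")
def frame_times():
    """The 25-frame acquisition schedule, 30 to 150 min every 5 min."""
    return np.asarray(DEFAULT_FRAME_TIMES_MIN)


@pytest.fixture(scope="session")
def small_phantom():
    """A deterministic desk-scale phantom cohort shared across tests."""
    spec = PhantomSpec(grid_shape=(28, 28, 20), seed=11)
    return spec, make_phantom_cohort(spec)


@pytest.fixture(scope="session")
def clean_phantom():
    """Zero-noise, zero-heterogeneity phantom: the generative model is exactly
    invertible by percent-signal-change normalization."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 16),
        seed=5,
        noise_sd_percent=0.0,
        baseline_cv=0.0,
        gain_jitter_sd=0.0,
        between_subject_tau_cv=0.0,
        n_subjects_per_group=2,
    )
    return spec, make_phantom_cohort(spec)
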