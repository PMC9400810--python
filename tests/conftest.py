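import numpy as np
import pytest

from cardioeeg.synthetic import CONTROL_GROUP, RE_GROUP, CohortSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_spec():
    """Short cohort spec with every noise/artifact term switched off."""
    return CohortSpec(
        n_per_group=(2, 2),
        duration_s=120.0,
        rr_jitter_ms=0.0,
        noise_sd_uv=0.0,
        cfa_gain=0.0,
        hep_amp_uv={RE_GROUP: 0.0, CONTROL_GROUP: 0.0},
        ecg_noise_sd_mv=0.0,
        ecg_wander_mv=0.0,
        seed=7,
    )


@pytest.fixture
def default_short_spec():
    """Default noise levels but short recordings, for round-trip tests."""
    return CohortSpec(n_per_group=(3, 3), duration_s=120.0, seed=11)
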