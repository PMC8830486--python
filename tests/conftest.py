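import numpy as np
import pytest

from neoprog.synthetic import (
    ArtifactSpec,
    CohortSpec,
    OscillationSpec,
)

#: 19-electrode montage used by the bad-channel fixtures.
FULL_MONTAGE = (
    "C3", "C4", "CZ", "F3", "F4", "F7", "F8", "FZ", "FP1", "FP2",
    "O1", "O2", "P3", "P4", "PZ", "T3", "T4", "T5", "T6",
)

#: The seven channels planted bad in the 19-channel fixture.
PLANTED_BAD = ("C4", "CZ", "F4", "F8", "FP1", "FP2", "PZ")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def bad_channel_spec():
    """19-channel cohort with three flat and four high-variance channels."""
    return CohortSpec(
        n_subjects=2,
        sampling_rate=128.0,
        duration=8.0,
        channel_labels=FULL_MONTAGE,
        oscillation_specs=(OscillationSpec(8.0, 10.0, "all"),),
        artifact_spec=ArtifactSpec(
            flat_channels=("C4", "CZ", "F4"),
            noisy_channels=("F8", "FP1", "FP2", "PZ"),
        ),
        noise_sd=2.0,
        seed=7,
    )


@pytest.fixture
def small_clean_spec():
    """Small artifact-free cohort for generic preprocessing tests."""
    return CohortSpec(
        n_subjects=3,
        sampling_rate=64.0,
        duration=8.0,
        channel_labels=("C3", "T3", "O1"),
        oscillation_specs=(OscillationSpec(8.0, 10.0, "all"),),
        noise_sd=2.0,
        seed=3,
    )
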