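import numpy as np
import pytest

import locomo as lm


@pytest.fixture(scope="session")
def young_profile():
    return lm.ParticipantProfile("young_000", "Young", "M", 30.0, None)


@pytest.fixture(scope="session")
def noise_free_recording(young_profile):
    """Five clean cycles at 100 Hz with known ground-truth events."""
    params = lm.KinematicParams(tremor_noise_sd=0.0)
    return lm.simulate_ftsts(young_profile, params, n_cycles=5, sample_rate_hz=100.0, seed=7)


@pytest.fixture(scope="session")
def preprocessed_recording(noise_free_recording):
    return lm.preprocess_recording(noise_free_recording)


@pytest.fixture(scope="session")
def segmented(preprocessed_recording):
    return lm.segment_recording(preprocessed_recording)


@pytest.fixture(scope="session")
def tiny_cohort_config():
    """A 4-group cohort small enough for fast end-to-end tests."""
    return lm.CohortConfig(group_counts={"NonLS": 6, "Stage1": 4, "Stage2": 6, "Young": 6})


@pytest.fixture(scope="session")
def default_cohort_features():
    """Feature table of the full default synthetic cohort (shared across tests)."""
    from locomo.features import build_feature_vector, feature_table
    from locomo.synth import cohort_manifest

    profiles, recordings = lm.generate_cohort(seed=11)
    rows = []
    for rec in recordings:
        pre = lm.preprocess_recording(rec)
        rows.append((rec.participant_id, build_feature_vector(pre, lm.segment_recording(pre))))
    return feature_table(rows, metadata=cohort_manifest(profiles))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
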