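import numpy as np
import pytest

from bcgid import TrainConfig, simulate_recording
from bcgid.pipeline import PipelineConfig, featurize_recording_pair, split_recording, stage_seed


def build_subject_features(panel, base_seed, config=None):
    """Simulate each panel subject once and split into train/test features."""
    config = config or PipelineConfig()
    duration = config.train_duration_s + config.test_duration_s
    features = {}
    for profile in panel:
        rec = simulate_recording(
            profile, duration, config.sampling_rate_hz,
            stage_seed(base_seed, "simulate", profile.subject_id),
        )
        train_rec, test_rec = split_recording(rec, config.train_duration_s)
        features[profile.subject_id] = featurize_recording_pair(
            train_rec, test_rec, config,
            stage_seed(base_seed, "featurize", profile.subject_id),
        )
    return features


@pytest.fixture(scope="session")
def fast_config():
    """Reduced problem sizes for unit tests that need a trained network."""
    return PipelineConfig(
        train_duration_s=60.0,
        test_duration_s=20.0,
        n_train_windows=100,
        train=TrainConfig(epochs=120, learning_rate=0.01, seed=0),
    )


@pytest.fixture(scope="session")
def single_peak_features(fast_config):
    from bcgid import single_peak_panel

    return build_subject_features(single_peak_panel(), base_seed=7, config=fast_config)


@pytest.fixture(scope="session")
def single_peak_model(single_peak_features, fast_config):
    from bcgid.evaluate import run_pattern

    members = tuple(sorted(single_peak_features))
    report, predictions, params = run_pattern(
        single_peak_features, members, fast_config.train, base_seed=7
    )
    return report, predictions, params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
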