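"""Helper shared by the example scripts: panel -> per-subject features."""

from bcgid import simulate_recording
from bcgid.pipeline import featurize_recording_pair, split_recording, stage_seed


def build_subject_features(panel, base_seed, config):
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
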