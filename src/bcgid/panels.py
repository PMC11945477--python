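"""Built-in synthetic subject panels.

The study design this package mirrors is a ten-person panel whose members
are distinguished by the spectral envelope of their heartbeat-driven sensor
signal: each subject has a fundamental (heart-rate) frequency, a decaying
harmonic envelope with one boosted "main peak" harmonic, respiratory
modulation and mild heart-rate jitter. No real subject's heart-rate range or
peak frequencies are published for the study these panels emulate, so the
parameter values below are invented defaults chosen to be physiologically
plausible (resting heart rates 60-87 bpm, respiration 12-18 breaths/min,
~2% cycle-to-cycle heart-rate variability).

Three factories are provided:

* :func:`well_separated_panel` — ten subjects with distinct fundamentals and
  envelopes; every five-subject classification problem drawn from it is
  easy. This is the default pipeline panel.
* :func:`near_duplicate_panel` — the same panel with one member replaced by
  a near-copy of another (similar fundamental and envelope, higher jitter,
  extra noise and motion artifacts), emulating the pair of confusable
  subjects whose similar spectra degrade classification.
* :func:`single_peak_panel` — five single-tone subjects whose class identity
  is carried entirely by one spectral peak; used to exercise the masking
  attribution procedures.
"""

from __future__ import annotations

import numpy as np

from .simulate import HarmonicProfile, SubjectProfile

__all__ = ["well_separated_panel", "near_duplicate_panel", "single_peak_panel"]


def _envelope(f0: float, decay: float, boost_harmonic: int, boost: float) -> tuple[float, ...]:
    """Exponentially decaying harmonic amplitudes with one boosted harmonic."""
    n_harm = min(10, int(15.0 / f0))
    amps = np.exp(-decay * np.arange(n_harm))
    if 1 <= boost_harmonic <= n_harm:
        amps[boost_harmonic - 1] *= boost
    return tuple(amps)


def _subject(
    subject_id: str,
    f0: float,
    decay: float,
    boost_harmonic: int,
    boost: float,
    resp_hz: float,
    depth: float,
    jitter: float,
    noise_sd: float = 1.0,
    artifact_rate: float = 0.0,
) -> SubjectProfile:
    return SubjectProfile(
        subject_id=subject_id,
        harmonic=HarmonicProfile(f0, _envelope(f0, decay, boost_harmonic, boost)),
        respiration_hz=resp_hz,
        respiration_depth=depth,
        hr_jitter=jitter,
        noise_sd=noise_sd,
        artifact_rate_per_min=artifact_rate,
    )


# id, f0 (Hz), envelope decay, boosted harmonic, boost, resp (Hz), depth, jitter
_WELL_SEPARATED = [
    ("M0", 1.00, 0.25, 7, 2.5, 0.25, 0.12, 0.015),
    ("M1", 1.05, 0.45, 3, 2.0, 0.22, 0.10, 0.020),
    ("M2", 1.10, 0.30, 5, 2.5, 0.28, 0.15, 0.015),
    ("M3", 1.15, 0.50, 8, 3.0, 0.20, 0.10, 0.020),
    ("M4", 1.20, 0.35, 4, 2.0, 0.30, 0.18, 0.025),
    ("M5", 1.25, 0.30, 6, 2.5, 0.24, 0.12, 0.020),
    ("M6", 1.30, 0.40, 5, 2.2, 0.26, 0.14, 0.015),
    ("M7", 1.35, 0.28, 4, 2.8, 0.21, 0.11, 0.020),
    ("M8", 1.40, 0.45, 7, 2.0, 0.27, 0.16, 0.025),
    ("M9", 1.45, 0.33, 6, 2.4, 0.23, 0.13, 0.020),
]


def well_separated_panel() -> list[SubjectProfile]:
    """Ten subjects with distinct fundamentals (1.0-1.45 Hz) and envelopes."""
    return [_subject(*row) for row in _WELL_SEPARATED]


def near_duplicate_panel() -> list[SubjectProfile]:
    """The default panel with M9 replaced by a near-copy of M5.

    The replacement shares M5's fundamental, envelope and respiration
    exactly, but has half again the heart-rate jitter (slightly broadened,
    shifting peaks), doubled sensor noise and occasional motion-artifact
    bursts — a subject whose spectral cloud overlaps its twin's. The
    overlap is asymmetric: the unstable twin's broad distribution swallows
    part of the clean twin's tight one, so classifiers trained on patterns
    containing both degrade mainly on the clean member of the pair.
    """
    panel = well_separated_panel()
    panel[9] = _subject(
        "M9", 1.25, 0.30, 6, 2.5, 0.24, 0.12, jitter=0.03,
        noise_sd=2.0, artifact_rate=2.0,
    )
    return panel


def single_peak_panel() -> list[SubjectProfile]:
    """Five single-tone subjects; each class is one isolated spectral peak.

    Fundamentals sit exactly on 0.1 Hz bin centres so a 10 s window resolves
    each subject as a single sharp line, making the discriminative feature
    for each class a single known bin — the controlled setting for the
    occlusion-masking attribution checks.
    """
    tones = [("P3", 3.0), ("P5", 5.0), ("P6", 6.5), ("P8", 8.0), ("P10", 10.0)]
    return [
        SubjectProfile(
            subject_id=sid,
            harmonic=HarmonicProfile(f0, (1.0,)),
            respiration_hz=0.25,
            respiration_depth=0.05,
            hr_jitter=0.0,
            noise_sd=0.5,
            artifact_rate_per_min=0.0,
        )
        for sid, f0 in tones
    ]
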