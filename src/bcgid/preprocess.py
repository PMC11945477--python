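"""Windowing, spectral feature extraction and motion screening.

Recordings are cut into 10 s windows (1000 samples at 100 Hz): training
windows at uniformly random offsets, test windows on a deterministic 1 s
stride. Each window becomes a 150-bin magnitude spectrum at 0.1 Hz
resolution — a one-sided FFT with bins below 0.5 Hz zeroed (DC and
respiratory drift) and bins at or above 15 Hz discarded (no cardiac
content) — then min-max normalised to [0, 1] per window. The normalised
150-vector is the classifier's input.

Motion screening flags 1 s segments whose peak absolute deviation exceeds
twice the recording's mean absolute deviation; flagged spans can optionally
be excluded from window extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import Recording

__all__ = [
    "Window",
    "Spectrum",
    "MotionFlags",
    "extract_training_windows",
    "extract_test_windows",
    "compute_spectrum",
    "normalize_spectrum",
    "detect_motion_segments",
    "spectra_matrix",
    "featurize_windows",
]

DEFAULT_WINDOW_LEN = 1000
N_BINS = 150
RESOLUTION_HZ = 0.1


@dataclass
class Window:
    """A fixed-length slice of a recording."""

    subject_id: str
    start_index: int
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def length(self) -> int:
        return len(self.samples)


@dataclass
class Spectrum:
    """A truncated one-sided magnitude spectrum (the feature vector).

    ``bins[i]`` is the magnitude at centre frequency ``i * resolution_hz``.
    ``degenerate`` marks a spectrum whose bins were all equal before
    normalisation (normalised output is then all zero).
    """

    bins: np.ndarray = field(repr=False)
    resolution_hz: float = RESOLUTION_HZ
    normalized: bool = False
    degenerate: bool = False
    subject_id: str = ""
    source_start_index: int = 0

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=np.float64)
        if np.any(self.bins < 0):
            raise ValueError("spectrum bins must be non-negative")


@dataclass
class MotionFlags:
    """Flagged movement segments: (start_index, end_index, peak_ratio)."""

    segments: list[tuple[int, int, float]]
    threshold_factor: float

    def __bool__(self) -> bool:
        return bool(self.segments)


def _check_window_len(recording: Recording, window_len: int) -> None:
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if len(recording) < window_len:
        raise ValueError(
            f"recording of {len(recording)} samples is shorter than one "
            f"{window_len}-sample window"
        )


def extract_training_windows(
    recording: Recording,
    n_windows: int = 500,
    window_len: int = DEFAULT_WINDOW_LEN,
    seed: int | None = None,
    exclude: MotionFlags | None = None,
) -> list[Window]:
    """Draw ``n_windows`` windows at uniformly random start offsets.

    Starts are sampled with replacement from all valid offsets; the draw is
    reproducible from ``seed``. If ``exclude`` is given, offsets whose window
    would overlap a flagged movement segment are removed from the candidate
    set first (an opt-in curation step; screening is off by default).
    """
    _check_window_len(recording, window_len)
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if seed is None:
        raise ValueError("a seed is required")
    valid = np.arange(len(recording) - window_len + 1)
    if exclude is not None and exclude.segments:
        mask = np.ones(len(valid), dtype=bool)
        for s, e, _ in exclude.segments:
            lo = max(s - window_len + 1, 0)
            mask[lo:e] = False
        if not mask.any():
            raise ValueError("motion screening removed every valid window start")
        valid = valid[mask]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    starts = rng.choice(valid, size=n_windows, replace=True)
    return [
        Window(recording.subject_id, int(s), recording.samples[s : s + window_len])
        for s in starts
    ]


def extract_test_windows(
    recording: Recording,
    shift_s: float = 1.0,
    window_len: int = DEFAULT_WINDOW_LEN,
) -> list[Window]:
    """Deterministic windows at 0, shift, 2*shift, ... while they fit.

    The count is ``floor((L - window_len) / (shift_s * fs)) + 1``.
    """
    _check_window_len(recording, window_len)
    if shift_s <= 0:
        raise ValueError("shift_s must be positive")
    step = int(round(shift_s * recording.sampling_rate_hz))
    if step < 1:
        raise ValueError("shift is below one sample")
    starts = range(0, len(recording) - window_len + 1, step)
    return [
        Window(recording.subject_id, s, recording.samples[s : s + window_len])
        for s in starts
    ]


def compute_spectrum(
    window: Window,
    sampling_rate_hz: float = 100.0,
    low_zero_hz: float = 0.5,
    high_cut_hz: float = 15.0,
    expected_bins: int = N_BINS,
) -> Spectrum:
    """One-sided FFT magnitude, low bins zeroed, truncated below 15 Hz.

    The window length and sampling rate must give exactly ``expected_bins``
    retained bins (150 at the 1000-sample / 100 Hz default, i.e. centre
    frequencies 0.0-14.9 Hz at 0.1 Hz resolution); anything else is
    rejected so feature vectors cannot silently change shape.
    """
    if sampling_rate_hz <= 0:
        raise ValueError("sampling_rate_hz must be positive")
    n = window.length
    if n < 2:
        raise ValueError("window too short for an FFT")
    resolution = sampling_rate_hz / n
    n_keep = int(round(high_cut_hz / resolution))
    if n_keep != expected_bins:
        raise ValueError(
            f"window of {n} samples at {sampling_rate_hz} Hz yields {n_keep} "
            f"bins below {high_cut_hz} Hz, expected {expected_bins}"
        )
    mags = np.abs(np.fft.rfft(window.samples))[:n_keep]
    freqs = np.arange(n_keep) * resolution
    mags[freqs < low_zero_hz] = 0.0
    return Spectrum(
        bins=mags,
        resolution_hz=resolution,
        normalized=False,
        subject_id=window.subject_id,
        source_start_index=window.start_index,
    )


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Per-spectrum min-max scaling ``x' = (x - min X) / (max X - min X)``.

    The min and max are taken over the spectrum's own 150 bins. A degenerate
    spectrum (all bins equal) maps to all zeros with ``degenerate=True``.
    Normalising twice is an error.
    """
    if spectrum.normalized:
        raise ValueError("spectrum is already normalized")
    lo = float(spectrum.bins.min())
    hi = float(spectrum.bins.max())
    if hi == lo:
        return replace(
            spectrum, bins=np.zeros_like(spectrum.bins), normalized=True, degenerate=True
        )
    return replace(
        spectrum, bins=(spectrum.bins - lo) / (hi - lo), normalized=True
    )


def detect_motion_segments(
    recording: Recording,
    threshold_factor: float = 2.0,
    window_s: float = 1.0,
) -> MotionFlags:
    """Flag body-movement segments by the 2x-average-amplitude rule.

    The recording is scanned in consecutive ``window_s`` segments; a segment
    is flagged when its peak absolute deviation from the recording mean
    exceeds ``threshold_factor`` times the recording's mean absolute
    deviation. A clean sinusoid is never flagged (its peak/mean-abs ratio is
    pi/2), while the injected artifact bursts always are.
    """
    if len(recording) == 0:
        raise ValueError("recording is empty")
    if threshold_factor <= 1:
        raise ValueError("threshold_factor must exceed 1")
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    dev = np.abs(recording.samples - np.mean(recording.samples))
    mean_abs = float(np.mean(dev))
    if mean_abs == 0.0:
        return MotionFlags([], threshold_factor)
    seg_len = max(int(round(window_s * recording.sampling_rate_hz)), 1)
    segments: list[tuple[int, int, float]] = []
    for start in range(0, len(recording), seg_len):
        end = min(start + seg_len, len(recording))
        peak_ratio = float(dev[start:end].max() / mean_abs)
        if peak_ratio > threshold_factor:
            segments.append((start, end, peak_ratio))
    return MotionFlags(segments, threshold_factor)


def spectra_matrix(spectra: list[Spectrum]) -> np.ndarray:
    """Stack spectra into an (n_windows, n_bins) float matrix."""
    if not spectra:
        raise ValueError("no spectra given")
    return np.stack([s.bins for s in spectra])


def featurize_windows(
    windows: list[Window],
    sampling_rate_hz: float = 100.0,
    low_zero_hz: float = 0.5,
    high_cut_hz: float = 15.0,
) -> np.ndarray:
    """Windows -> normalised spectra, stacked as an (n_windows, 150) matrix."""
    specs = [
        normalize_spectrum(
            compute_spectrum(w, sampling_rate_hz, low_zero_hz, high_cut_hz)
        )
        for w in windows
    ]
    return spectra_matrix(specs)
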