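"""Occlusion-masking attribution for the spectral classifier.

Which frequency bins carry a subject's identity? The procedure zeroes parts
of the normalised input spectrum and re-runs inference, reading the drop in
mean own-class probability as the masked region's importance. Three mask
shapes are supported: cumulative from the low-frequency side, cumulative
from the high-frequency side, and a single peak of configurable half-width.
Masks act in the model's input space (after normalisation) and the masked
spectrum is *not* re-normalised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import find_peaks

from .network import NetworkParameters, predict
from .preprocess import N_BINS, RESOLUTION_HZ, Spectrum

__all__ = [
    "MaskMode",
    "MaskSpec",
    "AttributionCurve",
    "apply_mask",
    "mask_array",
    "cumulative_mask_scan",
    "single_peak_scan",
    "detect_peaks",
]


class MaskMode(str, Enum):
    LOW_CUMULATIVE = "low_cumulative"
    HIGH_CUMULATIVE = "high_cumulative"
    SINGLE_PEAK = "single_peak"


@dataclass(frozen=True)
class MaskSpec:
    """One masking instruction.

    For cumulative modes ``boundary_bin`` splits the spectrum: low mode
    zeroes every bin below the boundary, high mode zeroes every bin at or
    above it. For single-peak mode bins within ``half_width`` of
    ``peak_bin`` are zeroed.
    """

    mode: MaskMode
    boundary_bin: int | None = None
    peak_bin: int | None = None
    half_width: int = 3

    def __post_init__(self) -> None:
        if self.mode is MaskMode.SINGLE_PEAK:
            if self.peak_bin is None or not 0 <= self.peak_bin < N_BINS:
                raise ValueError(f"peak_bin must lie in [0, {N_BINS})")
            if self.half_width < 0:
                raise ValueError("half_width must be >= 0")
        else:
            if self.boundary_bin is None or not 0 <= self.boundary_bin <= N_BINS:
                raise ValueError(f"boundary_bin must lie in [0, {N_BINS}]")

    def bin_mask(self) -> np.ndarray:
        """Boolean vector, True where the spectrum is zeroed."""
        mask = np.zeros(N_BINS, dtype=bool)
        if self.mode is MaskMode.LOW_CUMULATIVE:
            mask[: self.boundary_bin] = True
        elif self.mode is MaskMode.HIGH_CUMULATIVE:
            mask[self.boundary_bin :] = True
        else:
            lo = max(self.peak_bin - self.half_width, 0)
            hi = min(self.peak_bin + self.half_width + 1, N_BINS)
            mask[lo:hi] = True
        return mask


@dataclass
class AttributionCurve:
    """Mean own-class probability against mask extent for one class."""

    class_id: str
    mode: MaskMode
    mask_extents_hz: np.ndarray = field(repr=False)
    mean_own_probability: np.ndarray = field(repr=False)
    reference_probability: float = 0.0


def mask_array(X: np.ndarray, mask: MaskSpec) -> np.ndarray:
    """Apply one mask to a (N, 150) feature matrix (masked bins -> 0)."""
    X = np.asarray(X, dtype=np.float64)
    out = X.copy()
    out[..., mask.bin_mask()] = 0.0
    return out


def apply_mask(spectrum: Spectrum, mask: MaskSpec) -> Spectrum:
    """Zero the masked bins of a normalised spectrum; no re-normalisation."""
    if not spectrum.normalized:
        raise ValueError("masks operate on normalised (model input) spectra")
    from dataclasses import replace

    return replace(spectrum, bins=mask_array(spectrum.bins, mask))


def _own_index(params: NetworkParameters, class_id: str) -> int:
    if class_id not in params.class_labels:
        raise ValueError(f"class {class_id!r} not among {params.class_labels}")
    return params.class_labels.index(class_id)


def cumulative_mask_scan(
    params: NetworkParameters,
    test_spectra: np.ndarray,
    class_id: str,
    direction: str = "low",
    step_bins: int = 5,
) -> AttributionCurve:
    """Scan a growing cumulative mask and record mean own-class probability.

    ``direction='low'`` grows the mask upward from 0 Hz; ``'high'`` grows it
    downward from the top of the band. The extent axis is the width of the
    masked band in Hz; extent 0 is the unmasked reference. Curves need not
    be monotone.
    """
    X = np.asarray(test_spectra, dtype=np.float64)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("test_spectra must be a non-empty (N, 150) matrix")
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    if step_bins < 1:
        raise ValueError("step_bins must be >= 1")
    own = _own_index(params, class_id)
    mode = MaskMode.LOW_CUMULATIVE if direction == "low" else MaskMode.HIGH_CUMULATIVE

    extents = list(range(0, N_BINS, step_bins)) + [N_BINS]
    probs = []
    for extent in extents:
        boundary = extent if direction == "low" else N_BINS - extent
        spec = MaskSpec(mode=mode, boundary_bin=boundary)
        probs.append(float(predict(params, mask_array(X, spec))[:, own].mean()))
    return AttributionCurve(
        class_id=class_id,
        mode=mode,
        mask_extents_hz=np.asarray(extents) * RESOLUTION_HZ,
        mean_own_probability=np.asarray(probs),
        reference_probability=probs[0],
    )


def single_peak_scan(
    params: NetworkParameters,
    test_spectra: np.ndarray,
    class_id: str,
    peaks: list[int],
    half_width: int = 3,
) -> list[tuple[int, float, float]]:
    """Mask one peak at a time; returns (peak_bin, masked_prob, reference).

    One re-inference per requested peak, in input order, zeroing only the
    ``peak +- half_width`` bins.
    """
    X = np.asarray(test_spectra, dtype=np.float64)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("test_spectra must be a non-empty (N, 150) matrix")
    if not peaks:
        raise ValueError("no peaks requested")
    own = _own_index(params, class_id)
    reference = float(predict(params, X)[:, own].mean())
    results = []
    for peak in peaks:
        spec = MaskSpec(mode=MaskMode.SINGLE_PEAK, peak_bin=int(peak), half_width=half_width)
        masked = float(predict(params, mask_array(X, spec))[:, own].mean())
        results.append((int(peak), masked, reference))
    return results


def detect_peaks(
    spectrum: Spectrum | np.ndarray,
    min_prominence: float = 0.2,
    min_separation_bins: int = 5,
) -> list[int]:
    """Prominent local maxima, sorted by descending magnitude.

    Prominence is relative to the spectrum's maximum; an all-zero spectrum
    has no peaks. Interior-only maxima (a monotone edge is not a peak).
    """
    bins = spectrum.bins if isinstance(spectrum, Spectrum) else np.asarray(spectrum)
    peak_max = float(bins.max())
    if peak_max == 0.0:
        return []
    idx, _ = find_peaks(
        bins,
        prominence=min_prominence * peak_max,
        distance=max(min_separation_bins, 1),
    )
    return [int(i) for i in idx[np.argsort(-bins[idx], kind="stable")]]
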