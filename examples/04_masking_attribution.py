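"""Which frequency bins carry a subject's identity? Occlusion masking.

Trains on the five single-tone subjects (each identified by exactly one
spectral line), then zeroes parts of the normalised input spectrum and
re-runs inference. Masking the known identity peak collapses the own-class
probability; masking empty regions leaves it untouched.
"""

from bcgid import cumulative_mask_scan, detect_peaks, single_peak_panel, single_peak_scan
from bcgid.evaluate import run_pattern
from bcgid.pipeline import PipelineConfig

import sys, pathlib
sys.path.insert(0, str(pathlib.Path(__file__).resolve().parent))
from _shared import build_subject_features  # noqa: E402

config = PipelineConfig(base_seed=1)
features = build_subject_features(single_peak_panel(), 1, config)
members = tuple(sorted(features))
_, _, params = run_pattern(features, members, config.train, base_seed=1)

X = features["P5"].test  # subject whose identity is the 5.0 Hz line
peaks = detect_peaks(X.mean(axis=0))
print(f"detected peaks in P5's mean test spectrum (bins): {peaks}")

print("\nsingle-peak masking (zero the peak +-0.3 Hz, re-infer):")
for peak, masked, ref in single_peak_scan(params, X, "P5", peaks=[50, 120]):
    print(f"  mask {peak / 10:.1f} Hz: mean own-class probability "
          f"{ref:.3f} -> {masked:.3f}  (delta {ref - masked:+.3f})")

curve = cumulative_mask_scan(params, X, "P5", "low")
crossing = curve.mask_extents_hz <= 5.5
print("\ncumulative low-side mask (extent in Hz -> mean own probability):")
for hz, p in zip(curve.mask_extents_hz[crossing][::2],
                 curve.mean_own_probability[crossing][::2]):
    print(f"  0-{hz:4.1f} Hz masked: {p:.3f}")
print("(the probability collapses only once the mask crosses the 5.0 Hz "
      "identity peak — the model's decision rests on that single feature)")
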