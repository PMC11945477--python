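# bcgid — person identification from ballistocardiogram spectra

`bcgid` is a research toolkit for identifying *who* is sitting or lying on
a piezoelectric pressure sensor from the frequency content of their
ballistocardiogram (BCG) — the body-surface vibration driven by the
heartbeat. It is aimed at people studying unobtrusive in-home monitoring:
the sensor needs no skin contact, and the question is whether the members
of a household (modelled as five people) can be told apart from ~10 s of
signal.

A PVDF piezoelectric film is a *differential* sensor: its voltage follows
the time derivative of the pressure. For a periodic cardiac pressure wave
with Fourier coefficients `c_n` at harmonics `n·f0` of the heart rate,
differentiation scales the n-th harmonic by `n`, emphasising the upper
harmonics that differ most between people. The package implements the full
experimental loop around that idea:

1. **Synthesis** (`bcgid.simulate`, `bcgid.panels`) — seeded, labelled
   BCG-like recordings: harmonic envelope per subject, respiratory
   amplitude modulation, heart-rate jitter, noise, motion-artifact bursts.
2. **Features** (`bcgid.preprocess`) — 10 s windows → 150-bin magnitude
   spectra (0.0–14.9 Hz at 0.1 Hz), low bins zeroed, min–max normalised
   per window: `x' = (x − min X)/(max X − min X)`.
3. **Classifier** (`bcgid.network`) — a hand-implemented 150-32-16-5
   ReLU/softmax network trained with cross-entropy
   `L = −(1/N) Σ_i Σ_k y_ik log ŷ_ik`; gradients are verified against
   finite differences in the tests.
4. **Evaluation** (`bcgid.evaluate`) — the accuracy statistic
   `R_k = (1/m_k) Σ_i 1[P_k^i ≥ 0.5]` (a window counts as correct only if
   the softmax mass on its own class reaches 0.5), swept over **all
   C(10,5) = 252 five-subject combinations** of a ten-subject panel
   (1260 per-class results), with best/worst/middle ranking and a
   dispersion diagnostic.
5. **Attribution** (`bcgid.attribution`) — occlusion masking: zero part of
   the input spectrum (cumulative low-side, cumulative high-side, or a
   single peak) and re-infer to find which frequency bins carry identity.

## Worked example

```python
from bcgid import well_separated_panel
from bcgid.evaluate import run_pattern
from bcgid.pipeline import PipelineConfig
# build features for five subjects (120 s train / 60 s test each)
# -- see examples/02_features_and_training.py for the full script
```

Running `python examples/02_features_and_training.py` prints:

```
pattern 01234: per-class accuracy rates (fraction of test windows with own-class probability >= 0.5)
  M0: 51/51 = 1.000
  M1: 51/51 = 1.000
  M2: 51/51 = 1.000
  M3: 51/51 = 1.000
  M4: 51/51 = 1.000

signed mean classification probability (own class positive):
  true M0: +0.982 -0.005 -0.005 -0.001 -0.006
  ...
```

Each subject's 51 test windows (a 60 s segment at a 1 s stride) all place
≥ 0.5 probability on the right person; the signed rows show where the
residual probability mass leaks. `examples/04_masking_attribution.py`
shows the attribution side:

```
mask 5.0 Hz: mean own-class probability 0.903 -> 0.162  (delta +0.740)
mask 12.0 Hz: mean own-class probability 0.903 -> 0.902  (delta +0.000)
```

masking the subject's single 5 Hz identity peak collapses the
classification, while masking an empty region does nothing.

There is also a thin CLI mirroring the pipeline stages
(`bcgid simulate | featurize | train | sweep | attribute | report | run`);
`bcgid run --seed 1 --out runs/demo` executes the whole loop and writes a
manifest with content hashes of every artifact.

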