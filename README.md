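# engfeat

Feature extraction and discrimination pipelines for multichannel
electroneurographic (ENG) recordings.

Peripheral-nerve interfaces such as multi-contact nerve cuffs record
*population* neural activity — compound signals with low SNR where single
units cannot be resolved. Decoding sensory state from such signals (here:
which of six hindlimb angles evoked the afferent response in a rat sciatic
nerve preparation) hinges far more on the choice of features than on the
classifier. `engfeat` implements five time-domain feature frameworks over
running observation windows, a supervised dimensionality reduction, a
cross-validated LDA harness, and a synthetic-data generator that emulates
the stimulation protocol so the whole chain is testable without animal data.

## Feature frameworks

All frameworks consume running observation windows (default 175 ms, 20%
overlap) cut from the 2.5 s steady state of each 3 s stimulus, after a
zero-phase 800–2200 Hz FIR bandpass. Every framework applies **window
fusion**: the current window's feature vector is multiplied elementwise
with one from an earlier window of the same stimulus and L2-normalised,
injecting temporal memory before classification.

- **MAV** — per-channel mean absolute value, `(1/N)·Σ|x_j|`.
- **MAV&WL** — MAV plus waveform length `Σ|x_{j+1} − x_j|`.
- **TDD** — six descriptors `f1–f6` built from root-squared power-spectrum
  moments `m̄0 = (Σx²)^½`, `m̄2 = ((1/N)Σ(Δx)²)^½`, `m̄4 = ((1/N)Σ(Δ²x)²)^½`
  (power-normalised `m = m̄^λ/λ`, λ = 0.1), computed entirely in the time
  domain via Parseval's relation; each channel's descriptors are combined
  with those of a log-scaled nonlinear copy `log(x²)²` through the
  similarity `−2·a_i·b_i/(a_i² + b_i²)`, and fused with the 3rd-previous
  window.
- **TSD** — TDD extended with the coefficient of variation and the
  Teager–Kaiser energy `Σ(x_j² − x_{j−1}·x_{j+1})` (`f7–f8`), evaluated on
  every channel *and* every between-channel difference `Cx − Cy`, with the
  norm-coupled similarity `a_i·b_i/(Σa² + Σb²)`.
- **STW (spatio-temporal warping)** — for every unordered channel pair and
  each of three derivative streams (signal, first, second difference), the
  dynamic-time-warping alignment cost between the two channels'
  simultaneous windows; `NC(NC−1)/2 · 3` features (360 for a 16-contact
  cuff). The log-scaled costs run through an LSTM-style memory with no
  trained parameters: a cell state accumulates `log(1+raw)` per window
  (long-term), window fusion multiplies in the previous output
  (short-term), and the β-weighted cell state (0.75 ≤ β ≤ 1.25) is mixed
  back before normalisation.

Downstream, orthogonal fuzzy neighbourhood discriminant analysis (OFNDA)
projects the features to at most one dimension per class (6), and a
shared-covariance LDA is scored with stratified 10-fold cross-validation.
Window-length effects are compared with Kruskal–Wallis plus
Bonferroni-adjusted pairwise rank tests; a timing harness measures mean
per-window extraction cost.

## Worked example

`examples/04_classification_pipeline.py` runs the full chain on the
bundled synthetic fixture (4 channels, 120 stimuli, 6 angle classes):

```
fixture: 4 ch, 120 stimuli, 6 angle classes
STW features: 360 windows x 18 columns
reduced to 6 dims; 10-fold accuracy 1.000 (folds [1. 1. 1. 1. 1. 1. 1. 1. 1. 1.])
confusion matrix (rows = true angle):
[[60  0  0  0  0  0]
 [ 0 60  0  0  0  0]
 ...
```

360 windows come from 120 stimuli × 3 windows of steady state; 18 STW
columns from 6 channel pairs × 3 derivative streams; the 6 reduced
dimensions match the 6 classes. Perfect accuracy reflects the fixture's
deliberately well-separated spatial gain patterns — shuffling the labels
drops accuracy to chance (≈ 1/6), as the test suite verifies.

The other examples show synthesis and spectra (`01`), the time-domain
frameworks (`02`), the STW memory mechanics (`03`) and the window sweep
plus timing grid (`05`). A thin CLI wraps the same functions:
`engfeat synth | features | classify | sweep | time`.

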