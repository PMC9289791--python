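# Methods

## Signal model and containers

A `Recording` is a channels × samples matrix with sampling rate, channel
ids and stimulus annotations (onset, duration, angle label). Sample
indices are 0-based; epochs are half-open `[start, stop)`; `onset_s` maps
to samples via `round(onset_s · fs)`. The native container is a flat
little-endian binary array (channel-major) with a JSON sidecar carrying
`fs`, channel ids, events and the array dtype — double precision by
default, single precision for generator output, either round-tripping
bit-exactly. CSV (samples as rows, header of channel ids) is supported
for interchange at 12-significant-digit precision.

## Preprocessing

The digital filter is a Hamming-windowed-sinc FIR bandpass, 800–2200 Hz,
default order 600 at 30 kHz (scaled proportionally at other rates),
applied forward–backward. Offline zero-phase filtering preserves event
alignment; the order gives > 40 dB attenuation a few hundred Hz outside
the band. Steady-state epochs trim 0.25 s from both ends of each
stimulus; epochs too short to survive the trim are skipped with a warning
rather than failing a whole recording. Window geometry: `W = round(
length_s · fs)`, `step = round(W · (1 − overlap))`, count `⌊(L − W)/step⌋
+ 1`, trailing partial windows discarded — deterministic and exactly
reproducible.

## Feature frameworks

Descriptor formulas are documented in the API; the choices that were
genuinely open:

- **Log guards.** Several descriptors take logarithms of differences
  (`m0 − m2`, TKEO sums) that can be non-positive; all logs evaluate
  `log(max(|·|, eps))` with `eps = 1e−8`. The sparseness and
  irregularity factors are computed as `S = m0/√((m0−m2)(m0−m4))` and
  `IF = √(m2²/(m0·m4))` with the same guards; zero crossings and peak
  counts are not computed separately (IF is defined through the moments).
- **COV guard.** The coefficient of variation divides by the window mean,
  which is near zero for bandpassed data; the denominator is
  `max(|mean|, eps)` and a constant window yields COV = 0 exactly.
- **Fusion.** The elementwise product of fusion partners is L2-normalised
  (the norm choice was open; L2 keeps rows on the unit sphere, with an
  all-zero guard). MAV and MAV&WL fuse recursively with the previous
  *fused* output (lag 1); TDD fuses the similarity vector with the raw
  similarity vector of the 3rd-previous window; TSD with the previous
  window's raw similarity (lag 1). Both lags are config fields. Fusion
  state resets at stimulus boundaries — fusing across stimuli would leak
  label information between instances.
- **TSD structure.** Descriptors are computed per stream (channels plus
  lexicographically ordered pairwise differences, x < y) and
  concatenated, giving stable column names; the nonlinear copy uses the
  same `log(x² + eps)²` transform as TDD.

## STW

DTW uses the classic dynamic programme with steps {(1,0), (0,1), (1,1)}
and absolute-difference local cost (squared cost and a Sakoe–Chiba band
are config options, both off by default — generic unconstrained DTW).
The two sequences compared are always the *simultaneous* windows of two
different channels (or of their difference streams); windows at different
time indices are never warped against each other. The inner loop is
numba-compiled; a pure-Python exhaustive path enumeration serves as the
test oracle.

The memory update per window, with `L = log(1 + raw + eps)` (non-negative
since DTW costs are non-negative, so the cell state is elementwise
non-decreasing):

```
cell'  = cell + L
fused  = L ⊙ prev_out        (L alone on the first window — pointwise switch)
out    = normalize(fused + β·cell') + normalize(log(1 + |cell'|))
```

The composition order of the published block diagram admits several
readings; this sequence — log-scale, accumulate, fuse, add the β-weighted
cell, normalise, add the normalised log cell — follows the stated order
of operations, and each sub-step is a separate function so variants can
be assembled. "Previous output" is read as the previous *final* output;
a config switch (`prev_partner="log"`) selects the raw log-distance
variant instead. β is a fixed scalar, default 1.0, validated against the
documented range [0.75, 1.25]; no per-iteration sampling, so the
extractor is fully deterministic. The normalisation function was left
unspecified in the source framework; L2 with an all-zero guard is used
throughout for consistency with window fusion.

## OFNDA

The published description delegates internals to its citation, so the
implementation fixes them explicitly: fuzzy memberships are
inverse-distance weights over each instance's k = 5 nearest neighbours
(self excluded), normalised per instance; class means and within-class
scatter are membership-weighted; between-class scatter weights each class
by its membership mass. Directions solve the generalized eigenproblem
`Sb v = λ(Sw + ridge·I)v` with a relative ridge of 1e−6 (logged and
escalated if the solver still fails), then thin-QR orthonormalisation.
The output dimension is capped at the number of classes. LDA uses the
SVD solver (pooled covariance, robust to collinear features); stratified
k-fold splits are seeded, with the fold partition covering every instance
exactly once.

Box statistics use linear-interpolation quantiles; whiskers extend to the
most extreme points within 1.5 × IQR and points beyond are outliers.
After Kruskal–Wallis, pairwise two-sided rank-sum tests are
Bonferroni-adjusted by the number of pairs; all-identical groups report
p = 1 rather than an undefined H statistic.

## Synthetic data

The generator emulates the stimulation protocol exactly (6 angles ×
5 blocks × 10 stimuli per angle per block, 3 s ON / 3 s OFF, seeded
pseudo-random order within blocks → 300 labelled stimuli by default) and
the recordings statistically:

- **Evoked activity** is Poisson shot noise: biphasic spike-like kernels
  (a Hann-windowed pair of carrier cycles at the neural-band midpoint,
  ~1.5 kHz) at Poisson times during ON phases. Class identity enters
  through a per-class spatial gain pattern across contacts (sinusoidal
  profile whose peak rotates with the class, modulation depth 0.6 by
  default) and a firing-rate multiplier growing with angle magnitude
  (200 Hz base, +50% at the largest angle). This mirrors the premise
  that angle information is distributed spatio-temporally across cuff
  contacts.
- **Background**: ongoing shot noise (50 Hz, variance 0.005), an
  EMG-like contaminant (colored noise below ~400 Hz, variance 0.05 —
  deliberately below the 800 Hz filter edge so the bandpass demonstrably
  removes it) and white amplifier noise (variance 0.01).
- Synthesis is single precision and seeded end-to-end; the low-frequency
  contaminant is generated at reduced rate and linearly upsampled (its
  interpolation images fall far above the contaminant band and are
  sinc²-attenuated), keeping the full default dataset (16 × 54 M
  samples) generatable in about a minute.

What the generator does **not** model: real spike waveform diversity,
inter-channel correlation beyond the gain patterns, electrode drift,
movement artefacts, or stimulation-locked transients beyond the trimmed
0.25 s. Passing pipeline tests therefore demonstrate correctness of the
processing chain and sensitivity to spatially distributed amplitude/rate
structure — not performance on animal recordings.

The easy fixture (4 channels at 10 kHz, 6 classes × 20 stimuli, 1 s ON,
gain depth 0.9, low noise) is sized so the full STW pipeline runs in
about a minute on one CPU while remaining strongly separable; its
near-perfect accuracy is a property of that construction, and the
shuffled-label control confirms the chain cannot manufacture accuracy
without label structure.

## Problem sizes in tests and scripts

The test suite exercises the full default protocol once (event
bookkeeping) and otherwise scales inputs down: short stimuli, reduced
sampling rates (2–10 kHz) and 3–4 channels, chosen so every property
remains non-trivial (windows hold hundreds of samples; DTW oracles use
exhaustive enumeration at length ≤ 6 where the path count is small).
Timing assertions compare orderings only, never absolute durations, since
wall-clock times are machine-dependent.

## Known limitations

- OFNDA with many more features than instances (TSD's 1088 columns)
  relies on the ridge; eigen-directions beyond rank(Sb) = C−1 carry no
  discriminative signal even though up to C are retained.
- The STW update is one faithful reading of an ambiguous diagram;
  alternative compositions are constructible from the exported sub-steps
  but only the default is validated end-to-end.
- CSV round-trips are exact to 12 significant digits, not bit-exact; use
  the binary container for archival.
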