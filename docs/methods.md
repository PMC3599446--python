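# Methods

This note documents the models, estimators, parameter choices and known
limitations of `songseg`. Defaults live in `songseg.pipeline.SegmentConfig`
and in the dataclasses of `songseg.synthetic_song`; everything listed here
is configurable.

## Signal model

A recording is a single channel of floating-point amplitude at a fixed
sample rate (default 10 kHz for synthetic data; integer PCM WAV is scaled
to [−1, 1) on read so thresholds are bit-depth independent). The song
model is additive: sparse pulse transients + intermittent sine song +
stationary Gaussian background noise of standard deviation σ.

## Noise floor

σ is estimated by partitioning the signal into non-overlapping 1 s
windows, ranking them by RMS, pooling the quietest 10% and taking their
SD. Because song occupies a minority of time and the estimator uses only
the quietest windows, σ is robust to song occupancy (tested up to 50%
occupancy, error ≤ 15%). An all-zero signal is floored at 1e-12 and
flagged `degenerate`. Both window length and quantile are parameters; 1 s
windows are long relative to a bout's trains but short relative to pauses,
which is what makes quiet windows plentiful.

## Pulse candidate detection

The continuous wavelet transform uses a complex Morlet
(`cmor1.5-1.0`) on 25 log-spaced scales whose center frequencies span
100–900 Hz — wide enough for the ~220 Hz fundamental and its second
harmonic, narrow enough to exclude low-frequency floor noise. For each
scale, |CWT| of Gaussian noise is Rayleigh; the per-scale noise level is
estimated as median/√(ln 4) (robust to sparse song) and the envelope is
the maximum over scales of the noise-normalized magnitude.

Candidates are local maxima of this envelope that

* exceed a threshold of √(k² + 2 ln n_scales) with k = 4 — the additive
  term is a Bonferroni-style correction for maximizing over `n_scales`
  normalized magnitudes, so `k` keeps its single-scale noise-sigma
  meaning (measured false-alarm rate on pure noise: well under one
  candidate per 10 s);
* stand at least a factor 2 above the envelope baseline (the smaller of
  the two side medians taken 1–2 refractory periods away). A pulse is by
  definition a *brief* transient; sustained oscillations (sine song) keep
  a flat envelope and are rejected here instead of flooding the culls;
* are separated by a 10 ms refractory period (closer maxima merge,
  keeping the larger).

Each candidate stores a ±10 ms waveform window re-centered on the
absolute raw-signal peak; windows clipped by the recording edge are
zero-padded and flagged, excluded from template building but kept in
counts. Detection is translation-equivariant and invariant to overall
amplitude rescaling (thresholds are in σ units).

## Heuristic culls

* **AmpCull**: peak amplitude ≥ 3σ (conservative, amplitude-only).
* **IPICull**: keep only pulses in runs of ≥ 2 whose successive intervals
  all lie in 15–100 ms. The bounds bracket the IPI distribution mass of
  melanogaster-like song; the run rule is this package's explicit,
  configurable stand-in for species-tuned IPI heuristics.

Culls are nested by construction: model ⊆ IPI ⊆ amplitude ⊆ candidates.

## Pulse model and likelihood cull

From ≥ 100 surviving pulses (fewer raises an explicit exclusion error —
individuals without a stable model are reported but excluded from
model-based statistics), per-recording templates are built:

1. windows are classed *fundamental* vs *second harmonic* by whether the
   window's peak-energy frequency exceeds 1.5 × the median carrier; the
   harmonic class gets its own template when it holds ≥ 10 pulses;
2. within a class, each unit-energy window is polarity-aligned to a
   running mean (pass 1), then lag-aligned (±2 ms) and polarity-aligned
   by cross-correlation to the pass-1 mean (pass 2), averaged, and
   re-normalized to unit energy. No post-hoc re-centering is applied: the
   windows are already peak-centered and the averaged peak is a plateau,
   so argmax-based rolling would add ±2-sample jitter.

The likelihood cull models a window as `x = a T + ε`, ε ~ N(0, σ²I), with
the amplitude the only fitted parameter, against the null `x = ε`:

    LLR_T = (‖x‖² − ‖x − a*T‖²) / (2σ²) = ⟨x, T⟩² / (2σ²)

maximized over an alignment lag of ±2 ms and over the available
templates. On white noise each fitted amplitude contributes χ²₁/2
(mean 1/2), so a plain `LLR > 0` rule would keep everything; `model_cull`
therefore subtracts the per-fit expectation 1/2 before applying the
positivity rule. Noise windows are then removed with probability
P(χ²₁ ≤ 1) ≈ 0.68 (verified by Monte-Carlo), while a genuine pulse's LLR
scales with pulse energy / 2σ² (hundreds at the default synthetic SNR).

Carrier frequency of a window is the peak of its 8×-zero-padded FFT power
spectrum with parabolic interpolation, restricted to 50–1000 Hz; spectral
flatness (Wiener entropy > ~0.5) flags low-confidence estimates on
near-white windows.

## Sine-train detection

Detected pulses are masked (windows zeroed, with a per-sample validity
track) so their broadband energy cannot mimic sine song. The masked
signal is analyzed in 100 ms frames stepped by 50 ms — the step defines
the 50 ms carrier-frequency bins — using K = 7 Slepian tapers at NW = 4
(standard multitaper variance/leakage trade-off for short frames).

A frame is "sine" under one of two criteria (config switch):

* **power** (default): band peak (100–300 Hz) of the taper-averaged
  spectrum > 8 × σ² (with unit-energy tapers a white-noise bin has
  expected power σ², and the taper average is χ²₁₄/14-concentrated, so
  8× is far in the null tail yet ~two orders of magnitude below a
  detectable sine's peak);
* **F-test**: Thomson's harmonic F statistic maximized over the band,
  tested at F(2, 2K−2) with a Bonferroni correction over the band's
  Rayleigh-resolution bin count (the F statistic is sharp in frequency,
  so it must be scanned, not evaluated at the broad power peak).

Frames more than 50% masked are skipped; a train may bridge one skipped
frame (pulses interleave with sine inside bouts; with bridging disabled
the detector over-splits, which is the documented bias direction).
Consecutive sine frames whose peak frequencies differ by ≤ 30 Hz merge;
trains shorter than 3 frames are culled. Per-bin carriers come from a
Hann-windowed periodogram with parabolic interpolation — the multitaper
main lobe (~2·NW/T ≈ 80 Hz) is flat-topped and good for detection but
poor for sub-bin frequency estimation.

Each accepted frame is credited one 50 ms step of sine time and the first
passing frame is not credited, because a frame already fires when only
its tail overlaps the sine onset; this symmetrizes the start/stop errors
(measured boundary bias ≲ 10 ms) and keeps adjacent trains disjoint.

## Song structure

Pulse trains are maximal runs with gaps ≤ 0.25 s (below the 0.5 s bout
criterion, above the IPI mass; configurable) and ≥ 2 pulses. Typed train
intervals merge into bouts when separated by < 0.5 s; gaps ≥ 0.5 s
between bouts are pauses. A bout may contain a single train — strict
alternation is not enforced. IPIs are taken within trains only and
timestamped at the first pulse of each pair, which makes the IPI series
unevenly sampled by construction.

## Per-individual statistics

* **IPI mixture**: two-component Gaussian mixture (EM, best of 10
  k-means-seeded restarts under a fixed seed, variance floor 1e-6) on raw
  IPIs in ms; components reported sorted by mean, the lower mean being
  the headline IPI statistic. The component mean (not a truncated sample
  mean) is reported.
* **Proportions**: recording time in sine trains / pulse trains
  (first-to-last pulse + half-window margins) / neither; sums to 1.
* **Within-bout trends**: per bout, the mean frequency of the initial
  50 ms bin of the first relevant train is subtracted, then scaled values
  are pooled across bouts per within-bout time bin (first-bin mean is 0
  by construction). Pulse-carrier trends use per-pulse carriers at pulse
  times; sine trends use the 50 ms bins.
* **Within-recording trends**: Pearson correlation of each parameter
  series against event time (≥ 10 events; constant series flagged NaN),
  with a one-sample t-test of per-individual correlations against zero.
* **Outliers**: iterative two-sided Grubbs test at α = 0.05 (largest
  absolute deviation removed while significant; needs n ≥ 3). On clean
  Gaussian samples the removal rate is ≈ α.

Across-strain ANOVA/ANCOVA is deliberately out of scope; the package
emits the per-individual table those standard tests consume.

## Rhythm analysis

The classical normalized Lomb–Scargle periodogram is computed on a grid
from 1/T to 1 Hz with spacing 1/(4T) (oversampling 4): values are
mean-centered, the tau-shifted power is evaluated from the two phasor
sums Σy·e^{iωt} and Σe^{2iωt} swept along the grid by a complex
recurrence (exact to ~1e-11 of the direct sums, orders of magnitude
faster), and power is normalized by the sample variance so noise-only
power is approximately Exp(1). On evenly sampled data the power equals
the classical periodogram at Fourier frequencies.

Local periodogram maxima receive false-alarm probabilities
p = 1 − (1 − e^(−z))^M. M defaults to the number of samples
(Horne–Baliunas-style); it is exact for independent Fourier frequencies
and only an order-of-magnitude estimate for clustered bout-structured
sampling — M is therefore a parameter (M = 1 gives the single-frequency
formula).

Injected-rhythm simulations add `baseline + A sin(2π f t + φ) + N(0, σ²)`
(φ uniform per seeded replicate) on realistic sampling times. The SNR
convention is **variance ratio**: snr = (A²/2)/σ², so A = √(2·snr)·σ; an
explicit amplitude override exists. Detection power at a given SNR is the
fraction of replicates with a significant (p < 0.05) local peak inside
the target band, default 0.016–0.022 Hz around the classically reported
0.0182 Hz (~55 s) IPI rhythm. Power is monotone in SNR and reproducible
bit-for-bit under a fixed seed.

## Evaluation

Detected pulses are matched one-to-one to reference pulses within ±10 ms
(safely below the ~35 ms IPI). Matching scans true pulses in time order
and pairs each with the earliest unmatched detection in its window;
because every pulse's candidate set is a contiguous run of detections
(convex bipartite structure), this greedy rule achieves maximum-cardinality
matching, verified against optimal assignment in tests. Sensitivity =
matched/true, PPV = matched/detected, F = their harmonic mean (F defined
0 when both are 0; undefined metrics flagged NaN). Sine song is compared
by per-recording train count, mean length and total time (plus interval
intersection), with paired two-tailed t-tests across recordings; no
train-identity matching is attempted.

## Synthetic-song generator

The generator is first-class, tested code and defines the study
conditions for every end-to-end check:

* **Pulses**: Gabor wavelets (cosine carrier × Gaussian envelope,
  SD 2.5 ms), carrier 220 Hz ± 10 Hz jitter, amplitude 0.25 against noise
  SD 0.05 (peak SNR 5); with probability 0.17 a pulse's carrier doubles
  (second-harmonic class). IPIs ~ N(35 ms, 3 ms) clipped to 16–99 ms.
* **Sine**: 150 Hz base carrier, amplitude 0.15, phase-continuous with a
  +3 Hz/s within-bout ramp and a +15 Hz drift across the recording
  (the observed scale of within-recording carrier increase), 10 ms
  cosine on/off tapers.
* **Structure**: alternating pulse/sine trains (lognormal lengths, means
  1.0 s and 1.5 s), 2–4 trains per bout, intra-bout gaps uniform in
  0.10–0.40 s (< 0.5 s by construction), pauses 0.5 s + Exp(3 s). At the
  14-minute default this yields a few thousand pulses, matching the scale
  of real recordings; tests use 30–60 s scaled versions.
* **Rhythm sampling**: `rhythm_sampling_config` uses shorter pulse trains
  (0.35 s) and longer pauses (0.5 + Exp(13 s)) so one 840 s session
  yields ~600 uneven IPI sampling times — the regime the power analysis
  is defined on; `sample_times_for_rhythm` uses only the structural
  layout (no waveform rendering). An optional sinusoidal IPI modulation
  can be injected at generation time.

Ground truth records every pulse time and class, train, bout, and
per-50 ms-bin sine frequency; generation is bit-reproducible under a
fixed seed.

What the generator does **not** emulate: non-Gaussian and non-stationary
background (grooming, jumps, electrical transients), microphone frequency
response, amplitude modulation within trains, overlapping pulse and sine
song, multi-fly crosstalk, and the naturally skewed IPI distribution
(IPIs are clipped-Gaussian per train). Passing end-to-end tests therefore
demonstrates correctness of the algorithms under the stated signal model,
not field performance on arbitrary real recordings — on real data the
heuristic constants (band edges, thresholds, culling bounds) are the
knobs to retune.

## Numerical choices and degenerate inputs

* All times in seconds, intervals half-open; annotation CSV times stored
  at nanosecond precision.
* Parabolic peak interpolation is clipped to ±0.5 bin and skipped at
  spectrum edges.
* GMM degeneracy (zero-spread input) returns a flagged single-point fit;
  EM monotonicity is asserted in tests by single-iteration stepping.
* Constant series: rejected by the periodogram (no variance to
  normalize), flagged NaN by trend correlations.
* Seeds: every stochastic routine takes an explicit seed; replicate seeds
  are spawned via `numpy.random.SeedSequence` and kept below 2³¹.

## Problem sizes used in validation

End-to-end tests run on 60 s synthetic songs (a few hundred pulses,
~17 s of sine); power analyses use ≥ 200 replicates of ~600-sample
(IPI) or ~2,400-sample (dense 50 ms) series over 840 simulated seconds;
null calibrations use 300–10,000 Monte-Carlo draws. These sizes were
chosen so each claim's Monte-Carlo error is comfortably below the margin
it is tested at.
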