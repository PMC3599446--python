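# songseg

Automated segmentation and analysis of *Drosophila melanogaster* courtship
song.

Courting males sing with one wing, alternating two modes: **pulse song**,
trains of brief (~few ms) transients with a carrier near 220 Hz separated
by ~35 ms inter-pulse intervals (IPIs), and **sine song**, a sustained
near-sinusoid around 100–200 Hz. Manual annotation of these events is slow
and biased; `songseg` segments recordings automatically and computes the
per-individual statistics (carrier frequencies, IPI mixture, song
proportions, train/bout durations, temporal trends, rhythm periodograms)
that downstream genetic and behavioral analyses consume.

## Method at a glance

1. **Noise floor** — σ is the pooled SD of the quietest 10% of 1 s
   windows of the raw signal.
2. **Pulse detection** — the scale-maximized modulus of a complex Morlet
   continuous wavelet transform (25 log-spaced scales, 100–900 Hz),
   normalized per scale to noise-sigma units; candidate pulses are
   transient local maxima above *k*σ (default *k* = 4, with a
   scale-multiplicity correction).
3. **Winnowing** — three nested culls: `AmpCull` (peak amplitude ≥ 3σ),
   `IPICull` (runs of ≥ 2 pulses with IPIs in 15–100 ms), and `ModelCull`:
   each window *x* is scored against the per-recording unit-energy pulse
   template *T* (plus a second-harmonic template) by the log-likelihood
   ratio of "scaled template + white noise" vs. white noise,

       LLR = (‖x‖² − ‖x − a*T‖²) / (2σ²),   a* = ⟨x, T⟩,

   and kept when the LLR exceeds the single fitted amplitude's
   chance expectation (χ²₁/2). Individuals with fewer than ~100 pulses
   are excluded from model-based analysis.
4. **Sine detection** — pulses are masked, then 100 ms frames (50 ms step)
   get a Slepian multitaper spectrum (NW = 4, K = 7); frames whose
   100–300 Hz band peak passes a power-ratio (or Thomson F-test)
   criterion merge into trains, with short trains culled and a carrier
   frequency tracked per 50 ms bin.
5. **Structure** — pulse trains (≥ 2 pulses), bouts (trains separated by
   < 0.5 s), pauses (≥ 0.5 s), and the unevenly-sampled IPI series.
6. **Statistics & rhythms** — two-component Gaussian mixture of IPIs
   (the lower component's mean is the headline IPI), sine/pulse/no-song
   proportions, within-bout and within-recording carrier trends, iterative
   Grubbs outlier removal, and classical normalized Lomb–Scargle
   periodograms with local-peak false-alarm probabilities
   p = 1 − (1 − e^(−z))^M for unevenly sampled song-parameter series.

Every stage is validated against a bundled synthetic-song generator that
emits ground-truthed recordings (Gabor pulses with a 17% second-harmonic
class, drifting sine trains, bout structure, Gaussian noise at controlled
SNR), so the whole pipeline is testable without any recordings.

## Worked example

```python
import numpy as np
import songseg as ss
from songseg.pipeline import segment
from songseg.song_structure import extract_ipi_series

cfg = ss.SynthConfig(duration_s=60.0, seed=1)   # 60 s synthetic song
rec, truth, events = ss.generate(cfg)
res = segment(rec)

det = np.array([p.center_time_s for p in res.model_culled])
ev = ss.evaluation.evaluate_pulses(truth.pulses, det)
fit = ss.fit_ipi_gmm(extract_ipi_series(res.pulse_trains).ipis_s * 1000)
```

which prints, via the obvious `print` statements:

```
true pulses: 314, detected after ModelCull: 314
sensitivity=1.000 PPV=1.000 F=1.000
sine trains: 11 true / 11 detected; total sine 16.96 s true / 17.05 s detected
pulse carrier: 219.2 Hz; IPI mixture lower mean: 33.5 ms
bouts: 8, pauses: 7
```

All 314 generated pulses are recovered with no false positives
(sensitivity, positive predictive value and their harmonic mean F all 1),
detected sine time agrees with the generated truth to 0.5%, the pulse
template's carrier recovers the generator's 220 Hz, and the lower mixture
component sits at the short-IPI mode.

The same pipeline is available from the shell:

```bash
songseg simulate --duration 60 --seed 1 --out out/sim
songseg segment out/sim/song.wav --out out/seg
songseg evaluate --truth out/sim/truth --detected out/seg --tol-ms 10
songseg rhythms --series ipi.csv --out out/rhythms
```

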