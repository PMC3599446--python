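"""Noise-floor estimation, wavelet pulse detection, and heuristic culls.

The detection chain mirrors the staged winnowing of the segmenter:

1. the background noise floor is estimated from the quietest stretches of
   the raw signal;
2. candidate pulses are local maxima of the scale-maximized continuous
   wavelet transform envelope (complex Morlet, ~100-900 Hz) exceeding a
   threshold expressed in noise-sigma units;
3. ``amp_cull`` applies a conservative amplitude-only winnow;
4. ``ipi_cull`` keeps only pulses occurring in runs with inter-pulse
   intervals typical of D. melanogaster pulse song.

Each stage returns a subset of the previous one (monotone culling).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pywt
from scipy import signal

from songseg.audio_io import Recording

__all__ = [
    "NoiseEstimate",
    "PulseCandidate",
    "estimate_noise_floor",
    "detect_pulse_candidates",
    "amp_cull",
    "ipi_cull",
]

#: amplitude floor used instead of zero for pathological silent input
_SIGMA_FLOOR = 1e-12

#: Rayleigh median -> sigma conversion for |complex CWT| of Gaussian noise
_RAYLEIGH_MEDIAN = np.sqrt(np.log(4.0))

_STAGES = ("candidate", "amp_cull", "ipi_cull", "model_cull")


@dataclass(frozen=True)
class NoiseEstimate:
    """Robust background amplitude SD from the quietest windows."""

    sigma: float
    window_s: float
    quantile: float
    n_windows_used: int
    degenerate: bool = False


@dataclass(frozen=True)
class PulseCandidate:
    """A putative pulse: center time, waveform window, and wavelet scale.

    ``window`` is a fixed-width excerpt centered on the within-window
    absolute sample peak; windows truncated at the recording boundary are
    zero-padded and flagged via ``edge``.
    """

    center_time_s: float
    peak_amplitude: float
    best_scale_freq_hz: float
    window: np.ndarray
    stage: str = "candidate"
    edge: bool = False

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


def estimate_noise_floor(
    rec: Recording, window_s: float = 1.0, quantile: float = 0.1
) -> NoiseEstimate:
    """Estimate the noise floor from the quietest fraction of the recording.

    The signal is partitioned into non-overlapping windows of ``window_s``
    seconds which are ranked by RMS; the lowest ``quantile`` fraction
    (at least one window) is pooled and its SD returned.  Because song is
    sparse in time, the quietest windows are essentially song-free, so the
    estimate is not inflated by song.
    """
    n_win = int(round(window_s * rec.sample_rate))
    n_windows = len(rec.samples) // n_win
    if n_windows < 1:
        raise ValueError(
            f"recording ({rec.duration_s:.3f} s) shorter than one noise window "
            f"({window_s} s)"
        )
    segs = rec.samples[: n_windows * n_win].reshape(n_windows, n_win)
    rms = np.sqrt(np.mean(segs**2, axis=1))
    k = max(1, int(np.ceil(quantile * n_windows)))
    quietest = segs[np.argsort(rms)[:k]].ravel()
    sigma = float(np.std(quietest))
    degenerate = sigma < _SIGMA_FLOOR
    if degenerate:
        sigma = _SIGMA_FLOOR
    return NoiseEstimate(
        sigma=sigma,
        window_s=window_s,
        quantile=quantile,
        n_windows_used=k,
        degenerate=degenerate,
    )


def _cwt_envelope(
    samples: np.ndarray,
    sample_rate: int,
    fmin_hz: float,
    fmax_hz: float,
    n_scales: int,
    wavelet: str,
):
    """Scale-maximized |CWT| envelope normalized to noise-sigma units.

    Each scale's magnitude is divided by a robust per-scale noise level
    (Rayleigh median of |coefficients|), so the returned envelope is a
    z-score-like quantity: Gaussian background maps to O(1) values
    regardless of scale or overall amplitude.
    """
    if not 0 < fmin_hz < fmax_hz:
        raise ValueError(f"invalid scale frequency range [{fmin_hz}, {fmax_hz}]")
    if fmax_hz >= sample_rate / 2:
        raise ValueError("fmax_hz must be below Nyquist")
    freqs = np.geomspace(fmin_hz, fmax_hz, n_scales)
    scales = pywt.frequency2scale(wavelet, freqs / sample_rate)
    coefs, _ = pywt.cwt(samples, scales, wavelet, method="fft")
    mag = np.abs(coefs)
    noise_level = np.median(mag, axis=1) / _RAYLEIGH_MEDIAN
    noise_level = np.maximum(noise_level, _SIGMA_FLOOR)
    z = mag / noise_level[:, None]
    best_scale = np.argmax(z, axis=0)
    envelope = z[best_scale, np.arange(z.shape[1])]
    return envelope, freqs[best_scale]


def _ring_baseline(envelope: np.ndarray, p: int, distance: int) -> float:
    """Envelope baseline around a peak: the smaller of the two side medians
    taken one-to-two refractory periods away (a transient has at least one
    — in practice both — quiet flank; a sustained tone has neither)."""
    left = envelope[max(p - 2 * distance, 0) : max(p - distance, 0)]
    right = envelope[p + distance : p + 2 * distance]
    sides = [float(np.median(s)) for s in (left, right) if s.size]
    return min(sides) if sides else 0.0


def extract_window(samples: np.ndarray, center: int, half_width: int):
    """Fixed-width excerpt around ``center``, zero-padded at the edges."""
    n = len(samples)
    lo, hi = center - half_width, center + half_width + 1
    edge = lo < 0 or hi > n
    window = np.zeros(2 * half_width + 1)
    src_lo, src_hi = max(lo, 0), min(hi, n)
    window[src_lo - lo : src_hi - lo] = samples[src_lo:src_hi]
    return window, edge


def detect_pulse_candidates(
    rec: Recording,
    noise: NoiseEstimate,
    *,
    fmin_hz: float = 100.0,
    fmax_hz: float = 900.0,
    n_scales: int = 25,
    k_sigma: float = 4.0,
    refractory_s: float = 0.010,
    window_s: float = 0.010,
    wavelet: str = "cmor1.5-1.0",
    transient_factor: float = 2.0,
) -> list[PulseCandidate]:
    """Find candidate pulses as peaks of the wavelet transform envelope.

    A candidate is a local maximum of the scale-maximized, noise-normalized
    |CWT| envelope exceeding ``k_sigma``; maxima closer than
    ``refractory_s`` are merged keeping the larger.  Because a pulse is a
    *brief* transient, the peak must additionally stand at least
    ``transient_factor`` above the envelope baseline one-to-two refractory
    periods away on both sides; sustained oscillations (sine song) keep a
    flat envelope and are rejected here rather than flooding the culls.
    Each candidate stores a +-``window_s`` waveform excerpt re-centered on
    the absolute raw-signal peak, and the frequency equivalent of the
    maximizing wavelet scale.
    """
    envelope, best_freq = _cwt_envelope(
        rec.samples, rec.sample_rate, fmin_hz, fmax_hz, n_scales, wavelet
    )
    # the envelope maximizes over n_scales noise-normalized magnitudes, so
    # the applied threshold carries a Bonferroni-style scale-multiplicity
    # correction; k_sigma keeps its single-scale noise-sigma meaning
    threshold = np.sqrt(k_sigma**2 + 2.0 * np.log(n_scales))
    distance = max(1, int(round(refractory_s * rec.sample_rate)))
    peaks, _ = signal.find_peaks(envelope, height=threshold, distance=distance)
    if transient_factor > 0:
        peaks = [
            p
            for p in peaks
            if envelope[p]
            >= transient_factor * _ring_baseline(envelope, p, distance)
        ]
    half = int(round(window_s * rec.sample_rate))

    cands: list[PulseCandidate] = []
    for p in peaks:
        # re-center on the absolute raw-signal peak inside the window
        lo, hi = max(p - half, 0), min(p + half + 1, len(rec.samples))
        center = lo + int(np.argmax(np.abs(rec.samples[lo:hi])))
        window, edge = extract_window(rec.samples, center, half)
        cands.append(
            PulseCandidate(
                center_time_s=center / rec.sample_rate,
                peak_amplitude=float(np.abs(rec.samples[center])),
                best_scale_freq_hz=float(best_freq[p]),
                window=window,
                stage="candidate",
                edge=edge,
            )
        )
    # re-centering can collapse neighbours onto the same raw peak: dedupe,
    # keeping the larger envelope candidate (they arrive in time order)
    deduped: list[PulseCandidate] = []
    for c in cands:
        if deduped and abs(c.center_time_s - deduped[-1].center_time_s) < refractory_s:
            if c.peak_amplitude > deduped[-1].peak_amplitude:
                deduped[-1] = c
        else:
            deduped.append(c)
    return deduped


def amp_cull(
    cands: list[PulseCandidate], noise: NoiseEstimate, amp_factor: float = 3.0
) -> list[PulseCandidate]:
    """Conservative amplitude-only winnow: keep peaks >= amp_factor * sigma."""
    if amp_factor < 0:
        raise ValueError("amp_factor must be >= 0")
    threshold = amp_factor * noise.sigma
    return [
        replace(c, stage="amp_cull") for c in cands if c.peak_amplitude >= threshold
    ]


def ipi_cull(
    cands: list[PulseCandidate],
    ipi_min_s: float = 0.015,
    ipi_max_s: float = 0.100,
    min_run: int = 2,
) -> list[PulseCandidate]:
    """Keep pulses in runs of >= min_run with song-like inter-pulse intervals.

    Candidates are split wherever a successive interval falls outside
    [ipi_min_s, ipi_max_s]; segments with fewer than ``min_run`` pulses are
    discarded.  Isolated pulses never survive (min_run >= 2).
    """
    if not 0 < ipi_min_s < ipi_max_s:
        raise ValueError("need 0 < ipi_min_s < ipi_max_s")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    if not cands:
        return []
    times = np.array([c.center_time_s for c in cands])
    gaps_ok = (np.diff(times) >= ipi_min_s) & (np.diff(times) <= ipi_max_s)
    kept: list[PulseCandidate] = []
    run_start = 0
    for i in range(len(cands)):
        end_of_run = i == len(cands) - 1 or not gaps_ok[i]
        if end_of_run:
            if i + 1 - run_start >= min_run:
                kept.extend(
                    replace(c, stage="ipi_cull") for c in cands[run_start : i + 1]
                )
            run_start = i + 1
    return kept
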