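"""Sine-train detection by multitaper spectral analysis of pulse-masked audio.

Pulse windows are first zeroed out (with a validity track) so the broadband
pulse transients do not masquerade as sine song.  The masked signal is cut
into overlapping frames (default 100 ms, 50 ms step); each frame gets a
Slepian multitaper spectrum, and a frame is declared "sine" when the peak
of the sine band (default 100-300 Hz) passes either a power-ratio
criterion against the white-noise floor or Thomson's harmonic F-test
(configurable).  Consecutive sine frames with continuous peak frequency
merge into trains; short trains are discarded (length cull).  Each train
carries a per-50-ms-bin carrier-frequency track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import windows

from songseg.audio_io import Recording
from songseg.pulse_detect import NoiseEstimate, PulseCandidate

__all__ = ["MaskedRecording", "SineTrain", "mask_pulses", "detect_sine_trains",
           "sine_carrier_track"]


@dataclass
class MaskedRecording:
    """A recording with pulse windows zeroed and a per-sample validity track."""

    recording: Recording
    valid: np.ndarray  # bool, False where samples were masked


@dataclass
class SineTrain:
    """A detected sine-song interval with a 50 ms carrier-frequency track."""

    start_s: float
    stop_s: float
    bin_freqs_hz: np.ndarray
    step_s: float = 0.05

    def __post_init__(self):
        self.bin_freqs_hz = np.asarray(self.bin_freqs_hz, dtype=float)
        if not self.stop_s > self.start_s:
            raise ValueError("sine train must have positive length")

    @property
    def length_s(self) -> float:
        return self.stop_s - self.start_s

    @property
    def mean_freq_hz(self) -> float:
        return float(np.mean(self.bin_freqs_hz))


def mask_pulses(
    rec: Recording, pulses: list[PulseCandidate], window_s: float = 0.010
) -> MaskedRecording:
    """Zero out +-window_s around each pulse; return the copy + validity track."""
    samples = rec.samples.copy()
    valid = np.ones(len(samples), dtype=bool)
    half = int(round(window_s * rec.sample_rate))
    for p in pulses:
        c = int(round(p.center_time_s * rec.sample_rate))
        lo, hi = max(c - half, 0), min(c + half + 1, len(samples))
        samples[lo:hi] = 0.0
        valid[lo:hi] = False
    masked = Recording(samples, rec.sample_rate, channel_id=rec.channel_id)
    return MaskedRecording(recording=masked, valid=valid)


def _multitaper_psd(frame: np.ndarray, tapers: np.ndarray, nfft: int) -> np.ndarray:
    """Mean over tapers of |FFT(taper * frame)|^2 (unit-energy tapers).

    With this scaling a white-noise frame of variance sigma^2 has expected
    per-bin power sigma^2, so power thresholds read directly in noise-
    variance units.
    """
    spec = np.fft.rfft(tapers * frame[None, :], nfft, axis=1)
    return np.mean(np.abs(spec) ** 2, axis=0)


def _harmonic_ftest_stat(frame: np.ndarray, tapers: np.ndarray, nfft: int) -> np.ndarray:
    """Thomson's harmonic F statistic per frequency bin (K tapers, 2,2K-2 dof)."""
    k = tapers.shape[0]
    y = np.fft.rfft(tapers * frame[None, :], nfft, axis=1)  # (K, nbins)
    h0 = tapers.sum(axis=1)  # DC gain of each taper
    mu = (h0[:, None] * y).sum(axis=0) / np.sum(h0**2)
    resid = np.sum(np.abs(y - mu[None, :] * h0[:, None]) ** 2, axis=0)
    resid = np.maximum(resid, 1e-300)
    return (k - 1) * np.abs(mu) ** 2 * np.sum(h0**2) / resid


def _parabolic_peak(power: np.ndarray, k: int, df: float, f0: float) -> float:
    if 0 < k < len(power) - 1:
        a, b, c = power[k - 1], power[k], power[k + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
    else:
        delta = 0.0
    return f0 + (k + delta) * df


def detect_sine_trains(
    masked: MaskedRecording,
    noise: NoiseEstimate,
    *,
    frame_s: float = 0.100,
    step_s: float = 0.050,
    nw: float = 4.0,
    k_tapers: int = 7,
    band_hz: tuple[float, float] = (100.0, 300.0),
    criterion: str = "power",
    alpha: float = 0.05,
    power_factor: float = 8.0,
    max_jump_hz: float = 30.0,
    min_len_frames: int = 3,
    bridge_frames: int = 1,
    max_masked_fraction: float = 0.5,
) -> list[SineTrain]:
    """Detect sine trains on a pulse-masked recording.

    Frames overlapping pulse masks by more than ``max_masked_fraction``
    are skipped; a train may bridge up to ``bridge_frames`` consecutive
    skipped frames (pulses interleave with sine inside bouts).  Trains
    shorter than ``min_len_frames`` frames are discarded (length cull).
    """
    rec = masked.recording
    n_frame = int(round(frame_s * rec.sample_rate))
    n_step = int(round(step_s * rec.sample_rate))
    if n_frame > len(rec.samples):
        raise ValueError("frame longer than recording")
    if criterion not in ("power", "ftest"):
        raise ValueError(f"unknown sine criterion {criterion!r}")
    tapers = windows.dpss(n_frame, nw, k_tapers)  # unit-energy rows
    hann = windows.hann(n_frame)
    nfft = max(4 * n_frame, 1 << int(np.ceil(np.log2(n_frame))))
    freqs = np.fft.rfftfreq(nfft, 1.0 / rec.sample_rate)
    df = freqs[1] - freqs[0]
    band_idx = np.flatnonzero((freqs >= band_hz[0]) & (freqs <= band_hz[1]))
    if band_idx.size == 0:
        raise ValueError(f"sine band {band_hz} is empty at this sample rate")
    sigma2 = noise.sigma**2

    n_frames = 1 + (len(rec.samples) - n_frame) // n_step
    frame_state: list[tuple[str, float]] = []  # (status, peak_freq)
    for i in range(n_frames):
        lo = i * n_step
        seg_valid = masked.valid[lo : lo + n_frame]
        if np.mean(~seg_valid) > max_masked_fraction:
            frame_state.append(("skipped", np.nan))
            continue
        frame = rec.samples[lo : lo + n_frame]
        psd = _multitaper_psd(frame, tapers, nfft)
        k_abs = band_idx[int(np.argmax(psd[band_idx]))]
        if criterion == "power":
            is_sine = psd[k_abs] > power_factor * sigma2
        else:
            # scan the whole band for a spectral line (the F statistic is
            # sharp in frequency), Bonferroni-corrected over the number of
            # Rayleigh-resolution bins in the band
            fstat = _harmonic_ftest_stat(frame, tapers, nfft)
            fmax = np.max(fstat[band_idx])
            n_indep = max(1, int(round((band_hz[1] - band_hz[0]) * frame_s)))
            p = stats.f.sf(fmax, 2, 2 * k_tapers - 2) * n_indep
            is_sine = p < alpha
        if is_sine:
            # carrier estimation uses a Hann periodogram: the multitaper
            # main lobe (~2*NW/frame wide, flat-topped) is good for
            # detection but poor for sub-bin frequency interpolation
            hann_psd = np.abs(np.fft.rfft(hann * frame, nfft)) ** 2
            k_h = band_idx[int(np.argmax(hann_psd[band_idx]))]
            peak_f = _parabolic_peak(hann_psd, k_h, df, 0.0)
            frame_state.append(("sine", peak_f))
        else:
            frame_state.append(("quiet", np.nan))

    # merge consecutive sine frames into trains, bridging skipped frames
    trains: list[SineTrain] = []
    cur: list[tuple[int, float]] = []  # (frame index, peak freq)
    skipped_run = 0

    def flush():
        nonlocal cur
        if len(cur) >= min_len_frames:
            # each frame hop is credited one step of sine time (so trains
            # from adjacent frame groups never overlap), and the first
            # passing frame is not credited: a frame already fires when
            # only its tail overlaps the sine onset, so its bin lies
            # mostly before the train and would bias starts early
            first, last = cur[0][0], cur[-1][0]
            start = (first + 1) * step_s
            stop = (last + 1) * step_s
            trains.append(
                SineTrain(
                    start_s=start,
                    stop_s=stop,
                    bin_freqs_hz=np.array([f for _, f in cur[1:]]),
                    step_s=step_s,
                )
            )
        cur = []

    for i, (status, f) in enumerate(frame_state):
        if status == "sine":
            if cur and (
                skipped_run > bridge_frames
                or abs(f - cur[-1][1]) > max_jump_hz
            ):
                flush()
            cur.append((i, f))
            skipped_run = 0
        elif status == "skipped" and cur:
            skipped_run += 1
        else:  # quiet, or skipped before any sine frame
            flush()
            skipped_run = 0
    flush()
    return trains


def sine_carrier_track(train: SineTrain) -> list[tuple[float, float]]:
    """(bin-center time, carrier Hz) pairs, one per 50 ms bin of the train."""
    return [
        (train.start_s + (i + 0.5) * train.step_s, float(f))
        for i, f in enumerate(train.bin_freqs_hz)
    ]
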