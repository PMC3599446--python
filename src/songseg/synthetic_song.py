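"""Ground-truthed synthetic courtship-song generator.

Emulates the statistical structure of D. melanogaster male courtship
song as the segmenter assumes it:

* **pulse song** — trains of brief Gabor-shaped transients (sinusoidal
  carrier ~220 Hz times a Gaussian envelope, SD ~2.5 ms) separated by
  ~35 ms inter-pulse intervals; a fraction (~17%) of pulses carry their
  peak energy at twice the carrier (second-harmonic class);
* **sine song** — sustained near-sinusoids (~150 Hz) whose carrier
  drifts slowly upward within a bout and across the recording;
* **bout structure** — alternating pulse and sine trains separated by
  short (< 0.5 s) intra-bout gaps, with inter-bout pauses >= 0.5 s;
* additive Gaussian background noise at a controlled level.

Every generated pulse time, pulse class, train, bout, and per-50-ms-bin
sine frequency is recorded as ground truth, so every pipeline stage can
be scored without any external data.  Generation is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from songseg.audio_io import Recording, SongAnnotation

__all__ = [
    "PulseParams",
    "SineParams",
    "StructureParams",
    "SynthConfig",
    "rhythm_sampling_config",
    "generate",
    "render_pulse",
    "sample_times_for_rhythm",
]


@dataclass
class PulseParams:
    """Pulse-song event parameters (times in ms, amplitudes in signal units)."""

    carrier_hz: float = 220.0
    carrier_jitter_hz: float = 10.0
    envelope_sd_ms: float = 2.5
    amplitude: float = 0.25
    harmonic_fraction: float = 0.17
    ipi_mean_ms: float = 35.0
    ipi_sd_ms: float = 3.0


@dataclass
class SineParams:
    carrier_hz: float = 150.0
    amplitude: float = 0.15
    #: within-bout upward carrier ramp, Hz per second of bout time
    within_bout_ramp_hz_per_s: float = 3.0
    #: total slow upward drift across the whole recording, Hz
    within_recording_drift_hz: float = 15.0
    #: on/off amplitude taper at train edges, s
    taper_s: float = 0.01


@dataclass
class StructureParams:
    """Lognormal train lengths, uniform intra-bout gaps, shifted-exponential pauses."""

    pulse_train_mean_s: float = 1.0
    pulse_train_sd_s: float = 0.4
    sine_train_mean_s: float = 1.5
    sine_train_sd_s: float = 0.6
    min_train_s: float = 0.25
    intra_bout_gap_range_s: tuple[float, float] = (0.10, 0.40)
    pause_min_s: float = 0.5
    pause_mean_extra_s: float = 3.0
    trains_per_bout_range: tuple[int, int] = (2, 4)

    def __post_init__(self):
        if self.intra_bout_gap_range_s[1] >= 0.5:
            raise ValueError("intra-bout gaps must stay below the 0.5 s bout criterion")
        if self.pause_min_s < 0.5:
            raise ValueError("inter-bout pauses must be >= 0.5 s")


@dataclass
class IpiRhythm:
    """Optional sinusoidal modulation of the IPI, in ms."""

    f_hz: float = 0.0182
    amplitude_ms: float = 3.0
    phase: float = 0.0


@dataclass
class SynthConfig:
    sample_rate: int = 10_000
    duration_s: float = 840.0
    noise_sd: float = 0.05
    pulse: PulseParams = field(default_factory=PulseParams)
    sine: SineParams = field(default_factory=SineParams)
    structure: StructureParams = field(default_factory=StructureParams)
    ipi_rhythm: IpiRhythm | None = None
    seed: int = 0


def rhythm_sampling_config(seed: int = 0, duration_s: float = 840.0) -> SynthConfig:
    """Structure tuned for the rhythm power analysis: ~600 IPI samples / 14 min.

    Shorter pulse trains and longer pauses than the song-statistics
    default, emulating the sparser pulse production of the recordings the
    power analysis was anchored to.
    """
    return SynthConfig(
        duration_s=duration_s,
        seed=seed,
        structure=StructureParams(
            pulse_train_mean_s=0.35,
            pulse_train_sd_s=0.15,
            sine_train_mean_s=2.0,
            sine_train_sd_s=0.8,
            pause_mean_extra_s=13.0,
            trains_per_bout_range=(2, 3),
        ),
    )


def _lognormal(rng, mean, sd, floor):
    """Lognormal draw parameterized by its own mean and SD, floored."""
    var = sd**2
    mu = np.log(mean**2 / np.sqrt(var + mean**2))
    s = np.sqrt(np.log(1 + var / mean**2))
    return max(float(rng.lognormal(mu, s)), floor)


def _layout(rng: np.random.Generator, cfg: SynthConfig) -> list[dict]:
    """Draw the train/bout skeleton: typed intervals + per-train pulse times."""
    st = cfg.structure
    pp = cfg.pulse
    trains: list[dict] = []
    t = st.pause_min_s + rng.exponential(st.pause_mean_extra_s) * 0.25
    bout_id = 0
    while True:
        n_trains = rng.integers(st.trains_per_bout_range[0], st.trains_per_bout_range[1] + 1)
        first_type = "pulse" if rng.random() < 0.5 else "sine"
        bout_done = False
        for k in range(n_trains):
            typ = first_type if k % 2 == 0 else ("sine" if first_type == "pulse" else "pulse")
            if typ == "pulse":
                length = _lognormal(rng, st.pulse_train_mean_s, st.pulse_train_sd_s, st.min_train_s)
                pulse_times = [t]
                while True:
                    ipi = rng.normal(pp.ipi_mean_ms, pp.ipi_sd_ms)
                    if cfg.ipi_rhythm is not None:
                        r = cfg.ipi_rhythm
                        ipi += r.amplitude_ms * np.sin(
                            2 * np.pi * r.f_hz * pulse_times[-1] + r.phase
                        )
                    ipi = float(np.clip(ipi, 16.0, 99.0)) / 1000.0
                    if pulse_times[-1] + ipi > t + length:
                        break
                    pulse_times.append(pulse_times[-1] + ipi)
                if len(pulse_times) < 2:  # degenerate short train: force a pair
                    pulse_times.append(pulse_times[-1] + pp.ipi_mean_ms / 1000.0)
                stop = pulse_times[-1]
                trains.append(
                    {"type": "pulse", "start_s": t, "stop_s": stop,
                     "pulse_times": pulse_times, "bout": bout_id}
                )
                t = stop
            else:
                length = _lognormal(rng, st.sine_train_mean_s, st.sine_train_sd_s, st.min_train_s)
                trains.append(
                    {"type": "sine", "start_s": t, "stop_s": t + length, "bout": bout_id}
                )
                t += length
            if t > cfg.duration_s - 1.0:
                bout_done = True
                break
            if k < n_trains - 1:
                t += rng.uniform(*st.intra_bout_gap_range_s)
        bout_id += 1
        t += st.pause_min_s + rng.exponential(st.pause_mean_extra_s)
        if bout_done or t > cfg.duration_s - 1.0:
            break
    return [tr for tr in trains if tr["stop_s"] <= cfg.duration_s - 0.05]


def render_pulse(
    sample_rate: int,
    carrier_hz: float,
    envelope_sd_s: float,
    amplitude: float,
    half_support_sds: float = 4.0,
) -> np.ndarray:
    """Analytic Gabor pulse: amplitude * cos(2 pi f tau) * exp(-tau^2 / 2 sd^2)."""
    half = int(round(half_support_sds * envelope_sd_s * sample_rate))
    tau = np.arange(-half, half + 1) / sample_rate
    return amplitude * np.cos(2 * np.pi * carrier_hz * tau) * np.exp(
        -(tau**2) / (2 * envelope_sd_s**2)
    )


def generate(cfg: SynthConfig) -> tuple[Recording, SongAnnotation, pd.DataFrame]:
    """Generate a synthetic song recording with full ground truth.

    Returns the noisy recording, a ``synthetic_truth`` annotation (pulse
    times and classes, sine-train / pulse-train / bout intervals), and an
    event table with one row per pulse (class, carrier) and per 50 ms
    sine bin (true instantaneous frequency).
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.sample_rate))
    samples = np.zeros(n)
    trains = _layout(rng, cfg)

    pulse_rows = []
    sine_rows = []
    all_pulses: list[float] = []
    pulse_train_recs = []
    sine_intervals = []
    bout_start_by_id: dict[int, float] = {}

    for tr in trains:
        bout_start_by_id.setdefault(tr["bout"], tr["start_s"])

    for tr in trains:
        if tr["type"] == "pulse":
            member_idx = []
            for pt in tr["pulse_times"]:
                is_harm = rng.random() < cfg.pulse.harmonic_fraction
                carrier = (2.0 if is_harm else 1.0) * cfg.pulse.carrier_hz + rng.normal(
                    0, cfg.pulse.carrier_jitter_hz
                )
                wave = render_pulse(
                    cfg.sample_rate,
                    carrier,
                    cfg.pulse.envelope_sd_ms / 1000.0,
                    cfg.pulse.amplitude,
                )
                c = int(round(pt * cfg.sample_rate))
                half = len(wave) // 2
                lo, hi = c - half, c + half + 1
                s_lo, s_hi = max(lo, 0), min(hi, n)
                samples[s_lo:s_hi] += wave[s_lo - lo : s_hi - lo]
                member_idx.append(len(all_pulses))
                all_pulses.append(pt)
                pulse_rows.append(
                    {
                        "time_s": pt,
                        "class": "harmonic" if is_harm else "fundamental",
                        "carrier_hz": carrier,
                        "bout": tr["bout"],
                    }
                )
            pulse_train_recs.append(
                {"start_s": tr["pulse_times"][0], "stop_s": tr["pulse_times"][-1],
                 "pulse_indices": member_idx}
            )
        else:
            a, b = tr["start_s"], tr["stop_s"]
            i0, i1 = int(round(a * cfg.sample_rate)), int(round(b * cfg.sample_rate))
            tt = np.arange(i0, i1) / cfg.sample_rate
            bout_t0 = bout_start_by_id[tr["bout"]]
            freq = (
                cfg.sine.carrier_hz
                + cfg.sine.within_recording_drift_hz * (tt / cfg.duration_s)
                + cfg.sine.within_bout_ramp_hz_per_s * (tt - bout_t0)
            )
            phase = 2 * np.pi * np.cumsum(freq) / cfg.sample_rate
            env = np.ones(len(tt))
            n_taper = int(round(cfg.sine.taper_s * cfg.sample_rate))
            if n_taper > 0 and len(env) > 2 * n_taper:
                ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
                env[:n_taper] = ramp
                env[-n_taper:] = ramp[::-1]
            samples[i0:i1] += cfg.sine.amplitude * env * np.sin(phase)
            # true per-50-ms-bin instantaneous frequency
            n_bins = int((b - a) / 0.05)
            for k in range(max(n_bins, 1)):
                bt = a + (k + 0.5) * 0.05
                bi = int(round((bt - a) * cfg.sample_rate))
                bi = min(bi, len(freq) - 1)
                sine_rows.append(
                    {"bin_time_s": bt, "freq_hz": float(freq[bi]), "bout": tr["bout"],
                     "train_start_s": a}
                )
            sine_intervals.append((a, b))

    samples += rng.normal(0.0, cfg.noise_sd, n)
    rec = Recording(samples, cfg.sample_rate, channel_id="synthetic")

    typed = [(tr["type"], (tr["start_s"], tr["stop_s"])) for tr in trains]
    bouts = []
    for bid in sorted({tr["bout"] for tr in trains}):
        members = [tr for tr in trains if tr["bout"] == bid]
        bouts.append((members[0]["start_s"], members[-1]["stop_s"]))

    ann = SongAnnotation(
        pulses=np.array(all_pulses),
        sine_trains=sine_intervals,
        pulse_trains=pulse_train_recs,
        bouts=bouts,
        source="synthetic_truth",
    )
    events = pd.concat(
        [
            pd.DataFrame(pulse_rows).assign(kind="pulse"),
            pd.DataFrame(sine_rows).assign(kind="sine_bin"),
        ],
        ignore_index=True,
    )
    return rec, ann, events


def sample_times_for_rhythm(cfg: SynthConfig | None = None, seed: int = 0) -> np.ndarray:
    """Uneven, bout-structured IPI sampling times (first pulse of each pair).

    Uses only the structural layout (no waveform rendering).  With the
    default :func:`rhythm_sampling_config` this yields on the order of
    600 sampling times over a 14-minute session, with the characteristic
    bimodal gap structure (~35 ms within trains, seconds between).
    """
    if cfg is None:
        cfg = rhythm_sampling_config(seed=seed)
    rng = np.random.default_rng(cfg.seed)
    trains = _layout(rng, cfg)
    times: list[float] = []
    for tr in trains:
        if tr["type"] == "pulse":
            times.extend(tr["pulse_times"][:-1])
    return np.array(times)
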