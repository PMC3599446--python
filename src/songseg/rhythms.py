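"""Lomb-Scargle rhythm analysis for unevenly sampled song-parameter series.

The inter-pulse interval is sampled unevenly in time (only within pulse
trains), so periodicity is assessed with the classical normalized
Lomb-Scargle periodogram.  Under a Gaussian-noise null each power value
is approximately Exp(1)-distributed; a local peak of power z receives a
false-alarm probability ``p = 1 - (1 - exp(-z))^M`` where M is the
effective number of independent frequencies (Horne-Baliunas style,
default: the number of samples; exact for independent Fourier
frequencies of an evenly sampled series).

``simulate_ipi_rhythm`` and ``estimate_power`` reproduce the injected-
rhythm power analysis: a sinusoidal IPI modulation (default 0.0182 Hz,
the classically reported ~55 s courtship-song rhythm) is added to
Gaussian noise on realistic bout-structured sampling times, and power is
the fraction of replicates with a significant local peak in the target
band (default 0.016-0.022 Hz).

SNR convention: ``snr = (A^2 / 2) / sigma^2`` — injected signal variance
over noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal

__all__ = [
    "Periodogram",
    "RhythmSimConfig",
    "PowerResult",
    "lomb_scargle",
    "peak_pvalues",
    "band_has_significant_peak",
    "simulate_ipi_rhythm",
    "estimate_power",
]

RELEVANT_BAND_HZ = (0.016, 0.022)


@dataclass
class Periodogram:
    """Normalized Lomb-Scargle power over a frequency grid."""

    freqs_hz: np.ndarray
    power: np.ndarray
    n_samples: int

    @property
    def n_independent_freqs(self) -> int:
        """Default Horne-Baliunas-style estimate of independent frequencies."""
        return self.n_samples


@dataclass
class RhythmSimConfig:
    """Injected-rhythm simulation settings.

    ``snr`` fixes the sinusoid amplitude given ``noise_sd``:
    ``A = sqrt(2 * snr) * noise_sd``; set ``amplitude_ms`` to override
    (e.g. a noiseless sinusoid with ``noise_sd = 0``).
    """

    sample_times_s: np.ndarray
    f_rhythm_hz: float = 0.0182
    snr: float = 1.0
    noise_sd: float = 3.0  # ms, typical within-individual IPI spread
    baseline: float = 35.0  # ms, mean IPI
    amplitude_ms: float | None = None
    seed: int = 0

    @property
    def amplitude(self) -> float:
        if self.amplitude_ms is not None:
            return float(self.amplitude_ms)
        return float(np.sqrt(2.0 * self.snr) * self.noise_sd)


@dataclass
class PowerResult:
    """Fraction of simulated series with a significant band peak."""

    snr: float
    power: float
    n_replicates: int
    band_hz: tuple[float, float]
    n_samples: int


def _ls_power(t: np.ndarray, yc: np.ndarray, freqs_hz: np.ndarray) -> np.ndarray:
    """Unnormalized classical (tau-shifted) Lomb-Scargle power.

    Uses the identity that the tau-corrected sums all derive from the two
    phasor sums ``Sy = sum y e^{i w t}`` and ``S2 = sum e^{2 i w t}``:
    with ``theta = arg(S2)`` (= 2 w tau),

        sum cos^2 w(t - tau) = (n + |S2|) / 2
        sum sin^2 w(t - tau) = (n - |S2|) / 2
        sum y cos w(t - tau) + i sum y sin w(t - tau) = Sy e^{-i theta / 2}

    The phasors are swept along the uniform frequency grid by a complex
    recurrence (one vector multiply per grid point), which is orders of
    magnitude faster than independent trig sums and agrees with the
    direct evaluation to ~1e-11 relative.
    """
    w0 = 2 * np.pi * freqs_hz[0]
    dw = 2 * np.pi * (freqs_hz[1] - freqs_hz[0] if len(freqs_hz) > 1 else 0.0)
    e = np.exp(1j * w0 * t)
    rot = np.exp(1j * dw * t)
    n, nf = len(t), len(freqs_hz)
    sy = np.empty(nf, dtype=complex)
    s2 = np.empty(nf, dtype=complex)
    for k in range(nf):
        sy[k] = np.dot(yc, e)
        s2[k] = np.dot(e, e)
        e *= rot
    syc = sy * np.exp(-0.5j * np.angle(s2))
    c2 = (n + np.abs(s2)) / 2.0
    sq = (n - np.abs(s2)) / 2.0
    return 0.5 * (
        syc.real**2 / np.maximum(c2, 1e-300) + syc.imag**2 / np.maximum(sq, 1e-300)
    )


def lomb_scargle(
    times_s: np.ndarray,
    values: np.ndarray,
    f_max_hz: float = 1.0,
    oversample: int = 4,
) -> Periodogram:
    """Classical normalized Lomb-Scargle periodogram.

    Values are mean-centered and power is normalized by the sample
    variance, so noise-only power is approximately Exp(1).  The grid runs
    from 1/T to ``f_max_hz`` with spacing 1/(oversample*T).
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly ascending")
    if np.ptp(y) == 0:
        raise ValueError("constant series has no periodogram")
    span = t[-1] - t[0]
    df = 1.0 / (oversample * span)
    freqs = np.arange(1.0 / span, f_max_hz * (1 + 1e-9), df)
    yc = y - y.mean()
    var = yc.var(ddof=1)
    power = _ls_power(t, yc, freqs) / var
    return Periodogram(freqs_hz=freqs, power=power, n_samples=len(t))


def _false_alarm_p(z: np.ndarray, m: int) -> np.ndarray:
    """p = 1 - (1 - e^-z)^M, computed stably for large z."""
    z = np.asarray(z, dtype=float)
    # log(1 - e^-z) is accurate via log1p; for tiny p use expm1
    with np.errstate(over="ignore"):
        log_one_minus = np.log1p(-np.exp(-z))
    p = -np.expm1(m * log_one_minus)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def peak_pvalues(
    pg: Periodogram, m: int | None = None
) -> list[tuple[float, float, float]]:
    """Local maxima of the periodogram with false-alarm probabilities.

    ``m`` is the number of independent frequencies used in the
    Horne-Baliunas correction (default: the number of samples; use m=1
    for a single pre-specified frequency).
    """
    if m is None:
        m = pg.n_independent_freqs
    idx, _ = signal.find_peaks(pg.power)
    ps = _false_alarm_p(pg.power[idx], m)
    return [
        (float(pg.freqs_hz[i]), float(pg.power[i]), float(p))
        for i, p in zip(idx, ps)
    ]


def band_has_significant_peak(
    pg: Periodogram,
    band_hz: tuple[float, float] = RELEVANT_BAND_HZ,
    alpha: float = 0.05,
    m: int | None = None,
) -> bool:
    """True if any local periodogram peak in ``band_hz`` has p < alpha."""
    return any(
        band_hz[0] <= f <= band_hz[1] and p < alpha
        for f, _, p in peak_pvalues(pg, m=m)
    )


def simulate_ipi_rhythm(cfg: RhythmSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a sinusoidally modulated series on the given sampling times.

    values = baseline + A sin(2 pi f t + phi) + N(0, sigma^2), with phi
    uniform under the seed and A set by the SNR convention above.
    """
    t = np.asarray(cfg.sample_times_s, dtype=float)
    if t.size == 0:
        raise ValueError("empty sampling times")
    rng = np.random.default_rng(cfg.seed)
    phi = rng.uniform(0, 2 * np.pi)
    values = (
        cfg.baseline
        + cfg.amplitude * np.sin(2 * np.pi * cfg.f_rhythm_hz * t + phi)
        + rng.normal(0.0, cfg.noise_sd, size=t.shape)
    )
    return t, values


def estimate_power(
    snr_grid,
    n_replicates: int,
    sample_times_s: np.ndarray | Callable[[int], np.ndarray],
    band_hz: tuple[float, float] = RELEVANT_BAND_HZ,
    f_rhythm_hz: float = 0.0182,
    noise_sd: float = 3.0,
    baseline: float = 35.0,
    alpha: float = 0.05,
    f_max_hz: float = 1.0,
    oversample: int = 4,
    seed: int = 0,
) -> list[PowerResult]:
    """Detection power over an SNR grid via seeded Monte-Carlo replicates.

    ``sample_times_s`` is either a fixed time vector or a callable mapping
    a replicate seed to a time vector (to resample the bout structure per
    replicate).  Power is the fraction of replicates whose periodogram has
    a local peak with false-alarm p < alpha inside ``band_hz``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    ss = np.random.SeedSequence(seed)
    results = []
    for snr in snr_grid:
        child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_replicates)]
        hits = 0
        n_used = 0
        for rep_seed in child_seeds:
            times = (
                sample_times_s(rep_seed)
                if callable(sample_times_s)
                else sample_times_s
            )
            cfg = RhythmSimConfig(
                sample_times_s=times,
                f_rhythm_hz=f_rhythm_hz,
                snr=snr,
                noise_sd=noise_sd,
                baseline=baseline,
                seed=rep_seed,
            )
            t, v = simulate_ipi_rhythm(cfg)
            pg = lomb_scargle(t, v, f_max_hz=f_max_hz, oversample=oversample)
            if band_has_significant_peak(pg, band_hz=band_hz, alpha=alpha):
                hits += 1
            n_used = len(t)
        results.append(
            PowerResult(
                snr=float(snr),
                power=hits / n_replicates,
                n_replicates=n_replicates,
                band_hz=band_hz,
                n_samples=n_used,
            )
        )
    return results
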