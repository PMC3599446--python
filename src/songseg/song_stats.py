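"""Per-individual song statistics.

Covers the descriptive statistics computed per recording: the
two-component Gaussian mixture of inter-pulse intervals (the lower
component's mean is the headline IPI statistic), the sine / pulse /
no-song three-way time proportions, within-bout scaled carrier-frequency
trends, within-recording correlations of song parameters against time,
and iterative Grubbs outlier removal used before across-individual
analysis.  Strain-level ANOVA/ANCOVA is out of scope: this module emits
the per-individual table such tests consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from songseg.audio_io import SongAnnotation

__all__ = [
    "GmmFit",
    "BoutTrendProfile",
    "fit_ipi_gmm",
    "song_proportions",
    "bout_trend",
    "recording_trends",
    "trend_ttest",
    "grubbs_outliers",
]


@dataclass
class GmmFit:
    """Two-component Gaussian mixture of IPIs (ms), components sorted by mean."""

    weights: np.ndarray
    means_ms: np.ndarray
    sds_ms: np.ndarray
    log_likelihood: float
    degenerate: bool = False

    @property
    def lower_mean_ms(self) -> float:
        return float(self.means_ms[0])


@dataclass
class BoutTrendProfile:
    """Scaled within-bout carrier-frequency profile aggregated across bouts.

    Per-bout frequencies have the bout's initial-bin value subtracted, so
    the first bin's mean is exactly zero by construction.
    """

    bin_offsets_s: np.ndarray
    mean_hz: np.ndarray
    sd_hz: np.ndarray
    counts: np.ndarray


def fit_ipi_gmm(
    ipis_ms: np.ndarray,
    n_init: int = 10,
    seed: int = 0,
    min_n: int = 50,
) -> GmmFit:
    """Fit a two-component Gaussian mixture to IPIs (in ms) by EM.

    Best of ``n_init`` k-means-seeded restarts under a fixed seed.
    Degenerate samples (zero spread) return a flagged single-point fit.
    """
    x = np.asarray(ipis_ms, dtype=float).reshape(-1, 1)
    if len(x) < min_n:
        raise ValueError(f"need >= {min_n} IPIs to fit the mixture, got {len(x)}")
    if np.ptp(x) == 0:
        v = float(x[0, 0])
        return GmmFit(
            weights=np.array([0.5, 0.5]),
            means_ms=np.array([v, v]),
            sds_ms=np.zeros(2),
            log_likelihood=np.inf,
            degenerate=True,
        )
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        random_state=seed,
        reg_covar=1e-6,
    ).fit(x)
    order = np.argsort(gm.means_.ravel())
    return GmmFit(
        weights=gm.weights_[order],
        means_ms=gm.means_.ravel()[order],
        sds_ms=np.sqrt(gm.covariances_.ravel()[order]),
        log_likelihood=float(gm.score(x) * len(x)),
    )


def _total(intervals) -> float:
    return float(sum(b - a for a, b in intervals))


def song_proportions(
    ann: SongAnnotation, duration_s: float, pulse_margin_s: float = 0.010
) -> tuple[float, float, float]:
    """Fractions of recording time in sine song, pulse song, and neither.

    Pulse-train time runs from the first to the last pulse of each train
    plus a half-window margin on each side.  The three fractions sum to 1.
    """
    sine_t = _total(ann.sine_trains)
    pulse_t = sum(
        (tr["stop_s"] - tr["start_s"]) + 2 * pulse_margin_s for tr in ann.pulse_trains
    )
    total = sine_t + pulse_t
    if total > duration_s:
        raise ValueError("song time exceeds recording duration")
    frac_sine = sine_t / duration_s
    frac_pulse = pulse_t / duration_s
    return frac_sine, frac_pulse, 1.0 - frac_sine - frac_pulse


def bout_trend(
    bout_tracks: list[list[tuple[float, float]]], bin_s: float = 0.05
) -> BoutTrendProfile:
    """Aggregate scaled within-bout carrier-frequency trends across bouts.

    ``bout_tracks`` holds, per bout, (time, frequency) pairs for one train
    type (sine bins or per-pulse carriers), with times in recording
    coordinates.  Within each bout, time is re-referenced to the first
    observation and the mean frequency of the bout's initial ``bin_s``
    bin is subtracted, so the aggregated first-bin mean is exactly zero.
    """
    binned: dict[int, list[float]] = {}
    for track in bout_tracks:
        if not track:
            continue
        t0 = track[0][0]
        bins = [int((t - t0) / bin_s + 1e-9) for t, _ in track]
        baseline = np.mean([f for b, (_, f) in zip(bins, track) if b == 0])
        for b, (_, f) in zip(bins, track):
            binned.setdefault(b, []).append(f - baseline)
    if not binned:
        raise ValueError("no bout tracks supplied")
    bins = np.array(sorted(binned))
    mean = np.array([np.mean(binned[b]) for b in bins])
    sd = np.array([np.std(binned[b]) for b in bins])
    counts = np.array([len(binned[b]) for b in bins])
    return BoutTrendProfile(
        bin_offsets_s=bins * bin_s, mean_hz=mean, sd_hz=sd, counts=counts
    )


def recording_trends(
    series: dict[str, tuple[np.ndarray, np.ndarray]], min_events: int = 10
) -> dict[str, float]:
    """Pearson correlation of each song parameter against event time.

    ``series`` maps parameter name -> (event times, values) within one
    recording.  Constant or too-short series yield NaN (flagged).
    """
    out: dict[str, float] = {}
    for name, (t, v) in series.items():
        t = np.asarray(t, float)
        v = np.asarray(v, float)
        if len(v) < min_events or np.ptp(v) == 0 or np.ptp(t) == 0:
            out[name] = np.nan
            continue
        out[name] = float(stats.pearsonr(t, v)[0])
    return out


def trend_ttest(correlations: np.ndarray) -> tuple[float, float]:
    """One-sample t-test of per-individual correlations against zero."""
    r = np.asarray(correlations, float)
    r = r[np.isfinite(r)]
    t, p = stats.ttest_1samp(r, 0.0)
    return float(t), float(p)


def grubbs_outliers(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative two-sided Grubbs test; returns (kept, removed) values.

    At each step the most extreme value is removed if its Grubbs statistic
    exceeds the critical value at ``alpha``; iteration stops when nothing
    more is significant or fewer than 3 values remain.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    kept = list(x)
    removed: list[float] = []
    while len(kept) >= 3:
        arr = np.array(kept)
        sd = arr.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(arr - arr.mean())
        i = int(np.argmax(dev))
        n = len(arr)
        g = dev[i] / sd
        t_crit = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = ((n - 1) / np.sqrt(n)) * np.sqrt(
            t_crit**2 / (n - 2 + t_crit**2)
        )
        if g > g_crit:
            removed.append(kept.pop(i))
        else:
            break
    return np.array(kept), np.array(removed)
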