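"""Audio and annotation I/O plus the shared recording data model.

Recordings are mono float arrays with a sample rate; integer PCM WAV data
is rescaled to [-1, 1) on read so amplitude thresholds are independent of
bit depth.  Annotations (pulse times, sine-train / pulse-train / bout
intervals) round-trip through a directory of CSV tables plus a JSON
metadata sidecar.  All times are seconds; all intervals half-open
[start, stop).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "Recording",
    "SongAnnotation",
    "read_recording",
    "write_recording",
    "write_annotation",
    "read_annotation",
]

#: formatting precision for times written to CSV (well below 1 us)
_TIME_FMT = "%.9f"


@dataclass
class Recording:
    """One channel of audio: float samples at a fixed sample rate."""

    samples: np.ndarray
    sample_rate: int
    channel_id: str = "0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Recording samples must be 1-D (one channel)")
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("Recording samples contain NaN or Inf")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def time_axis(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def _as_intervals(intervals) -> list[tuple[float, float]]:
    out = [(float(a), float(b)) for a, b in intervals]
    for a, b in out:
        if not b > a:
            raise ValueError(f"interval [{a}, {b}) has non-positive length")
    for (_, b0), (a1, _) in zip(out, out[1:]):
        if a1 < b0:
            raise ValueError("intervals overlap or are not sorted ascending")
    return out


@dataclass
class SongAnnotation:
    """Detected or ground-truth song events for one recording.

    ``pulse_trains`` maps each train interval to the indices of its member
    pulses in ``pulses``; every pulse train must contain at least two
    pulses.  ``bouts`` are merged train groups separated by >= 0.5 s.
    """

    pulses: np.ndarray = field(default_factory=lambda: np.empty(0))
    sine_trains: list[tuple[float, float]] = field(default_factory=list)
    pulse_trains: list[dict] = field(default_factory=list)
    bouts: list[tuple[float, float]] = field(default_factory=list)
    source: str = "automated"

    def __post_init__(self) -> None:
        self.pulses = np.asarray(self.pulses, dtype=np.float64)
        if self.pulses.size and np.any(np.diff(self.pulses) < 0):
            raise ValueError("pulse times must be ascending")
        if self.pulses.size and self.pulses[0] < 0:
            raise ValueError("pulse times must be non-negative")
        self.sine_trains = _as_intervals(self.sine_trains)
        self.bouts = _as_intervals(self.bouts)
        for tr in self.pulse_trains:
            if len(tr["pulse_indices"]) < 2:
                raise ValueError("pulse trains must contain at least two pulses")
        if self.source not in ("automated", "manual", "synthetic_truth"):
            raise ValueError(f"unknown annotation source {self.source!r}")

    @property
    def n_pulses(self) -> int:
        return int(self.pulses.size)


def read_recording(path, channel: int = 0) -> Recording:
    """Read one channel of a WAV file as a float Recording.

    Integer PCM is scaled to [-1, 1); float WAV is taken as-is.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim == 1:
        n_channels = 1
        col = data
        if channel != 0:
            raise IndexError(f"channel {channel} out of range for mono file")
    else:
        n_channels = data.shape[1]
        if not 0 <= channel < n_channels:
            raise IndexError(f"channel {channel} out of range (file has {n_channels})")
        col = data[:, channel]
    if np.issubdtype(col.dtype, np.integer):
        scale = float(2 ** (8 * col.dtype.itemsize - 1))
        samples = col.astype(np.float64) / scale
    elif np.issubdtype(col.dtype, np.floating):
        samples = col.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample encoding {col.dtype}")
    return Recording(samples, int(rate), channel_id=str(channel))


def write_recording(rec: Recording, path) -> None:
    """Write a Recording as mono float32 WAV."""
    wavfile.write(str(path), int(rec.sample_rate), rec.samples.astype(np.float32))


def write_annotation(ann: SongAnnotation, out_dir) -> Path:
    """Write an annotation as CSV tables + JSON sidecar under ``out_dir``.

    Files: pulses.csv, sine_trains.csv, trains.csv, bouts.csv, meta.json.
    Times are stored with nanosecond precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": ann.pulses}).to_csv(
        out_dir / "pulses.csv", index=False, float_format=_TIME_FMT
    )
    pd.DataFrame(ann.sine_trains, columns=["start_s", "stop_s"]).to_csv(
        out_dir / "sine_trains.csv", index=False, float_format=_TIME_FMT
    )
    pd.DataFrame(
        [
            {
                "start_s": tr["start_s"],
                "stop_s": tr["stop_s"],
                "pulse_indices": ";".join(str(i) for i in tr["pulse_indices"]),
            }
            for tr in ann.pulse_trains
        ],
        columns=["start_s", "stop_s", "pulse_indices"],
    ).to_csv(out_dir / "trains.csv", index=False, float_format=_TIME_FMT)
    pd.DataFrame(ann.bouts, columns=["start_s", "stop_s"]).to_csv(
        out_dir / "bouts.csv", index=False, float_format=_TIME_FMT
    )
    (out_dir / "meta.json").write_text(
        json.dumps({"source": ann.source, "n_pulses": ann.n_pulses}, indent=2)
    )
    return out_dir


def read_annotation(in_dir) -> SongAnnotation:
    """Read an annotation directory written by :func:`write_annotation`."""
    in_dir = Path(in_dir)
    meta_path = in_dir / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not an annotation directory (no meta.json): {in_dir}")
    meta = json.loads(meta_path.read_text())
    pulses = pd.read_csv(in_dir / "pulses.csv")["time_s"].to_numpy()
    sines = [
        (row.start_s, row.stop_s)
        for row in pd.read_csv(in_dir / "sine_trains.csv").itertuples()
    ]
    trains_df = pd.read_csv(in_dir / "trains.csv")
    trains = []
    for row in trains_df.itertuples():
        idx = [int(i) for i in str(row.pulse_indices).split(";") if i != ""]
        trains.append({"start_s": row.start_s, "stop_s": row.stop_s, "pulse_indices": idx})
    bouts = [
        (row.start_s, row.stop_s) for row in pd.read_csv(in_dir / "bouts.csv").itertuples()
    ]
    return SongAnnotation(
        pulses=pulses,
        sine_trains=sines,
        pulse_trains=trains,
        bouts=bouts,
        source=meta["source"],
    )
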