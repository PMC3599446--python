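"""Assembly of pulses and sine trains into trains, bouts, and pauses.

Pulse trains are maximal runs of pulses with successive gaps below a
break threshold (default 0.25 s) and must contain at least two pulses.
Bouts merge pulse and sine trains separated by less than 0.5 s of
silence; gaps of at least 0.5 s between bouts are pauses.  Inter-pulse
intervals (IPIs) are taken only within trains, timestamped at the first
pulse of each pair, which makes the IPI series unevenly sampled in time
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PulseTrain",
    "Bout",
    "IPISeries",
    "build_pulse_trains",
    "build_bouts",
    "extract_ipi_series",
]


@dataclass
class PulseTrain:
    start_s: float
    stop_s: float
    pulse_times: np.ndarray
    pulse_indices: list[int]

    def __post_init__(self):
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        if len(self.pulse_times) < 2:
            raise ValueError("a pulse train must contain at least two pulses")

    @property
    def ipis_s(self) -> np.ndarray:
        return np.diff(self.pulse_times)

    @property
    def length_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class Bout:
    """A continuous period of song: trains separated by < 0.5 s gaps."""

    start_s: float
    stop_s: float
    trains: list[tuple[str, tuple[float, float]]] = field(default_factory=list)

    @property
    def length_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class IPISeries:
    """Unevenly time-stamped inter-pulse intervals (within trains only)."""

    times_s: np.ndarray
    ipis_s: np.ndarray

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.ipis_s = np.asarray(self.ipis_s, dtype=float)
        if len(self.times_s) != len(self.ipis_s):
            raise ValueError("times and IPIs must have equal length")
        if len(self.times_s) > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("IPI timestamps must be strictly ascending")


def build_pulse_trains(
    pulse_times: np.ndarray, break_s: float = 0.25
) -> list[PulseTrain]:
    """Group sorted pulse times into maximal runs with gaps <= break_s.

    Runs of a single pulse are discarded (a train needs >= 2 pulses).
    """
    if break_s <= 0:
        raise ValueError("break_s must be positive")
    t = np.asarray(pulse_times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise ValueError("pulse times must be sorted")
    trains: list[PulseTrain] = []
    start = 0
    for i in range(len(t)):
        if i == len(t) - 1 or t[i + 1] - t[i] > break_s:
            if i + 1 - start >= 2:
                trains.append(
                    PulseTrain(
                        start_s=float(t[start]),
                        stop_s=float(t[i]),
                        pulse_times=t[start : i + 1],
                        pulse_indices=list(range(start, i + 1)),
                    )
                )
            start = i + 1
    return trains


def build_bouts(
    trains: list[tuple[str, tuple[float, float]]], gap_s: float = 0.5
) -> tuple[list[Bout], list[float]]:
    """Merge typed train intervals into bouts; return (bouts, pause durations).

    ``trains`` holds ("pulse"|"sine", (start, stop)) items.  Consecutive
    trains separated by a gap < ``gap_s`` belong to the same bout; gaps
    between consecutive bouts are the reported pauses.
    """
    items = sorted(trains, key=lambda x: x[1][0])
    for (_, (a0, b0)), (_, (a1, _)) in zip(items, items[1:]):
        if a1 < b0:
            raise ValueError("train intervals overlap")
    bouts: list[Bout] = []
    for typ, (a, b) in items:
        if bouts and a - bouts[-1].stop_s < gap_s:
            bouts[-1].stop_s = b
            bouts[-1].trains.append((typ, (a, b)))
        else:
            bouts.append(Bout(start_s=a, stop_s=b, trains=[(typ, (a, b))]))
    pauses = [
        later.start_s - earlier.stop_s for earlier, later in zip(bouts, bouts[1:])
    ]
    return bouts, pauses


def extract_ipi_series(trains: list[PulseTrain]) -> IPISeries:
    """Concatenate within-train IPIs; no interval ever spans a train gap."""
    times: list[float] = []
    ipis: list[float] = []
    for tr in trains:
        times.extend(tr.pulse_times[:-1])
        ipis.extend(np.diff(tr.pulse_times))
    return IPISeries(times_s=np.array(times), ipis_s=np.array(ipis))
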