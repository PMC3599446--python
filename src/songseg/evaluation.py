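"""Scoring of automated segmentation against ground truth.

Pulses are matched one-to-one to reference pulses by greedy nearest-
neighbor pairing within a tolerance (default 10 ms, safely below the
~35 ms inter-pulse interval).  From the matching:

    sensitivity = matched / n_true
    PPV         = matched / n_detected
    F           = 2 * sensitivity * PPV / (sensitivity + PPV)

with F = 1 meaning perfect classification.  Sine trains are compared by
per-recording count, mean length, and total sine time (plus interval-
intersection overlap), with paired two-tailed t-tests across recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["EvalResult", "match_pulses", "score", "evaluate_pulses",
           "sine_summary", "compare_sine", "interval_overlap_s"]


@dataclass
class EvalResult:
    n_true: int
    n_detected: int
    n_matched: int
    sensitivity: float
    ppv: float
    f_score: float


def match_pulses(
    true_times: np.ndarray, det_times: np.ndarray, tol_s: float = 0.010
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching within ``tol_s`` (provably optimal).

    Each true pulse may match any detection within +-``tol_s``, so the
    compatibility graph is convex bipartite (every true pulse's candidate
    detections form a contiguous run).  Scanning true pulses in time order
    and pairing each with the earliest unmatched detection in its window
    (Glover's rule) therefore achieves maximum-cardinality matching —
    identical in count to optimal bipartite assignment.
    """
    t = np.asarray(true_times, dtype=float)
    d = np.asarray(det_times, dtype=float)
    if tol_s <= 0:
        raise ValueError("tol_s must be positive")
    matching: list[tuple[int, int]] = []
    j = 0
    for i, ti in enumerate(t):
        while j < len(d) and d[j] < ti - tol_s:
            j += 1
        if j < len(d) and d[j] <= ti + tol_s:
            matching.append((i, j))
            j += 1
    return matching


def score(n_matched: int, n_true: int, n_det: int) -> EvalResult:
    """Sensitivity, positive predictive value, and their harmonic mean F."""
    if n_matched > min(n_true, n_det):
        raise ValueError("matched count exceeds event counts")
    sens = n_matched / n_true if n_true else np.nan
    ppv = n_matched / n_det if n_det else np.nan
    if np.isnan(sens) or np.isnan(ppv):
        f = np.nan
    elif sens + ppv == 0:
        f = 0.0
    else:
        f = 2 * sens * ppv / (sens + ppv)
    return EvalResult(
        n_true=n_true,
        n_detected=n_det,
        n_matched=n_matched,
        sensitivity=sens,
        ppv=ppv,
        f_score=f,
    )


def evaluate_pulses(
    true_times: np.ndarray, det_times: np.ndarray, tol_s: float = 0.010
) -> EvalResult:
    """Match and score detected pulse times against ground truth."""
    matching = match_pulses(true_times, det_times, tol_s)
    return score(len(matching), len(np.atleast_1d(true_times)),
                 len(np.atleast_1d(det_times)))


def interval_overlap_s(a: list[tuple[float, float]], b: list[tuple[float, float]]) -> float:
    """Total intersection time of two sets of non-overlapping intervals."""
    total = 0.0
    for a0, a1 in a:
        for b0, b1 in b:
            total += max(0.0, min(a1, b1) - max(a0, b0))
    return total


def sine_summary(trains: list[tuple[float, float]]) -> dict:
    lengths = [b - a for a, b in trains]
    return {
        "n_trains": len(trains),
        "mean_len_s": float(np.mean(lengths)) if lengths else 0.0,
        "total_s": float(np.sum(lengths)),
    }


def compare_sine(
    recordings: list[tuple[list[tuple[float, float]], list[tuple[float, float]]]],
) -> tuple[pd.DataFrame, dict]:
    """Compare sine-train statistics between truth and detection.

    ``recordings`` holds (true_trains, detected_trains) per recording.
    Returns a per-recording table and, when >= 2 recordings are supplied,
    paired two-tailed t-tests across recordings on mean train length,
    train count, and total sine time.
    """
    rows = []
    for true_trains, det_trains in recordings:
        st, sd = sine_summary(true_trains), sine_summary(det_trains)
        rows.append(
            {
                "n_trains_true": st["n_trains"],
                "n_trains_det": sd["n_trains"],
                "mean_len_true_s": st["mean_len_s"],
                "mean_len_det_s": sd["mean_len_s"],
                "total_sine_true_s": st["total_s"],
                "total_sine_det_s": sd["total_s"],
                "overlap_s": interval_overlap_s(true_trains, det_trains),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 2:
        return table, {}
    tests = {}
    for name, a, b in [
        ("mean_len", "mean_len_det_s", "mean_len_true_s"),
        ("n_trains", "n_trains_det", "n_trains_true"),
        ("total_sine", "total_sine_det_s", "total_sine_true_s"),
    ]:
        diffs = table[a].to_numpy() - table[b].to_numpy()
        if np.allclose(diffs, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(table[a], table[b])
        tests[name] = {"t": float(t), "p": float(p)}
    return table, tests
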