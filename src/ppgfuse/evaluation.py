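"""Scoring detected beats against a reference annotation.

Detections and reference beats are matched one-to-one within a tolerance;
matched pairs are true positives (TP), unmatched detections false positives
(FP), unmatched references false negatives (FN).  From the counts:

    Se  = 100 * TP / (TP + FN)      sensitivity
    +P  = 100 * TP / (TP + FP)      positive predictivity
    FDR = 100 * FP / TP             failed detection rate

(FDR here is the beat-detection "failed detection rate", not the
multiple-testing false discovery rate.)  Undefined ratios — e.g. FDR with
zero TP — are reported as NaN, never silently as 0.  The first and last
``trim_s`` seconds of a record are excluded before matching, mirroring the
device warm-up discard used when the method was evaluated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "DetectionMetrics",
    "compute_metrics",
    "evaluate_detection",
    "match_peaks",
    "trim_window",
]


@dataclass(frozen=True)
class DetectionMetrics:
    """TP/FP/FN counts and the derived percentages (NaN where undefined)."""

    tp: int
    fp: int
    fn: int
    se_pct: float
    ppv_pct: float
    fdr_pct: float

    def to_dict(self) -> dict:
        def _clean(x: float) -> Optional[float]:
            return None if math.isnan(x) else x

        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "se_pct": _clean(self.se_pct),
            "ppv_pct": _clean(self.ppv_pct),
            "fdr_pct": _clean(self.fdr_pct),
        }


def trim_window(record_length: int, fs: float, trim_s: float) -> Tuple[int, int]:
    """Half-open scored sample window after head/tail trimming."""
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if trim_s < 0:
        raise ValueError(f"trim_s must be >= 0, got {trim_s}")
    margin = int(round(trim_s * fs))
    if record_length <= 2 * margin:
        raise ValueError(
            f"record of {record_length} samples is too short to trim {trim_s} s "
            f"({margin} samples) from each end"
        )
    return margin, record_length - margin


def match_peaks(detected, reference, tolerance: float) -> Tuple[int, int, int]:
    """Greedy one-to-one matching of two sorted index trains.

    Both trains are walked in order; a detection and a reference beat within
    ``tolerance`` samples (inclusive) of each other pair up, and each beat
    pairs at most once.  For sorted point trains with a common tolerance
    this in-order sweep attains the maximum possible number of pairs, so it
    agrees with an exhaustive optimal assignment.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be >= 0, got {tolerance}")
    det = np.asarray(detected, dtype=float).ravel()
    ref = np.asarray(reference, dtype=float).ravel()
    if det.size > 1 and np.any(np.diff(det) < 0):
        raise ValueError("detected indices must be sorted")
    if ref.size > 1 and np.any(np.diff(ref) < 0):
        raise ValueError("reference indices must be sorted")

    i = j = tp = 0
    while i < det.size and j < ref.size:
        if abs(det[i] - ref[j]) <= tolerance:
            tp += 1
            i += 1
            j += 1
        elif det[i] < ref[j] - tolerance:
            i += 1
        else:
            j += 1
    return tp, int(det.size - tp), int(ref.size - tp)


def compute_metrics(tp: int, fp: int, fn: int) -> DetectionMetrics:
    """Se / +P / FDR percentages from the match counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    se = 100.0 * tp / (tp + fn) if tp + fn > 0 else math.nan
    ppv = 100.0 * tp / (tp + fp) if tp + fp > 0 else math.nan
    fdr = 100.0 * fp / tp if tp > 0 else math.nan
    return DetectionMetrics(tp=int(tp), fp=int(fp), fn=int(fn), se_pct=se, ppv_pct=ppv, fdr_pct=fdr)


def evaluate_detection(
    detected,
    reference,
    record_length: int,
    fs: float,
    config,
    group_delay: int = 0,
    reference_offset: int = 0,
) -> DetectionMetrics:
    """Trim, align and score a detection train against reference beats.

    ``group_delay`` shifts detections back by the FIR delay before matching;
    ``reference_offset`` shifts the reference forward (useful when scoring
    against an ECG-style reference that systematically precedes the PPG
    pulse).  Both trains are restricted to the trimmed window, matched
    within ``config.match_tolerance_s`` and scored.
    """
    start, end = trim_window(record_length, fs, config.trim_s)
    det = np.asarray(detected, dtype=int) - int(group_delay)
    ref = np.asarray(reference, dtype=int) + int(reference_offset)
    det = det[(det >= start) & (det < end)]
    ref = ref[(ref >= start) & (ref < end)]
    tolerance = int(round(config.match_tolerance_s * fs))
    tp, fp, fn = match_peaks(det, ref, tolerance)
    return compute_metrics(tp, fp, fn)
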