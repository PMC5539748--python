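"""Channel fusion: plain averaging and detection-quality-weighted averaging.

Four PPG sensors see different vascular beds of the palm, so channel quality
differs between users and drifts with hand posture.  Two mixing rules turn
the four filtered channels S_i[n] into one waveform:

* average:   S_mix[n] = sum_i S_i[n] / 4
* weighted:  S_mix[n] = sum_i W_i[n] S_i[n] / sum_i W_i[n]

The weights follow each channel's recent detection quality.  An independent
slope/threshold detector runs on every channel; at each sample a channel
experiences one of four events:

* ``valid_peak``    — a candidate peak whose PPI passed the gate: W += alpha
* ``invalid_peak``  — a candidate rejected by the gate (noise): W -= alpha
* ``missed_window`` — more than ppi_high_factor x the channel's last
  accepted PPI elapsed since its last accepted peak with no candidate at
  all: W -= alpha (one event per elapsed window)
* ``none``          — otherwise: W unchanged

Weights are clamped to [weight_min, weight_max] (default [2, 20], step
alpha = 2) and start at weight_min, so the cold-start mix equals the plain
average.  The final pulse rate always comes from a fresh detector run on the
mixed waveform; the per-channel detectors only drive the weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .peak_detection import DetectorState, PeakTrain, compute_slope, detect_peaks
from .preprocessing import design_lowpass_fir, filter_channel

__all__ = [
    "MixedSignal",
    "WeightTrace",
    "detect_on_mixed",
    "mix_average",
    "mix_weighted",
    "run_weight_dynamics",
    "smooth_trace",
    "update_weight",
]

_EVENTS = ("valid_peak", "invalid_peak", "missed_window", "none")


@dataclass
class WeightTrace:
    """Per-channel, per-sample weight sequences W_i[n]."""

    weights: np.ndarray  # shape (n_channels, n_samples)
    alpha: float
    bounds: Tuple[float, float]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D (channels x samples)")
        lo, hi = self.bounds
        if self.weights.size and (self.weights.min() < lo or self.weights.max() > hi):
            raise ValueError(f"weights must lie within bounds [{lo}, {hi}]")


@dataclass
class MixedSignal:
    """A fused single-channel waveform and how it was produced."""

    values: np.ndarray
    method: str
    trace: Optional[WeightTrace] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _as_channel_matrix(channels) -> np.ndarray:
    arr = np.asarray(channels, dtype=float)
    if arr.ndim != 2:
        raise ValueError("channels must form a 2-D (channels x samples) array of equal lengths")
    return arr


def mix_average(channels) -> MixedSignal:
    """Per-sample mean of the channels."""
    arr = _as_channel_matrix(channels)
    return MixedSignal(values=arr.mean(axis=0), method="average")


def mix_weighted(channels, trace: WeightTrace) -> MixedSignal:
    """Per-sample normalized weighted mean of the channels."""
    arr = _as_channel_matrix(channels)
    if trace.weights.shape != arr.shape:
        raise ValueError(
            f"weight trace shape {trace.weights.shape} does not match channels {arr.shape}"
        )
    totals = trace.weights.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("total weight must be positive at every sample")
    values = (trace.weights * arr).sum(axis=0) / totals
    return MixedSignal(values=values, method="weighted", trace=trace)


def update_weight(prev_w: float, event: str, config) -> float:
    """One weight update step, clamped to [weight_min, weight_max]."""
    if event == "valid_peak":
        w = prev_w + config.alpha
    elif event in ("invalid_peak", "missed_window"):
        w = prev_w - config.alpha
    elif event == "none":
        return prev_w
    else:
        raise ValueError(f"unknown weight event {event!r}; expected one of {_EVENTS}")
    return float(min(max(w, config.weight_min), config.weight_max))


def run_weight_dynamics(channels, fs: float, config) -> WeightTrace:
    """Evolve per-channel weights from per-channel detection quality.

    An independent detector state machine runs on each (already filtered)
    channel.  Weights start at ``weight_min``, change only at event samples
    and are piecewise constant in between.  A ``missed_window`` event cannot
    fire before the channel's PPI gate has been seeded (two candidates
    accepted), because there is no expected interval to miss yet.
    """
    arr = _as_channel_matrix(channels)
    n_ch, n_samples = arr.shape
    slopes = [compute_slope(arr[i]) for i in range(n_ch)]

    n_calib = min(int(round(config.threshold_init_s * fs)), n_samples)
    detectors = []
    for i in range(n_ch):
        max_slope = float(slopes[i][:n_calib].max()) if n_calib > 0 else 0.0
        detectors.append(
            DetectorState(
                config=config,
                init_threshold=config.threshold_fraction * max_slope,
                fs=float(fs),
            )
        )

    w = np.full(n_ch, float(config.weight_min))
    weights = np.empty((n_ch, n_samples), dtype=float)
    # anchor for the missed-window clock: last accepted peak or last window expiry
    anchors: List[Optional[int]] = [None] * n_ch

    start = max(n_calib, 1)
    weights[:, :start] = w[:, None]
    for n in range(start, n_samples):
        for i in range(n_ch):
            det = detectors[i]
            event = "none"
            result = det.step(n, slopes[i][n])
            if result is not None:
                peak, accepted = result
                event = "valid_peak" if accepted else "invalid_peak"
                if accepted:
                    anchors[i] = peak
            elif det.last_accepted_ppi is not None and anchors[i] is not None:
                if n - anchors[i] > config.ppi_high_factor * det.last_accepted_ppi:
                    event = "missed_window"
                    anchors[i] = n
            if event != "none":
                w[i] = update_weight(w[i], event, config)
        weights[:, n] = w

    return WeightTrace(
        weights=weights,
        alpha=config.alpha,
        bounds=(config.weight_min, config.weight_max),
    )


def smooth_trace(trace: WeightTrace, fs: float, ramp_s: float) -> WeightTrace:
    """Causal moving-average smoothing of a weight trace for mixing.

    The event-driven weight schedule is piecewise constant, so every update
    puts a step into the weighted mix; a step's one-sample slope can dwarf a
    pulse upstroke and derail the slope detector downstream.  Ramping each
    change over ``ramp_s`` seconds (a causal boxcar average) removes the
    steps while preserving the weight bounds, since every smoothed value is
    a convex combination of in-bound values.  The raw trace remains the
    quantity of record; only the mix consumes the smoothed copy.
    """
    n = max(1, int(round(ramp_s * fs)))
    if n == 1 or trace.weights.shape[1] == 0:
        return trace
    padded = np.concatenate(
        [np.repeat(trace.weights[:, :1], n - 1, axis=1), trace.weights], axis=1
    )
    kernel = np.ones(n) / n
    smoothed = np.vstack([np.convolve(row, kernel, mode="valid") for row in padded])
    return WeightTrace(weights=smoothed, alpha=trace.alpha, bounds=trace.bounds)


def detect_on_mixed(record, method: str, config) -> Tuple[MixedSignal, PeakTrain, np.ndarray]:
    """Full pipeline: filter every channel, mix, detect peaks, compute PR.

    ``method`` is ``"average"``, ``"weighted"`` or ``"channel:<k>"`` with k
    a 1-based channel number (the single-sensor comparison baseline, which
    bypasses mixing entirely).  Returns the mixed signal, the peak train
    detected on it, and the pulse-rate series (bpm, one value per accepted
    PPI).
    """
    coeffs = design_lowpass_fir(config.filter_order, config.cutoff_hz, record.fs)
    filtered = np.vstack([filter_channel(ch, coeffs) for ch in record.samples])

    if method == "average":
        mixed = mix_average(filtered)
    elif method == "weighted":
        trace = run_weight_dynamics(filtered, record.fs, config)
        mixed = mix_weighted(filtered, smooth_trace(trace, record.fs, config.weight_ramp_s))
        mixed.trace = trace  # report the event-driven schedule, not the mixing ramp
    elif method.startswith("channel:"):
        try:
            k = int(method.split(":", 1)[1])
        except ValueError as exc:
            raise ValueError(f"bad channel method {method!r}; use e.g. 'channel:3'") from exc
        if not 1 <= k <= record.n_channels:
            raise ValueError(f"channel {k} out of range 1..{record.n_channels}")
        mixed = MixedSignal(values=filtered[k - 1].copy(), method=method)
    else:
        raise ValueError(
            f"unknown method {method!r}; expected 'average', 'weighted' or 'channel:<k>'"
        )

    peaks = detect_peaks(mixed.values, record.fs, config)
    return mixed, peaks, peaks.pulse_rates
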