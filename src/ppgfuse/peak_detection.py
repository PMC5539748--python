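"""Slope-based adaptive-threshold pulse peak detection.

The detector is a sample-by-sample state machine built for a small MCU loop:
the first backward difference of the filtered PPG serves as the slope; when
the slope exceeds a dynamic threshold Th the machine arms (Flag true) and
buffers subsequent slopes; the first sample where the slope drops to <= 0
marks a pulse peak candidate at the previous sample (the local maximum).
Th is then refreshed from the maximum buffered slope of that upstroke,
scaled by a configurable fraction, so the threshold tracks pulse-amplitude
changes beat by beat.  Because Th only refreshes at candidates, a single
steep artifact could otherwise park it above every subsequent pulse slope
and silence the detector; after ``th_decay_grace_s`` without a candidate,
Th therefore decays exponentially (half-life ``th_halflife_s``) until the
signal arms it again.

Every candidate passes a peak-to-peak-interval (PPI) plausibility gate: the
interval to the previous candidate must lie strictly within
(0.7, 1.3) x the last accepted PPI.  The first two candidates are accepted
unconditionally to seed the gate.  A rejected candidate still refreshes Th
(its upstroke was real signal energy) but never updates the accepted PPI.
After ``gate_reset_after`` consecutive rejections the gate concludes its
expected interval is stale (a posture change, a contact loss, or a gate
seeded on noise) and re-seeds from the next candidates; without this cold
restart a gate seeded on an artifact burst would reject every true beat for
the rest of the record.

Pulse rate follows from each accepted interval as PR = 60 * fs / PPI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "DetectorState",
    "PeakTrain",
    "check_ppi",
    "compute_slope",
    "detect_peaks",
    "pulse_rate",
]

# Threshold floor: keeps Th strictly positive after calibrating on a flat
# segment, without ever arming on numerical noise of a truly constant signal.
_TH_FLOOR = 1e-12


@dataclass
class PeakTrain:
    """Ordered detected peak candidates with PPI-gate acceptance status."""

    indices: np.ndarray
    accepted: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if self.indices.shape != self.accepted.shape:
            raise ValueError("indices and accepted must have equal length")
        if self.indices.size > 1 and np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def accepted_indices(self) -> np.ndarray:
        return self.indices[self.accepted]

    @property
    def ppis(self) -> np.ndarray:
        """Intervals between consecutive accepted peaks, in samples."""
        return np.diff(self.accepted_indices)

    @property
    def pulse_rates(self) -> np.ndarray:
        """Instantaneous pulse rate (bpm) for each accepted PPI."""
        ppis = self.ppis
        return 60.0 * self.fs / ppis if ppis.size else np.empty(0)


def compute_slope(values) -> np.ndarray:
    """First backward difference; slope[0] = 0 so output matches input length."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("compute_slope needs a 1-D sequence of length >= 2")
    return np.diff(values, prepend=values[0])


def check_ppi(prev_ppi: float, new_ppi: float, config) -> bool:
    """Plausibility gate: strictly prev*0.7 < new < prev*1.3 (factors from config)."""
    if prev_ppi <= 0 or new_ppi <= 0:
        raise ValueError("PPIs must be positive")
    return prev_ppi * config.ppi_low_factor < new_ppi < prev_ppi * config.ppi_high_factor


def pulse_rate(ppi: float, fs: float) -> float:
    """Pulse rate in bpm from a peak-to-peak interval in samples: 60*fs/PPI."""
    if ppi <= 0:
        raise ValueError(f"ppi must be positive, got {ppi}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    return 60.0 * fs / ppi


@dataclass
class DetectorState:
    """Mutable state of the slope/threshold state machine.

    ``step`` consumes one (index, slope) pair at a time and returns a
    ``(peak_index, accepted)`` tuple when an upstroke completes, else None.
    Keeping the machine incremental lets the weight dynamics of the fusion
    stage interleave four per-channel detectors sample by sample.
    """

    config: object
    init_threshold: float
    fs: float
    flag: bool = False
    th: float = field(init=False)
    slope_buffer: List[float] = field(default_factory=list)
    last_peak_index: Optional[int] = None
    last_accepted_index: Optional[int] = None
    last_accepted_ppi: Optional[int] = None
    consecutive_rejects: int = 0

    def __post_init__(self) -> None:
        self.th = max(float(self.init_threshold), _TH_FLOOR)
        self._idle = 0  # samples since the last candidate (or since start)
        self._grace = int(round(self.config.th_decay_grace_s * self.fs))
        self._decay = 0.5 ** (1.0 / (self.config.th_halflife_s * self.fs))

    def step(self, n: int, slope: float) -> Optional[Tuple[int, bool]]:
        if not self.flag:
            self._idle += 1
            if self._idle > self._grace:
                self.th = max(self.th * self._decay, _TH_FLOOR)
            if slope > self.th:  # strict: a slope equal to Th does not arm
                self.flag = True
                self.slope_buffer = [slope]
            return None
        if slope > 0.0:
            self.slope_buffer.append(slope)
            return None
        # slope <= 0 while armed: the previous sample was the local maximum
        peak = n - 1
        self.th = max(self.config.threshold_fraction * max(self.slope_buffer), _TH_FLOOR)
        self.slope_buffer = []
        self.flag = False
        self._idle = 0
        accepted = self._gate(peak)
        self.last_peak_index = peak
        if accepted:
            self.last_accepted_index = peak
        return peak, accepted

    def _gate(self, peak: int) -> bool:
        if self.last_peak_index is None:
            return True  # cold start: first candidate seeds the train
        new_ppi = peak - self.last_peak_index
        if new_ppi <= 0:
            return False
        if self.last_accepted_ppi is None:
            # second candidate establishes PPI[1] unconditionally
            self.last_accepted_ppi = new_ppi
            self.consecutive_rejects = 0
            return True
        if check_ppi(self.last_accepted_ppi, new_ppi, self.config):
            self.last_accepted_ppi = new_ppi
            self.consecutive_rejects = 0
            return True
        self.consecutive_rejects += 1
        if self.consecutive_rejects >= self.config.gate_reset_after:
            # stale expected interval: restart the cold-start seeding
            self.last_accepted_ppi = None
            self.consecutive_rejects = 0
        return False


def detect_peaks(values, fs: float, config) -> PeakTrain:
    """Run the slope/adaptive-threshold detector over a filtered signal.

    The initial threshold is calibrated as ``threshold_fraction`` times the
    maximum slope over the first ``threshold_init_s`` seconds; no peaks are
    emitted inside that calibration window.  A constant signal yields an
    empty train, not an error.  The result is a pure function of the input
    and config.
    """
    values = np.asarray(values, dtype=float)
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    slopes = compute_slope(values)
    n_calib = min(int(round(config.threshold_init_s * fs)), values.size)
    max_calib_slope = float(slopes[:n_calib].max()) if n_calib > 0 else 0.0
    det = DetectorState(
        config=config, init_threshold=config.threshold_fraction * max_calib_slope, fs=float(fs)
    )

    indices: List[int] = []
    accepted: List[bool] = []
    for n in range(max(n_calib, 1), values.size):
        result = det.step(n, slopes[n])
        if result is not None:
            indices.append(result[0])
            accepted.append(result[1])
    return PeakTrain(
        indices=np.asarray(indices, dtype=int),
        accepted=np.asarray(accepted, dtype=bool),
        fs=float(fs),
    )
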