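"""Low-pass FIR preprocessing of raw PPG channels.

Each raw channel passes through a linear-phase low-pass FIR filter (default:
40th order, 5 Hz cutoff at 200 Hz sampling) to remove high-frequency noise
before slope-based peak detection and channel mixing.  The filter is a
windowed-sinc design (Hamming window) normalized to unit DC gain; being a
symmetric type-I FIR it delays every in-band feature by exactly order/2
samples, which downstream scoring compensates for via
:func:`align_for_reference`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FilterCoefficients",
    "align_for_reference",
    "design_lowpass_fir",
    "filter_channel",
]


@dataclass(frozen=True)
class FilterCoefficients:
    """Taps of a linear-phase low-pass FIR filter."""

    taps: np.ndarray
    order: int
    cutoff_hz: float
    fs: float

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if taps.size != self.order + 1:
            raise ValueError(f"expected {self.order + 1} taps, got {taps.size}")
        if not np.allclose(taps, taps[::-1], atol=1e-12):
            raise ValueError("taps must be symmetric (linear phase)")
        if abs(taps.sum() - 1.0) > 1e-6:
            raise ValueError("taps must sum to 1 (unit DC gain)")

    @property
    def group_delay(self) -> int:
        """Constant delay of a symmetric FIR, in samples."""
        return self.order // 2

    def response(self, freqs_hz) -> np.ndarray:
        """Magnitude response |H(f)| at the given frequencies in Hz."""
        w = 2.0 * np.pi * np.atleast_1d(np.asarray(freqs_hz, dtype=float)) / self.fs
        _, h = signal.freqz(self.taps, worN=w)
        return np.abs(h)


def design_lowpass_fir(order: int, cutoff_hz: float, fs: float) -> FilterCoefficients:
    """Design a type-I (even order, symmetric) windowed-sinc low-pass FIR.

    Parameters
    ----------
    order : even filter order; the filter has ``order + 1`` taps.
    cutoff_hz : -6 dB cutoff frequency, strictly below Nyquist.
    fs : sampling rate in Hz.
    """
    if order < 2 or order % 2 != 0:
        raise ValueError(f"order must be an even integer >= 2, got {order}")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError(f"cutoff_hz must lie in (0, fs/2) = (0, {fs / 2}), got {cutoff_hz}")
    taps = signal.firwin(order + 1, cutoff_hz, window="hamming", fs=fs)
    taps = taps / taps.sum()  # firwin scales to unit DC gain; renormalize exactly
    return FilterCoefficients(taps=taps, order=order, cutoff_hz=cutoff_hz, fs=fs)


def filter_channel(values, coeffs: FilterCoefficients) -> np.ndarray:
    """Causal FIR filtering of one channel.

    The output has the same length as the input with a leading transient of
    ``order`` samples (zero initial state); detection ignores the transient
    because the scoring window drops the first seconds of every record
    anyway.  In-band features come out delayed by ``coeffs.group_delay``
    samples — the delay is documented and compensated at scoring time, not
    here.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("filter_channel expects a 1-D sequence")
    if values.size <= coeffs.order:
        raise ValueError(
            f"input length {values.size} must exceed filter order {coeffs.order}"
        )
    return signal.lfilter(coeffs.taps, [1.0], values)


def align_for_reference(peaks, group_delay: int):
    """Shift detected peak indices back by the filter group delay.

    Indices are clipped at 0; if clipping collapses two candidates onto the
    same sample, only the first is kept (with its acceptance status).
    """
    from .peak_detection import PeakTrain

    if group_delay < 0:
        raise ValueError(f"group_delay must be >= 0, got {group_delay}")
    shifted = np.maximum(peaks.indices - int(group_delay), 0)
    keep = np.ones(shifted.size, dtype=bool)
    if shifted.size > 1:
        keep[1:] = np.diff(shifted) > 0
    return PeakTrain(indices=shifted[keep], accepted=peaks.accepted[keep], fs=peaks.fs)
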