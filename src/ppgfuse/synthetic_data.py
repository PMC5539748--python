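"""Synthetic 4-channel palm-PPG recordings with known beat times.

No recordings from the original mouse hardware are publicly available, so
this module emulates them: 1-minute, 4-channel, 200 Hz records under six
usage conditions (rest; slow/rapid x horizontal/vertical cursor movement;
document browsing with clicks).  Each channel is a superposition of an
asymmetric pulse template at randomized beat times, scaled by a per-channel
amplitude (palm vasculature differs under each sensor), plus sinusoidal
baseline wander, white sensor noise, Poisson-arriving band-limited motion
artifact bursts, and — for the browsing condition — contact-loss dropouts
where the pulsatile component vanishes while the palm lifts off the sensor.

Beat times are the ground-truth reference: each annotation marks the pulse
*peak* sample of the noise-free template, the same fiducial the detector
reports, so no pulse-transit-time offset is needed at scoring time.

The condition presets differ only in degradation severity (artifact rate and
amplitude, noise level, dropout rate), ordered rest < slow < rapid, with
browsing adding dropouts.  These severities are this simulator's own
calibration — chosen to exercise the detector and fusion logic, not fitted
to any measured artifact statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal as _sig

from .io_config import MultiChannelRecord

__all__ = [
    "SCENARIO_NAMES",
    "ScenarioConfig",
    "clean_scenario",
    "contrast_scenario",
    "generate_beat_times",
    "generate_channel",
    "generate_record",
    "pulse_template",
    "scenario_preset",
]

PerChannel = Union[float, Sequence[float]]

SCENARIO_NAMES = (
    "rest",
    "slow_horizontal",
    "slow_vertical",
    "rapid_horizontal",
    "rapid_vertical",
    "browsing",
)

_MIN_IBI_S = 0.3  # physiological floor on the inter-beat interval (200 bpm)
_N_CHANNELS = 4
_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything that determines one simulated record (a pure function of this)."""

    name: str = "rest"
    duration_s: float = 60.0
    fs: float = 200.0
    hr_bpm: float = 89.0
    hr_sd_bpm: float = 2.5
    channel_amplitudes: Tuple[float, float, float, float] = (1.0, 0.8, 1.2, 0.6)
    noise_sd: PerChannel = 0.03
    wander_amp: float = 0.15
    wander_hz: float = 0.25
    artifact_rate_per_min: PerChannel = 0.0
    artifact_amp: PerChannel = 0.0
    artifact_dur_s: float = 0.8
    dropout_rate_per_min: PerChannel = 0.0
    dropout_dur_s: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 30.0 <= self.hr_bpm <= 220.0:
            raise ValueError(f"hr_bpm must lie in [30, 220], got {self.hr_bpm}")
        if self.hr_sd_bpm < 0:
            raise ValueError(f"hr_sd_bpm must be >= 0, got {self.hr_sd_bpm}")
        if len(self.channel_amplitudes) != _N_CHANNELS:
            raise ValueError("channel_amplitudes must have 4 entries")
        if min(self.channel_amplitudes) <= 0:
            raise ValueError("channel amplitudes must be positive")
        for name in ("noise_sd", "artifact_rate_per_min", "artifact_amp", "dropout_rate_per_min"):
            if np.any(_per_channel(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be nonnegative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _per_channel(value: PerChannel) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return np.full(_N_CHANNELS, float(arr[0]))
    if arr.size != _N_CHANNELS:
        raise ValueError(f"per-channel parameter needs 1 or {_N_CHANNELS} values, got {arr.size}")
    return arr


# ---------------------------------------------------------------------------
# condition presets
# ---------------------------------------------------------------------------

_PRESETS = {
    # rest: nearly clean palm contact; the 89 bpm default echoes a typical
    # young-adult resting pulse rate while seated at a desk.
    "rest": dict(noise_sd=0.03, artifact_rate_per_min=1.0, artifact_amp=0.6, artifact_dur_s=0.5),
    "slow_horizontal": dict(
        noise_sd=0.04, artifact_rate_per_min=6.0, artifact_amp=1.0, artifact_dur_s=0.8
    ),
    "slow_vertical": dict(
        noise_sd=0.04, artifact_rate_per_min=6.0, artifact_amp=1.2, artifact_dur_s=0.8
    ),
    "rapid_horizontal": dict(
        noise_sd=0.05, artifact_rate_per_min=18.0, artifact_amp=1.8, artifact_dur_s=1.0
    ),
    "rapid_vertical": dict(
        noise_sd=0.05, artifact_rate_per_min=18.0, artifact_amp=2.0, artifact_dur_s=1.0
    ),
    # browsing: moderate movement plus clicking at roughly one page flip per
    # 10 s, each click briefly lifting the palm off the sensors.
    "browsing": dict(
        noise_sd=0.04,
        artifact_rate_per_min=6.0,
        artifact_amp=1.2,
        artifact_dur_s=0.8,
        dropout_rate_per_min=6.0,
        dropout_dur_s=0.4,
    ),
}


def scenario_preset(name: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Build one of the six named condition presets (overrides allowed)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    params = dict(_PRESETS[name])
    params.update(overrides)
    return ScenarioConfig(name=name, seed=seed, **params)


def clean_scenario(
    hr_bpm: float = 60.0, seed: int = 0, duration_s: float = 60.0, hr_sd_bpm: float = 0.0
) -> ScenarioConfig:
    """A degradation-free record: pulses only, no noise/wander/artifacts."""
    return ScenarioConfig(
        name="clean",
        duration_s=duration_s,
        hr_bpm=hr_bpm,
        hr_sd_bpm=hr_sd_bpm,
        noise_sd=0.0,
        wander_amp=0.0,
        seed=seed,
    )


def contrast_scenario(seed: int = 0, clean_channel: int = 2, hr_bpm: float = 80.0) -> ScenarioConfig:
    """One clean channel, three heavily artifact-laden channels.

    The configuration that separates the weighted mix from the plain
    average: three sensors with poor palm contact carry strong motion bursts
    and noise while one keeps a clean pulse.
    """
    noise = np.full(_N_CHANNELS, 0.3)
    rate = np.full(_N_CHANNELS, 20.0)
    amp = np.full(_N_CHANNELS, 2.0)
    noise[clean_channel] = 0.02
    rate[clean_channel] = 0.0
    amp[clean_channel] = 0.0
    return ScenarioConfig(
        name="contrast",
        hr_bpm=hr_bpm,
        hr_sd_bpm=2.0,
        channel_amplitudes=(1.0, 1.0, 1.0, 1.0),
        noise_sd=tuple(noise),
        artifact_rate_per_min=tuple(rate),
        artifact_amp=tuple(amp),
        artifact_dur_s=0.8,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_beat_times(
    duration_s: float, hr_bpm: float, hr_sd_bpm: float, fs: float, seed: int
) -> np.ndarray:
    """Ground-truth beat sample indices with Gaussian inter-beat jitter.

    Successive inter-beat intervals are 60/hr_bpm seconds plus zero-mean
    Gaussian jitter of sd 60*hr_sd_bpm/hr_bpm**2 seconds (the first-order
    propagation of a rate sd into an interval sd), floored at 0.3 s.  The
    first beat falls half an interval into the record.
    """
    if hr_bpm <= 0:
        raise ValueError(f"hr_bpm must be positive, got {hr_bpm}")
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    if hr_sd_bpm < 0:
        raise ValueError(f"hr_sd_bpm must be >= 0, got {hr_sd_bpm}")
    rng = np.random.default_rng(int(seed) & _SEED_MASK)
    mean_ibi = 60.0 / hr_bpm
    sd_ibi = 60.0 * hr_sd_bpm / hr_bpm**2

    def draw() -> float:
        return max(_MIN_IBI_S, mean_ibi + (rng.normal(0.0, sd_ibi) if sd_ibi > 0 else 0.0))

    n_samples = int(round(duration_s * fs))
    beats = []
    t = 0.5 * draw()
    while True:
        idx = int(round(t * fs))
        if idx >= n_samples:
            break
        beats.append(idx)
        t += draw()
    return np.asarray(beats, dtype=int)


def pulse_template(fs: float, width_s: float = 0.6) -> np.ndarray:
    """Asymmetric unimodal pulse: fast rise, slow decay, peak normalized to 1.

    A difference of two exponentials (rise constant width/12, decay constant
    width/5) gives the rapid upstroke the slope detector keys on, with the
    maximum well before the midpoint of the support.
    """
    if fs <= 0 or width_s <= 0:
        raise ValueError("fs and width_s must be positive")
    t = np.arange(int(round(width_s * fs))) / fs
    tau_rise = width_s / 12.0
    tau_decay = width_s / 5.0
    g = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return g / g.max()


def _event_intervals(
    rng: np.random.Generator, rate_per_min: float, duration_s: float, dur_s: float, fs: float
) -> list:
    """Poisson-arriving (start, length) sample intervals within the record."""
    n_samples = int(round(duration_s * fs))
    dur_n = max(1, int(round(dur_s * fs)))
    count = rng.poisson(rate_per_min * duration_s / 60.0) if rate_per_min > 0 else 0
    out = []
    for _ in range(count):
        start = int(rng.integers(0, max(1, n_samples - dur_n)))
        out.append((start, dur_n))
    return out


def _artifact_burst(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-std band-limited (0.5-8 Hz) noise burst with tapered edges."""
    raw = rng.normal(0.0, 1.0, n + 4 * int(fs))  # pad so filtfilt settles
    sos = _sig.butter(2, [0.5, 8.0], btype="bandpass", fs=fs, output="sos")
    band = _sig.sosfiltfilt(sos, raw)[2 * int(fs) : 2 * int(fs) + n]
    sd = band.std()
    if sd > 0:
        band = band / sd
    return band * np.hanning(n)


def generate_channel(
    beats: np.ndarray, scenario: ScenarioConfig, channel_index: int, seed: Optional[int] = None
) -> np.ndarray:
    """Synthesize one sensor channel for the given beat train.

    The channel-specific random stream is seeded with ``seed XOR
    channel_index`` so channels of one record differ while the whole record
    stays reproducible.
    """
    if not 0 <= channel_index < _N_CHANNELS:
        raise ValueError(f"channel_index must lie in [0, {_N_CHANNELS}), got {channel_index}")
    fs = scenario.fs
    n = scenario.n_samples
    base_seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng((int(base_seed) ^ int(channel_index)) & _SEED_MASK)

    tmpl = pulse_template(fs)
    peak_offset = int(np.argmax(tmpl))
    pulse = np.zeros(n)
    for b in np.asarray(beats, dtype=int):
        start = b - peak_offset
        lo, hi = max(start, 0), min(start + tmpl.size, n)
        if hi > lo:
            pulse[lo:hi] += tmpl[lo - start : hi - start]

    amp = scenario.channel_amplitudes[channel_index]
    noise_sd = _per_channel(scenario.noise_sd)[channel_index]
    art_rate = _per_channel(scenario.artifact_rate_per_min)[channel_index]
    art_amp = _per_channel(scenario.artifact_amp)[channel_index]
    drop_rate = _per_channel(scenario.dropout_rate_per_min)[channel_index]

    # baseline wander with a channel-specific phase
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / fs
    wander = (
        scenario.wander_amp * np.sin(2.0 * np.pi * scenario.wander_hz * t + phase)
        if scenario.wander_amp > 0
        else 0.0
    )

    # contact-loss dropouts: pulsatile component collapses, 50 ms taper
    mask = np.ones(n)
    taper = max(1, int(round(0.05 * fs)))
    for start, dur in _event_intervals(rng, drop_rate, scenario.duration_s, scenario.dropout_dur_s, fs):
        lo, hi = start, min(start + dur, n)
        mask[lo:hi] = 0.0
        ramp_in = np.linspace(1.0, 0.0, taper)
        ramp_out = np.linspace(0.0, 1.0, taper)
        a = max(lo - taper, 0)
        mask[a:lo] = np.minimum(mask[a:lo], ramp_in[taper - (lo - a) :])
        b_hi = min(hi + taper, n)
        mask[hi:b_hi] = np.minimum(mask[hi:b_hi], ramp_out[: b_hi - hi])

    # motion-artifact bursts
    artifacts = np.zeros(n)
    if art_amp > 0:
        for start, dur in _event_intervals(
            rng, art_rate, scenario.duration_s, scenario.artifact_dur_s, fs
        ):
            hi = min(start + dur, n)
            artifacts[start:hi] += art_amp * _artifact_burst(rng, dur, fs)[: hi - start]

    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
    return amp * pulse * mask + wander + artifacts + noise


def generate_record(scenario: ScenarioConfig) -> MultiChannelRecord:
    """Generate a full 4-channel record with ground-truth beat annotations."""
    beats = generate_beat_times(
        scenario.duration_s, scenario.hr_bpm, scenario.hr_sd_bpm, scenario.fs, scenario.seed
    )
    channels = np.vstack(
        [generate_channel(beats, scenario, i) for i in range(_N_CHANNELS)]
    )
    return MultiChannelRecord(
        samples=channels,
        fs=scenario.fs,
        reference_beats=beats,
        meta={"scenario": scenario.name, "seed": int(scenario.seed)},
    )
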