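"""Record/annotation/config I/O for multi-channel PPG processing.

A record is a delimited text table with a time column ``t`` (seconds) and
one column per sensor channel named ``ch1`` .. ``ch4``.  Beat annotations
travel in a sidecar file (same stem, ``.ann`` extension) holding one sample
index per line.  All indexing is 0-based and in samples, never seconds:
sample indices are exact, float times are not.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigError",
    "FormatError",
    "MultiChannelRecord",
    "RunConfig",
    "annotation_path",
    "load_config",
    "read_record",
    "write_peaks",
    "write_record",
]

N_CHANNELS = 4


class FormatError(ValueError):
    """A record or annotation file violates the expected text format."""


class ConfigError(ValueError):
    """A run-configuration value violates its contract."""


@dataclass(frozen=True)
class RunConfig:
    """Detector / fusion / scoring parameters.

    Defaults are the published operating point of the method: a 40th-order
    low-pass FIR at 5 Hz, weight step alpha = 2 with weights confined to
    [2, 20], a pulse-interval plausibility window of (0.7, 1.3) times the
    previous accepted interval, and 5 s head/tail trimming before scoring.

    The threshold update fraction and its calibration window, and the beat
    matching tolerance, are this implementation's documented choices (the
    method's description leaves them open); all are exposed here.
    """

    filter_order: int = 40
    cutoff_hz: float = 5.0
    alpha: float = 2.0
    weight_min: float = 2.0
    weight_max: float = 20.0
    ppi_low_factor: float = 0.7
    ppi_high_factor: float = 1.3
    threshold_fraction: float = 0.6
    threshold_init_s: float = 2.0
    gate_reset_after: int = 3
    th_decay_grace_s: float = 2.0
    th_halflife_s: float = 1.0
    weight_ramp_s: float = 0.3
    match_tolerance_s: float = 0.15
    trim_s: float = 5.0

    def __post_init__(self) -> None:
        if self.filter_order < 2 or self.filter_order % 2 != 0:
            raise ConfigError(f"filter_order must be an even integer >= 2, got {self.filter_order}")
        if self.cutoff_hz <= 0:
            raise ConfigError(f"cutoff_hz must be positive, got {self.cutoff_hz}")
        if self.alpha <= 0:
            raise ConfigError(f"alpha must be positive, got {self.alpha}")
        if not self.weight_min < self.weight_max:
            raise ConfigError(
                f"weight_min must be < weight_max, got {self.weight_min} >= {self.weight_max}"
            )
        if self.weight_min <= 0:
            raise ConfigError(f"weight_min must be positive, got {self.weight_min}")
        if not 0 < self.ppi_low_factor < 1:
            raise ConfigError(f"ppi_low_factor must lie in (0, 1), got {self.ppi_low_factor}")
        if self.ppi_high_factor <= 1:
            raise ConfigError(f"ppi_high_factor must be > 1, got {self.ppi_high_factor}")
        if not 0 < self.threshold_fraction <= 1:
            raise ConfigError(
                f"threshold_fraction must lie in (0, 1], got {self.threshold_fraction}"
            )
        if self.threshold_init_s < 0:
            raise ConfigError(f"threshold_init_s must be >= 0, got {self.threshold_init_s}")
        if self.gate_reset_after < 1:
            raise ConfigError(f"gate_reset_after must be >= 1, got {self.gate_reset_after}")
        if self.th_decay_grace_s < 0:
            raise ConfigError(f"th_decay_grace_s must be >= 0, got {self.th_decay_grace_s}")
        if self.th_halflife_s <= 0:
            raise ConfigError(f"th_halflife_s must be positive, got {self.th_halflife_s}")
        if self.weight_ramp_s < 0:
            raise ConfigError(f"weight_ramp_s must be >= 0, got {self.weight_ramp_s}")
        if self.match_tolerance_s < 0:
            raise ConfigError(f"match_tolerance_s must be >= 0, got {self.match_tolerance_s}")
        if self.trim_s < 0:
            raise ConfigError(f"trim_s must be >= 0, got {self.trim_s}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MultiChannelRecord:
    """A sampled multi-channel PPG recording with optional beat annotations.

    ``samples`` has shape (n_channels, n_samples); ``reference_beats`` are
    strictly increasing ground-truth beat sample indices (the pulse peak
    fiducial), or None when no reference is available.
    """

    samples: np.ndarray
    fs: float
    reference_beats: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D (channels x samples) array")
        if self.fs <= 0:
            raise FormatError(f"fs must be positive, got {self.fs}")
        if self.reference_beats is not None:
            beats = np.asarray(self.reference_beats, dtype=int)
            if beats.size and (np.any(np.diff(beats) <= 0)):
                raise FormatError("reference_beats must be strictly increasing")
            if beats.size and (beats[0] < 0 or beats[-1] >= self.n_samples):
                raise FormatError("reference_beats must lie within [0, n_samples)")
            self.reference_beats = beats

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def annotation_path(record_path: str | Path) -> Path:
    return Path(record_path).with_suffix(".ann")


def read_record(path: str | Path, fs: Optional[float] = None) -> MultiChannelRecord:
    """Read a CSV record (columns ``t, ch1..ch4``) and its ``.ann`` sidecar.

    The sampling rate is inferred from the time column; if ``fs`` is given
    it must agree with the inferred rate — a mismatch is an error, never a
    silent resample.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"{path}: cannot parse record table: {exc}") from exc

    channel_cols = [f"ch{i + 1}" for i in range(N_CHANNELS)]
    missing = [c for c in ["t", *channel_cols] if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if table[["t", *channel_cols]].isna().any().any():
        raise FormatError(f"{path}: table contains missing values (ragged rows?)")

    t = table["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: record must contain at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column is not strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 1e-6 * max(step, 1e-12) + 1e-9:
        raise FormatError(f"{path}: time column is not uniformly sampled")
    fs_inferred = 1.0 / step
    if fs is not None and abs(fs - fs_inferred) > 1e-6 * fs:
        raise FormatError(
            f"{path}: sampling rate mismatch (time column implies {fs_inferred:.6g} Hz, "
            f"config says {fs:.6g} Hz)"
        )
    fs_val = float(fs) if fs is not None else fs_inferred

    samples = table[channel_cols].to_numpy(dtype=float).T

    beats = None
    ann = annotation_path(path)
    if ann.exists():
        beats = read_annotations(ann)

    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    return MultiChannelRecord(samples=samples, fs=fs_val, reference_beats=beats, meta=meta)


def write_record(record: MultiChannelRecord, path: str | Path) -> None:
    """Write a record as CSV; annotations and metadata go to sidecar files."""
    path = Path(path)
    if record.n_channels != N_CHANNELS:
        raise FormatError(f"record has {record.n_channels} channels, expected {N_CHANNELS}")
    t = np.arange(record.n_samples) / record.fs
    table = pd.DataFrame({"t": t})
    for i in range(record.n_channels):
        table[f"ch{i + 1}"] = record.samples[i]
    table.to_csv(path, index=False, float_format="%.12g")
    if record.reference_beats is not None:
        write_annotations(record.reference_beats, annotation_path(path))
    if record.meta:
        path.with_suffix(".json").write_text(json.dumps(record.meta, indent=2, default=str))


def read_annotations(path: str | Path) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    try:
        beats = np.array([int(ln) for ln in lines], dtype=int)
    except ValueError as exc:
        raise FormatError(f"{path}: annotation lines must be integers: {exc}") from exc
    if beats.size and np.any(np.diff(beats) <= 0):
        raise FormatError(f"{path}: annotations must be strictly increasing")
    return beats


def write_annotations(beats: Sequence[int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{int(b)}\n" for b in beats))


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load a YAML key-value config; absent keys take the published defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping of parameter names to values")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {unknown}")
    return RunConfig(**raw)


def write_peaks(train, path: str | Path) -> None:
    """Write detected peaks, one candidate per line.

    Columns (tab-separated): sample index, accepted flag (0/1), interval to
    the previous accepted peak in samples (NA for the first accepted peak
    and for rejected candidates), and the pulse rate in bpm implied by that
    interval.
    """
    from .peak_detection import pulse_rate

    lines = ["index\taccepted\tppi_samples\tpr_bpm"]
    last_accepted = None
    for idx, acc in zip(train.indices, train.accepted):
        ppi_txt = pr_txt = "NA"
        if acc:
            if last_accepted is not None:
                ppi = int(idx - last_accepted)
                ppi_txt = str(ppi)
                pr_txt = f"{pulse_rate(ppi, train.fs):.6g}"
            last_accepted = int(idx)
        lines.append(f"{int(idx)}\t{int(acc)}\t{ppi_txt}\t{pr_txt}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_peaks(path: str | Path, fs: float = float("nan")):
    """Read a peak file written by :func:`write_peaks`."""
    from .peak_detection import PeakTrain

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("index"):
        raise FormatError(f"{path}: missing peak-file header")
    idx, acc = [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}: malformed peak line {ln!r}")
        idx.append(int(parts[0]))
        acc.append(bool(int(parts[1])))
    return PeakTrain(np.array(idx, dtype=int), np.array(acc, dtype=bool), fs=fs)
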