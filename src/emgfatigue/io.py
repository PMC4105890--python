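"""Reading and writing EMG recordings and analysis results.

Recordings travel as delimited text (comma or tab, autodetected): a time
column in seconds followed by one column per electrode channel in µV.
Channel columns are named ``<level>_<side>`` where the level is one of
the three lumbar recording sites (L1 iliocostalis lumborum, L2
longissimus, L5 multifidus) and the side is ``left`` or ``right``,
e.g. ``L5_left``. Columns whose names start with ``acc`` or ``aux``
(accelerometer/auxiliary channels) are carried along untouched and never
analyzed; any other column name is a format error.

The sampling rate is inferred from the time column (median inter-sample
interval) and the column is checked for uniformity to 1 ppm — spectral
estimates depend directly on the sampling rate, so a drifting or
resampled time base is rejected rather than warned about.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, SamplingError, ValidationError

LEVELS = ("L1", "L2", "L5")
SIDES = ("left", "right")

#: Fixed channel order used for deterministic iteration and tie-breaks.
CHANNEL_ORDER = tuple(f"{lvl}_{side}" for lvl in LEVELS for side in SIDES)

_EXTRA_PREFIXES = ("acc", "aux")

#: Relative tolerance for time-step uniformity.
TIME_STEP_TOLERANCE = 1e-6


@dataclass(frozen=True)
class ChannelLabel:
    """A (lumbar level, body side) electrode label, e.g. ``L5_left``."""

    level: str
    side: str

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValidationError(f"unknown lumbar level {self.level!r}; expected one of {LEVELS}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}; expected one of {SIDES}")

    def __str__(self) -> str:
        return f"{self.level}_{self.side}"

    @classmethod
    def parse(cls, name: str) -> "ChannelLabel":
        """Parse ``"L5_left"``-style strings; raises ValidationError otherwise."""
        parts = str(name).split("_")
        if len(parts) != 2:
            raise ValidationError(f"cannot parse channel label {name!r} (expected '<level>_<side>')")
        return cls(parts[0], parts[1])

    @property
    def opposite(self) -> "ChannelLabel":
        return ChannelLabel(self.level, "left" if self.side == "right" else "right")


def is_channel_name(name: str) -> bool:
    try:
        ChannelLabel.parse(name)
    except ValidationError:
        return False
    return True


@dataclass
class EMGRecording:
    """A multi-channel surface-EMG recording.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (Hz); 2000 Hz in the reference acquisition setup.
    samples : dict[str, numpy.ndarray]
        Per-channel amplitude series in µV, keyed by the channel label
        string. All channels must have equal length.
    metadata : dict
        Free-form recording metadata (subject id, day index, %MVC load,
        trunk-flexion angle, processing provenance). Never interpreted by
        the signal path itself.
    extras : dict[str, numpy.ndarray]
        Non-EMG columns (e.g. accelerometer axes) preserved for round-trip
        fidelity but ignored by every analysis stage.
    """

    sampling_rate: float
    samples: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)
    extras: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not self.samples:
            raise ValidationError("recording has no channels")
        lengths = {len(v) for v in self.samples.values()}
        if len(lengths) != 1:
            raise ValidationError(f"channels have unequal lengths: {sorted(lengths)}")
        for name in self.samples:
            ChannelLabel.parse(name)  # raises on bad labels
        self.samples = {k: np.asarray(v, dtype=float) for k, v in self.samples.items()}

    @property
    def channels(self) -> list[ChannelLabel]:
        return [ChannelLabel.parse(name) for name in self.samples]

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.samples.values())))

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, label: "ChannelLabel | str") -> np.ndarray:
        return self.samples[str(label)]

    def has_bilateral_pair(self, level: str) -> bool:
        return f"{level}_left" in self.samples and f"{level}_right" in self.samples

    def validate_for_fatigue(self, min_duration: float = 30.0) -> list[str]:
        """Return advisory flags; short recordings are flagged, not rejected."""
        flags = []
        if self.duration < min_duration:
            flags.append(f"duration {self.duration:.2f} s < {min_duration:g} s")
        return flags

    def copy_with(self, samples: dict[str, np.ndarray], **meta) -> "EMGRecording":
        md = dict(self.metadata)
        md.update(meta)
        return EMGRecording(self.sampling_rate, samples, md, dict(self.extras))


def _detect_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _looks_like_time(name: str) -> bool:
    return str(name).strip().lower() in {"time", "time_s", "t", "time (s)", "time_sec"}


def read_emg(
    path: "str | Path",
    format: str = "delimited",
    sampling_rate: "float | None" = None,
) -> EMGRecording:
    """Read a delimited EMG recording.

    The first column must be a time column (named ``time``/``time_s``/``t``);
    remaining columns are EMG channels (``L5_left`` etc.) or accelerometer
    extras. ``sampling_rate`` overrides the rate inferred from the time
    column; with or without an override the time column must be uniform to
    1 ppm.
    """
    if format != "delimited":
        raise FormatError(f"unsupported format {format!r}")
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            first = fh.readline()
    sep = _detect_delimiter(first)
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path.name}: need a time column plus at least one channel column")
    time_col = df.columns[0]
    if not _looks_like_time(time_col):
        raise FormatError(f"{path.name}: first column {time_col!r} is not a recognized time column")
    samples: dict[str, np.ndarray] = {}
    extras: dict[str, np.ndarray] = {}
    for col in df.columns[1:]:
        name = str(col).strip()
        if is_channel_name(name):
            samples[name] = df[col].to_numpy(dtype=float)
        elif name.lower().startswith(_EXTRA_PREFIXES):
            extras[name] = df[col].to_numpy(dtype=float)
        else:
            raise FormatError(f"{path.name}: column {name!r} is neither a channel label nor an extra")
    if not samples:
        raise FormatError(f"{path.name}: no EMG channel columns found")

    t = df[time_col].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0:
        raise SamplingError(f"{path.name}: recording has a single sample")
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise SamplingError(f"{path.name}: non-increasing time column")
    if np.max(np.abs(dt - dt_med)) > TIME_STEP_TOLERANCE * dt_med:
        raise SamplingError(
            f"{path.name}: non-uniform time steps exceed {TIME_STEP_TOLERANCE:.0e} relative tolerance"
        )
    fs = sampling_rate if sampling_rate is not None else 1.0 / dt_med
    return EMGRecording(fs, samples, metadata={"source": str(path)}, extras=extras)


def write_emg(rec: EMGRecording, path: "str | Path", delimiter: str = ",") -> Path:
    """Write a recording as delimited text (time + channel columns).

    Amplitudes are printed with 6 decimal places (≤ 0.5e-6 µV rounding
    loss); time with full float precision so re-reading passes the
    uniformity check.
    """
    if not rec.samples:
        raise ValidationError("cannot write a recording with no channels")
    path = Path(path)
    cols = {"time_s": rec.times}
    cols.update(rec.samples)
    cols.update(rec.extras)
    data = np.column_stack(list(cols.values()))
    fmt = ["%.12g"] + ["%.6f"] * (data.shape[1] - 1)
    np.savetxt(path, data, fmt=fmt, delimiter=delimiter,
               header=delimiter.join(cols), comments="")
    return path


def write_results(result, path: "str | Path", format: str = "delimited") -> Path:
    """Write an analysis result object to disk.

    Any result exposing ``to_frame()`` can be written as a delimited table;
    any result exposing ``to_dict()`` can be written as structured text
    (JSON). Nested reliability results default naturally to JSON.
    """
    path = Path(path)
    if format == "delimited":
        if not hasattr(result, "to_frame"):
            raise TypeError(f"{type(result).__name__} cannot be written as a delimited table")
        result.to_frame().to_csv(path, index=False)
    elif format == "structured-text":
        if not hasattr(result, "to_dict"):
            raise TypeError(f"{type(result).__name__} cannot be written as structured text")
        with open(path, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2, default=float)
            fh.write("\n")
    else:
        raise TypeError(f"unknown result format {format!r}")
    return path
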