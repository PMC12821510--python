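"""Shared time-series model, filtering/resampling primitives and CSV I/O.

The whole pipeline works on two multichannel recordings per session: joint
angles sampled at 100 Hz (degrees) and raw surface EMG sampled at 2000 Hz
(arbitrary units). Both are represented by :class:`TimeSeries`, a thin
container around a ``channels x samples`` float array with a sampling rate,
unique channel labels and a start time.

File format: comma-separated text with a header row. An optional leading
``time_s`` column carries the time stamps; when present the sampling rate can
be inferred from it, otherwise it must be supplied. Decimal point only, no
thousands separators.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .errors import FormatError, ParameterError, StructuralError

__all__ = [
    "MUSCLES",
    "SET_TYPES",
    "DOF_LABELS",
    "TimeSeries",
    "TaskManifest",
    "read_timeseries",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "butterworth_filter",
    "resample_linear",
]

#: The 16 recorded muscles of the dominant upper limb and trunk, in electrode
#: order: latissimus dorsi, lower/middle/upper trapezius, infraspinatus,
#: anterior/middle/posterior deltoid, pectoralis major, triceps long/lateral
#: head, biceps long/short head, brachioradialis, flexor/extensor carpi
#: radialis.
MUSCLES: tuple[str, ...] = (
    "LD", "LT", "MT", "UT", "In", "AD", "MD", "PD",
    "PM", "TLongH", "TLatH", "BLongH", "BShH", "Br", "FlexCR", "ExCR",
)

#: The nine set (overhead pass) variants, grouped by target: outside hitter
#: (high ball, 'super' ball, pipe), middle blocker (quick, seven, fast) and
#: opposite hitter (two, high back, back-row to zone 1).
SET_TYPES: tuple[str, ...] = (
    "high_ball", "super_ball", "pipe",
    "quick", "seven", "fast",
    "two", "high_back", "back_row",
)

#: The six upper-limb degrees of freedom, in reporting order.
DOF_LABELS: tuple[str, ...] = (
    "shoulder_fe", "shoulder_aa", "shoulder_rot",
    "elbow_fe", "elbow_ps", "wrist_fe",
)

_TIME_COLUMN_NAMES = ("time_s", "time", "t_s")


@dataclass
class TimeSeries:
    """A uniformly sampled multichannel signal.

    Parameters
    ----------
    values
        Array of shape ``(n_channels, n_samples)``.
    rate_hz
        Sampling rate in Hz, strictly positive.
    labels
        One unique name per channel.
    start_time_s
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    rate_hz: float
    labels: tuple[str, ...]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = tuple(str(x) for x in self.labels)
        if self.rate_hz <= 0:
            raise ParameterError(f"rate_hz must be positive, got {self.rate_hz}")
        if len(self.labels) != self.values.shape[0]:
            raise StructuralError(
                f"{len(self.labels)} labels for {self.values.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise StructuralError(f"duplicate channel labels in {self.labels}")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        """Time stamps of every sample, in seconds."""
        return self.start_time_s + np.arange(self.n_samples) / self.rate_hz

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D array."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise StructuralError(
                f"channel {label!r} not found; have {self.labels}"
            ) from None
        return self.values[idx]

    def slice(self, start: int, stop: int) -> "TimeSeries":
        """Sample-index slice ``[start, stop)`` keeping rate and labels."""
        if not 0 <= start < stop <= self.n_samples:
            raise ParameterError(
                f"slice [{start}, {stop}) outside 0..{self.n_samples}"
            )
        return TimeSeries(
            self.values[:, start:stop].copy(),
            self.rate_hz,
            self.labels,
            self.start_time_s + start / self.rate_hz,
        )

    def index_at(self, time_s: float) -> int:
        """Nearest sample index for a time in seconds (clipped to range)."""
        i = int(round((time_s - self.start_time_s) * self.rate_hz))
        return min(max(i, 0), self.n_samples - 1)


@dataclass
class TaskManifest:
    """Chronologically ordered mapping of repetitions to set types.

    ``entries`` holds ``(set_type, repetition_index)`` pairs in the order the
    repetitions were performed; indices are 1-based and unique within a set
    type. Set types must come from :data:`SET_TYPES`.
    """

    entries: tuple[tuple[str, int], ...]
    session_id: str = ""

    def __post_init__(self) -> None:
        self.entries = tuple((str(s), int(r)) for s, r in self.entries)
        seen: set[tuple[str, int]] = set()
        for set_type, rep in self.entries:
            if set_type not in SET_TYPES:
                raise StructuralError(
                    f"unknown set type {set_type!r}; expected one of {SET_TYPES}"
                )
            if rep < 1:
                raise StructuralError(f"repetition index must be >= 1, got {rep}")
            if (set_type, rep) in seen:
                raise StructuralError(
                    f"duplicate repetition {rep} for set type {set_type!r}"
                )
            seen.add((set_type, rep))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def set_types(self) -> tuple[str, ...]:
        """Distinct set types in first-appearance order."""
        out: list[str] = []
        for s, _ in self.entries:
            if s not in out:
                out.append(s)
        return tuple(out)


def read_timeseries(path: str | Path, rate_hz: float | None = None) -> TimeSeries:
    """Read a delimited-text time series.

    The first header column may be a time column (``time_s``/``time``/``t_s``);
    it is excluded from the values and, when ``rate_hz`` is not given, the
    sampling rate is inferred from its median increment. Errors cite the
    1-based file line of the offending row.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if len(set(header)) != len(header):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise FormatError(f"{path}: duplicate header names {dups}")
        ncol = len(header)
        rows: list[list[float]] = []
        for lineno, raw in enumerate(reader, start=2):
            if not raw or (len(raw) == 1 and raw[0].strip() == ""):
                continue  # ignore trailing blank lines
            if len(raw) != ncol:
                raise FormatError(
                    f"{path}: line {lineno}: expected {ncol} fields, got {len(raw)}"
                )
            parsed = []
            for col, cell in zip(header, raw):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric cell {cell!r} "
                        f"in column {col!r}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float).T  # columns x samples

    has_time = header[0].lower() in _TIME_COLUMN_NAMES
    start_time = 0.0
    if has_time:
        tcol, data = data[0], data[1:]
        header = header[1:]
        start_time = float(tcol[0])
        if rate_hz is None:
            if len(tcol) < 2:
                raise FormatError(
                    f"{path}: cannot infer sampling rate from a single sample"
                )
            dt = float(np.median(np.diff(tcol)))
            if dt <= 0:
                raise FormatError(f"{path}: non-increasing time column")
            rate_hz = 1.0 / dt
    elif rate_hz is None:
        raise ParameterError(
            f"{path}: no time column present, rate_hz must be supplied"
        )
    if not header:
        raise FormatError(f"{path}: no data channels besides the time column")
    return TimeSeries(data, float(rate_hz), tuple(header), start_time)


def write_timeseries(series: TimeSeries, path: str | Path) -> None:
    """Write a time series as CSV with a derived ``time_s`` first column."""
    if series.n_channels == 0:
        raise ParameterError("no channels to write")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("time_s",) + series.labels)
        times = series.times()
        for i in range(series.n_samples):
            writer.writerow(
                [format(times[i], ".10g")]
                + [format(v, ".12g") for v in series.values[:, i]]
            )


def read_manifest(path: str | Path, session_id: str = "") -> TaskManifest:
    """Read a manifest CSV with columns ``set_type, repetition``."""
    df = pd.read_csv(path)
    required = {"set_type", "repetition"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{path}: manifest must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    entries = tuple(
        (str(row.set_type), int(row.repetition)) for row in df.itertuples()
    )
    return TaskManifest(entries, session_id=session_id)


def write_manifest(manifest: TaskManifest, path: str | Path) -> None:
    pd.DataFrame(manifest.entries, columns=["set_type", "repetition"]).to_csv(
        path, index=False
    )


def butterworth_filter(
    series: TimeSeries,
    kind: str,
    cutoff_hz: float,
    order: int = 4,
    zero_phase: bool = True,
) -> TimeSeries:
    """Butterworth-filter every channel.

    ``zero_phase`` applies the filter forward and backward (``sosfiltfilt``),
    which cancels phase lag at the cost of doubling the effective attenuation;
    all pipeline defaults use it so that onset detection is not delayed by
    filter lag.
    """
    if kind not in ("lowpass", "highpass"):
        raise ParameterError(f"kind must be 'lowpass' or 'highpass', got {kind!r}")
    nyquist = series.rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz"
        )
    if order < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    if series.n_samples <= 3 * order:
        raise ParameterError(
            f"signal of {series.n_samples} samples too short for order {order} "
            f"(need > {3 * order})"
        )
    filtered = filter_array(
        series.values, series.rate_hz, kind, cutoff_hz, order, zero_phase
    )
    return TimeSeries(filtered, series.rate_hz, series.labels, series.start_time_s)


def filter_array(
    values: np.ndarray,
    rate_hz: float,
    kind: str,
    cutoff_hz: float,
    order: int,
    zero_phase: bool = True,
) -> np.ndarray:
    """Array-level Butterworth filter along the last axis (no validation)."""
    sos = _sig.butter(order, cutoff_hz, btype=kind, fs=rate_hz, output="sos")
    if zero_phase:
        return _sig.sosfiltfilt(sos, values, axis=-1)
    return _sig.sosfilt(sos, values, axis=-1)


def resample_linear(values: Sequence[float], target_length: int) -> np.ndarray:
    """Piecewise-linear resampling onto a uniform grid of ``target_length``.

    Endpoints are preserved exactly; the identity when lengths already match.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ParameterError(f"expected a 1-D sequence, got shape {x.shape}")
    if x.size < 2:
        raise ParameterError(f"need at least 2 samples, got {x.size}")
    if target_length < 2:
        raise ParameterError(f"target_length must be >= 2, got {target_length}")
    if target_length == x.size:
        return x.copy()
    grid = np.linspace(0.0, x.size - 1.0, target_length)
    out = np.interp(grid, np.arange(x.size), x)
    out[0], out[-1] = x[0], x[-1]
    return out


def resample_rows(values: np.ndarray, target_length: int) -> np.ndarray:
    """Apply :func:`resample_linear` to every row of a 2-D array."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return np.vstack([resample_linear(row, target_length) for row in values])
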