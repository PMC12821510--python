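"""Repetition segmentation and joint-angle summaries.

Segmentation works on the elbow flexion-extension angle: the trace is
low-pass filtered (3 Hz default), differentiated, and candidate flexion
events are the derivative peaks exceeding a fraction (20-30 %) of the
largest absolute derivative over the whole recording. Each retained maximum
is paired with the first following retained minimum; the movement onset is
the last derivative zero-crossing before the maximum, the offset the first
zero-crossing after the minimum. Events without a flanking zero-crossing are
clamped to the trace ends and flagged rather than dropped, so repetition
counts stay auditable.

Profile averaging resamples every repetition of a set type to the duration
of the longest one and reports the per-sample mean and standard deviation;
range of motion (ROM) is max minus min of the filtered repetition trace,
summarized by median and quartiles per (set type, degree of freedom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ParameterError, StructuralError
from .timeseries import TimeSeries, filter_array, resample_linear

__all__ = [
    "SegmentationConfig",
    "SegmentationEvents",
    "MeanProfile",
    "RomSummary",
    "derivative",
    "segment_repetitions",
    "average_profiles",
    "compute_rom",
    "rom_summary",
]


@dataclass
class SegmentationConfig:
    """Tunables for repetition segmentation.

    ``threshold_fraction`` is the peak-detection threshold as a fraction of
    the maximum absolute derivative over the recording (0.20-0.30 in
    practice, per set type); ``min_event_separation_s`` suppresses duplicate
    peaks from residual noise and is safe because repetitions are separated
    by at least 2 s of rest.
    """

    lowpass_cutoff_hz: float = 3.0
    threshold_fraction: float = 0.25
    min_event_separation_s: float = 0.5
    filter_order: int = 4
    zero_tol_fraction: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ParameterError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )
        if self.lowpass_cutoff_hz <= 0:
            raise ParameterError("lowpass_cutoff_hz must be positive")
        if self.min_event_separation_s < 0:
            raise ParameterError("min_event_separation_s must be >= 0")
        if not 0.0 <= self.zero_tol_fraction < 1.0:
            raise ParameterError("zero_tol_fraction must be in [0, 1)")


@dataclass
class SegmentationEvents:
    """Ordered, non-overlapping (onset, offset) sample-index pairs.

    ``clamped[i]`` is True when pair ``i`` had to be closed at a trace end
    because no flanking zero-crossing existed.
    """

    pairs: tuple[tuple[int, int], ...]
    rate_hz: float
    clamped: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        self.pairs = tuple((int(a), int(b)) for a, b in self.pairs)
        if not self.clamped:
            self.clamped = (False,) * len(self.pairs)
        prev_end = -1
        for onset, offset in self.pairs:
            if onset >= offset:
                raise StructuralError(f"onset {onset} not before offset {offset}")
            if onset <= prev_end:
                raise StructuralError("segmentation pairs overlap or are unordered")
            prev_end = offset

    def __len__(self) -> int:
        return len(self.pairs)

    def onsets_s(self) -> np.ndarray:
        return np.array([a for a, _ in self.pairs]) / self.rate_hz

    def offsets_s(self) -> np.ndarray:
        return np.array([b for _, b in self.pairs]) / self.rate_hz

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": self.onsets_s(),
                "offset_s": self.offsets_s(),
                "clamped": self.clamped,
            }
        )


def derivative(signal: Sequence[float], rate_hz: float) -> np.ndarray:
    """First time derivative: central differences inside, one-sided at ends.

    Input in degrees at ``rate_hz`` gives degrees/second out, same length.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ParameterError(f"need at least 2 samples, got {x.size}")
    if rate_hz <= 0:
        raise ParameterError("rate_hz must be positive")
    return np.gradient(x, 1.0 / rate_hz)


def _last_nonpositive_before(d: np.ndarray, tol: float, stop: int) -> int:
    """Index of the last sample <= +tol strictly before ``stop``, else -1.

    This is the zero-crossing preceding a derivative maximum, detected with
    a small dead-band: samples within ``tol`` of zero count as zero, which
    keeps the zero-phase filter's pre-ringing (a sub-degree/s undershoot
    just before a movement starts) from displacing the crossing. With
    ``tol = 0`` this reduces to the strict sign-change rule.
    """
    idx = np.flatnonzero(d[:stop] <= tol)
    return int(idx[-1]) if idx.size else -1


def _first_nonnegative_after(d: np.ndarray, tol: float, start: int) -> int:
    """Index of the first sample >= -tol at or after ``start``, else -1.

    The zero-crossing following a derivative minimum, with the same
    dead-band convention as :func:`_last_nonpositive_before`.
    """
    idx = np.flatnonzero(d[start:] >= -tol)
    return int(start + idx[0]) if idx.size else -1


def segment_repetitions(
    elbow_fe: Sequence[float],
    rate_hz: float,
    config: SegmentationConfig | None = None,
) -> SegmentationEvents:
    """Detect repetition onsets/offsets on an elbow flexion-extension trace.

    Returns an empty event list (not an error) for constant or featureless
    traces. See the module docstring for the algorithm.
    """
    config = config or SegmentationConfig()
    x = np.asarray(elbow_fe, dtype=float)
    if x.ndim != 1:
        raise ParameterError(f"expected a 1-D trace, got shape {x.shape}")
    if x.size < 2:
        return SegmentationEvents((), rate_hz)
    if config.lowpass_cutoff_hz >= rate_hz / 2:
        raise ParameterError(
            f"lowpass cutoff {config.lowpass_cutoff_hz} Hz >= Nyquist {rate_hz / 2} Hz"
        )
    if x.size > 3 * config.filter_order:
        x = filter_array(
            x, rate_hz, "lowpass", config.lowpass_cutoff_hz, config.filter_order
        )
    d = derivative(x, rate_hz)
    amplitude = float(np.max(np.abs(d)))
    if amplitude <= 0.0 or not np.isfinite(amplitude):
        return SegmentationEvents((), rate_hz)
    threshold = config.threshold_fraction * amplitude
    zero_tol = config.zero_tol_fraction * amplitude
    spacing = max(1, int(round(config.min_event_separation_s * rate_hz)))
    maxima, _ = find_peaks(d, height=threshold, distance=spacing)
    minima, _ = find_peaks(-d, height=threshold, distance=spacing)

    pairs: list[tuple[int, int]] = []
    clamped: list[bool] = []
    last_offset = -1
    n = d.size
    for peak in maxima:
        if peak <= last_offset:
            continue  # falls inside the previous repetition
        flag = False
        later_minima = minima[minima > peak]
        if later_minima.size == 0:
            # unpaired flexion at the end of the trace: close at the end
            offset = n - 1
            flag = True
        else:
            valley = int(later_minima[0])
            offset = _first_nonnegative_after(d, zero_tol, valley)
            if offset < 0:
                offset = n - 1
                flag = True
        onset = _last_nonpositive_before(d, zero_tol, peak)
        if onset <= last_offset:
            onset = last_offset + 1
            flag = True
        if onset >= offset:
            continue  # degenerate window, skip
        pairs.append((onset, offset))
        clamped.append(flag)
        last_offset = offset
    return SegmentationEvents(tuple(pairs), rate_hz, tuple(clamped))


@dataclass
class MeanProfile:
    """Mean +/- SD joint-angle profile of one set type.

    Sample count equals the longest repetition's length; ``sd`` is the
    sample standard deviation (ddof=1) across repetitions, zero when there
    is a single repetition.
    """

    mean: np.ndarray  # (n_dof, n_samples), degrees
    sd: np.ndarray
    labels: tuple[str, ...]
    rate_hz: float

    @property
    def duration_s(self) -> float:
        return self.mean.shape[1] / self.rate_hz

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape:
            raise StructuralError("mean and sd shapes differ")
        if np.any(self.sd < 0):
            raise StructuralError("negative standard deviation")


def average_profiles(repetitions: Sequence[TimeSeries]) -> MeanProfile:
    """Average the repetitions of one set type, resampled to the longest.

    All repetitions must share the same channel labels and rate. The longest
    repetition fixes the output length; every other one is linearly
    resampled to it, preserving the natural duration differences between set
    types while aligning repetitions within a type.
    """
    if not repetitions:
        raise ParameterError("need at least one repetition")
    labels = repetitions[0].labels
    rate = repetitions[0].rate_hz
    for rep in repetitions[1:]:
        if rep.labels != labels:
            raise StructuralError(
                f"channel sets differ: {rep.labels} vs {labels}"
            )
        if rep.rate_hz != rate:
            raise StructuralError("sampling rates differ between repetitions")
    target = max(rep.n_samples for rep in repetitions)
    stack = np.stack(
        [
            np.vstack([resample_linear(ch, target) for ch in rep.values])
            for rep in repetitions
        ]
    )  # (n_reps, n_dof, target)
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sd = stack.std(axis=0, ddof=1)
    else:
        sd = np.zeros_like(mean)
    return MeanProfile(mean, sd, labels, rate)


def compute_rom(profile: Sequence[float]) -> float:
    """Range of motion: max minus min of one repetition trace, in degrees."""
    x = np.asarray(profile, dtype=float)
    if x.size == 0:
        raise ParameterError("empty trace")
    return float(np.max(x) - np.min(x))


@dataclass
class RomSummary:
    """Per-repetition ROM table and quartile summary.

    ``per_repetition`` columns: set_type, dof, repetition, rom_deg.
    ``summary`` columns: set_type, dof, q1, median, q3 (the box-plot
    quantities).
    """

    per_repetition: pd.DataFrame
    summary: pd.DataFrame


def rom_summary(trials: Mapping[str, Sequence[TimeSeries]]) -> RomSummary:
    """Summarize ROM per (set type, DOF) over segmented repetitions.

    ``trials`` maps set type to its repetition segments (all sharing the
    same channel labels). Empty groups are skipped with a warning.
    Quartiles use linear interpolation between order statistics.
    """
    rows: list[dict] = []
    for set_type, reps in trials.items():
        if not reps:
            warnings.warn(f"set type {set_type!r} has no repetitions; skipped")
            continue
        for rep_idx, rep in enumerate(reps, start=1):
            for dof, trace in zip(rep.labels, rep.values):
                rows.append(
                    {
                        "set_type": set_type,
                        "dof": dof,
                        "repetition": rep_idx,
                        "rom_deg": compute_rom(trace),
                    }
                )
    if not rows:
        raise ParameterError("no repetitions in any group")
    per_rep = pd.DataFrame(rows)
    summary = (
        per_rep.groupby(["set_type", "dof"], sort=False)["rom_deg"]
        .agg(
            q1=lambda s: float(np.percentile(s, 25)),
            median=lambda s: float(np.percentile(s, 50)),
            q3=lambda s: float(np.percentile(s, 75)),
        )
        .reset_index()
    )
    return RomSummary(per_rep, summary)
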