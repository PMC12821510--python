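"""EMG envelopes, epoch assembly and muscle-synergy extraction by NMF.

The spatial synergy model factorizes the non-negative envelope matrix V
(M muscles x L samples) as V ~ W C, where the columns of W are
time-invariant spatial synergy vectors (each muscle's weighting within a
synergy) and the rows of C are the time-varying activation coefficients.

Processing chain per session:

1. raw EMG (2000 Hz) -> 10 Hz high-pass -> full-wave rectification ->
   5 Hz low-pass (5th-order Butterworth, zero-phase) -> envelope;
2. per repetition, the envelope window from 0.25 s before onset to 0.25 s
   after offset is resampled to T = 100 samples;
3. epochs are concatenated in chronological order into an M x (K*T*N)
   matrix (K set types, N repetitions) and each muscle row is divided by
   its maximum over all trials, so every row peaks at 1;
4. NMF (multiplicative updates, squared Euclidean loss) is run with 20
   random restarts per candidate order; reconstruction quality is
   R^2 = 1 - SSE/SST with SST taken about the per-muscle mean vector; the
   selected order is the smallest whose best-restart R^2 reaches 0.80.

After extraction each spatial vector is scaled to unit Euclidean norm and
its coefficient row by the reciprocal, which leaves the reconstruction W C
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    EventError,
    ParameterError,
    StructuralError,
    UndefinedStatisticError,
)
from .timeseries import TaskManifest, TimeSeries, filter_array, resample_rows

__all__ = [
    "EnvelopeConfig",
    "EmgMatrix",
    "SynergyModel",
    "RsqCurve",
    "compute_envelope",
    "extract_epoch",
    "build_matrix",
    "r_squared",
    "nmf_decompose",
    "select_order",
]

_EPS = 1e-12


@dataclass
class EnvelopeConfig:
    """EMG envelope and epoch parameters.

    The high-pass (10 Hz) acts on the raw signal, the low-pass (5 Hz) on the
    rectified signal; both are 5th-order Butterworth filters applied
    zero-phase. ``pad_s`` extends each epoch 0.25 s before the onset and
    after the offset so the complete EMG burst is captured;
    ``epoch_samples`` is the common length T every padded epoch is
    resampled to.
    """

    highpass_hz: float = 10.0
    lowpass_hz: float = 5.0
    filter_order: int = 5
    pad_s: float = 0.25
    epoch_samples: int = 100

    def __post_init__(self) -> None:
        if self.highpass_hz <= 0 or self.lowpass_hz <= 0:
            raise ParameterError("filter cutoffs must be positive")
        if self.pad_s < 0:
            raise ParameterError("pad_s must be >= 0")
        if self.epoch_samples < 2:
            raise ParameterError("epoch_samples must be >= 2")
        if self.filter_order < 1:
            raise ParameterError("filter_order must be >= 1")


@dataclass
class EmgMatrix:
    """Concatenated, max-normalized envelope matrix M x (K*T*N).

    ``column_index`` labels every column with its (set_type, repetition,
    sample) origin in concatenation order.
    """

    values: np.ndarray
    muscle_labels: tuple[str, ...]
    column_index: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise StructuralError("EmgMatrix values must be 2-D")
        if len(self.muscle_labels) != self.values.shape[0]:
            raise StructuralError("muscle label count does not match rows")
        if len(self.column_index) != self.values.shape[1]:
            raise StructuralError("column index length does not match columns")
        if np.any(self.values < 0):
            raise DataError("EmgMatrix entries must be non-negative")

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


@dataclass
class SynergyModel:
    """Result of one NMF decomposition at a fixed order.

    ``W`` is M x S (unit-norm spatial vectors), ``C`` is S x L (activation
    coefficients); ``restart_seeds`` records the per-restart RNG seeds for
    audit, and ``best_restart`` which of them won.
    """

    W: np.ndarray
    C: np.ndarray
    order: int
    r_squared: float
    restart_seeds: tuple[int, ...]
    best_restart: int = 0
    n_iterations: int = 0


@dataclass
class RsqCurve:
    """R^2 versus synergy order, and the selected order.

    ``selected_order`` is the minimum order whose best-restart R^2 reaches
    ``threshold`` (the full order M, with a warning, if none does).
    ``models`` keeps the fitted model per order so the selected one can be
    reused without refitting.
    """

    orders: tuple[int, ...]
    r_squared_per_order: tuple[float, ...]
    selected_order: int
    threshold: float
    models: dict[int, SynergyModel] = field(default_factory=dict)

    @property
    def selected_model(self) -> SynergyModel:
        return self.models[self.selected_order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"order": self.orders, "r_squared": self.r_squared_per_order}
        )


def compute_envelope(
    raw_emg: TimeSeries, config: EnvelopeConfig | None = None
) -> TimeSeries:
    """High-pass, full-wave rectify and low-pass every EMG channel.

    Small negative excursions from filter ringing are clamped to zero so the
    result is a valid non-negative envelope.
    """
    config = config or EnvelopeConfig()
    if raw_emg.rate_hz < 4 * config.highpass_hz:
        raise ParameterError(
            f"sampling rate {raw_emg.rate_hz} Hz too low for a "
            f"{config.highpass_hz} Hz high-pass (need >= 4x)"
        )
    x = filter_array(
        raw_emg.values, raw_emg.rate_hz, "highpass",
        config.highpass_hz, config.filter_order,
    )
    x = np.abs(x)
    x = filter_array(
        x, raw_emg.rate_hz, "lowpass", config.lowpass_hz, config.filter_order
    )
    np.clip(x, 0.0, None, out=x)
    return TimeSeries(x, raw_emg.rate_hz, raw_emg.labels, raw_emg.start_time_s)


def extract_epoch(
    envelope: TimeSeries,
    onset_s: float,
    offset_s: float,
    config: EnvelopeConfig | None = None,
) -> tuple[np.ndarray, bool]:
    """Slice the padded window of one repetition and resample it to T.

    The window ``[onset - pad, offset + pad]`` (seconds) is clamped to the
    recording bounds; the second return value flags whether clamping
    occurred. Every channel is then linearly resampled to
    ``config.epoch_samples`` columns.
    """
    config = config or EnvelopeConfig()
    if offset_s <= onset_s:
        raise EventError(f"offset {offset_s} s not after onset {onset_s} s")
    t0 = onset_s - config.pad_s
    t1 = offset_s + config.pad_s
    end_time = envelope.start_time_s + (envelope.n_samples - 1) / envelope.rate_hz
    if t1 <= envelope.start_time_s or t0 >= end_time:
        raise EventError(
            f"window [{t0}, {t1}] s lies outside the recording "
            f"[{envelope.start_time_s}, {end_time}] s"
        )
    i0 = int(round((t0 - envelope.start_time_s) * envelope.rate_hz))
    i1 = int(round((t1 - envelope.start_time_s) * envelope.rate_hz))
    clamped = i0 < 0 or i1 > envelope.n_samples - 1
    i0 = max(i0, 0)
    i1 = min(i1, envelope.n_samples - 1)
    if i1 - i0 < 1:
        raise EventError("window too short after clamping")
    window = envelope.values[:, i0 : i1 + 1]
    return resample_rows(window, config.epoch_samples), clamped


def build_matrix(
    epochs: Mapping[tuple[str, int], np.ndarray],
    manifest: TaskManifest,
) -> EmgMatrix:
    """Concatenate epochs in manifest order and normalize per muscle.

    ``epochs`` maps (set_type, repetition) to an M x T envelope epoch; the
    manifest fixes the chronological concatenation order. Each muscle row of
    the concatenated matrix is divided by its maximum across all trials. A
    muscle whose envelope is zero everywhere indicates a dead channel and is
    reported as an error rather than silently rescaled.
    """
    if not manifest.entries:
        raise ParameterError("empty manifest")
    missing = [key for key in manifest.entries if key not in epochs]
    if missing:
        raise StructuralError(f"manifest entries without epochs: {missing}")
    first = np.asarray(epochs[manifest.entries[0]], dtype=float)
    n_muscles, n_samples = first.shape
    blocks: list[np.ndarray] = []
    index_rows: list[dict] = []
    for set_type, rep in manifest.entries:
        block = np.asarray(epochs[(set_type, rep)], dtype=float)
        if block.shape != (n_muscles, n_samples):
            raise StructuralError(
                f"epoch {(set_type, rep)} has shape {block.shape}, "
                f"expected {(n_muscles, n_samples)}"
            )
        blocks.append(block)
        index_rows.extend(
            {"set_type": set_type, "repetition": rep, "sample": t}
            for t in range(n_samples)
        )
    values = np.hstack(blocks)
    if np.any(values < 0):
        raise DataError("negative envelope values in epochs")
    row_max = values.max(axis=1)
    silent = np.flatnonzero(row_max <= 0.0)
    muscle_labels = _muscle_labels(epochs, manifest, n_muscles)
    if silent.size:
        names = [muscle_labels[i] for i in silent]
        raise DataError(
            f"muscle channel(s) {names} have zero envelope across all trials"
        )
    values = values / row_max[:, None]
    return EmgMatrix(values, muscle_labels, pd.DataFrame(index_rows))


def _muscle_labels(epochs, manifest, n_muscles) -> tuple[str, ...]:
    from .timeseries import MUSCLES

    if n_muscles == len(MUSCLES):
        return MUSCLES
    return tuple(f"ch{i + 1}" for i in range(n_muscles))


def _as_values(data: "EmgMatrix | np.ndarray") -> np.ndarray:
    if isinstance(data, EmgMatrix):
        return data.values
    return np.asarray(data, dtype=float)


def r_squared(
    data: "EmgMatrix | np.ndarray", W: np.ndarray, C: np.ndarray
) -> float:
    """Reconstruction R^2 = 1 - SSE/SST.

    SSE is the summed squared residual of W C; SST is the summed squared
    deviation of the data from the per-muscle mean vector (each row's mean
    repeated along time), so R^2 measures variance captured beyond a
    constant activation level per muscle.
    """
    V = _as_values(data)
    W = np.asarray(W, dtype=float)
    C = np.asarray(C, dtype=float)
    if W.shape[0] != V.shape[0] or C.shape[1] != V.shape[1] or W.shape[1] != C.shape[0]:
        raise StructuralError(
            f"shapes do not conform: data {V.shape}, W {W.shape}, C {C.shape}"
        )
    sse = float(np.sum((V - W @ C) ** 2))
    sst = float(np.sum((V - V.mean(axis=1, keepdims=True)) ** 2))
    if sst == 0.0:
        raise UndefinedStatisticError(
            "SST is zero (constant per-muscle data); R^2 undefined"
        )
    return 1.0 - sse / sst


def _mu_nmf(
    V: np.ndarray,
    order: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """One multiplicative-update NMF run from a random initialization.

    Minimizes ||V - W H||_F^2; convergence when the relative change of the
    squared error between iterations drops below ``tol``. The update loop
    runs in single precision for speed — the multiplicative updates are
    self-correcting and the attainable factorization accuracy is far above
    float32 resolution — and the factors are returned in double precision.
    """
    m, n = V.shape
    norm_v = float(np.einsum("ij,ij->", V, V, dtype=np.float64))
    V = np.ascontiguousarray(V, dtype=np.float32)
    scale = np.sqrt(max(float(V.mean()), _EPS) / order)
    W = (scale * (0.1 + 0.9 * rng.random((m, order)))).astype(np.float32)
    H = (scale * (0.1 + 0.9 * rng.random((order, n)))).astype(np.float32)
    prev_err: float | None = None
    err = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        VHt = V @ H.T
        HHt = H @ H.T
        W *= VHt / (W @ HHt + _EPS)
        # ||V - W H||^2 from terms already computed (VHt, HHt are exact for
        # the current H; only the two small traces involve the new W)
        err = max(
            norm_v
            - 2.0 * float(np.einsum("ij,ij->", W, VHt))
            + float(np.einsum("ij,ij->", W.T @ W, HHt)),
            0.0,
        )
        if prev_err is not None and abs(prev_err - err) <= tol * max(prev_err, _EPS):
            break
        prev_err = err
    return W.astype(np.float64), H.astype(np.float64), err, it


def _normalize(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scale W columns to unit Euclidean norm, C rows by the reciprocal."""
    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return W / safe, C * safe[:, None]


def nmf_decompose(
    data: "EmgMatrix | np.ndarray",
    order: int,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> SynergyModel:
    """Multi-restart NMF at a fixed synergy order.

    Each restart draws its own initialization from a seed spawned
    deterministically from ``seed``; the restart with the lowest squared
    reconstruction error (equivalently highest R^2) wins. The returned model
    is normalized (unit-norm spatial vectors) and bitwise reproducible for a
    given seed.
    """
    V = _as_values(data)
    if V.ndim != 2:
        raise StructuralError("data must be a 2-D matrix")
    if np.any(V < 0):
        raise DataError("NMF requires non-negative data")
    m = V.shape[0]
    if not 1 <= order <= m:
        raise ParameterError(f"order must be in 1..{m}, got {order}")
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")
    seeds = tuple(
        int(s) for s in np.random.SeedSequence(seed).generate_state(n_restarts)
    )
    best: tuple[float, int, np.ndarray, np.ndarray, int] | None = None
    for idx, restart_seed in enumerate(seeds):
        rng = np.random.default_rng(restart_seed)
        W, H, err, iters = _mu_nmf(V, order, rng, tol, max_iter)
        if best is None or err < best[0]:
            best = (err, idx, W, H, iters)
    err, idx, W, H, iters = best
    W, H = _normalize(W, H)
    return SynergyModel(
        W=W,
        C=H,
        order=order,
        r_squared=r_squared(V, W, H),
        restart_seeds=seeds,
        best_restart=idx,
        n_iterations=iters,
    )


def select_order(
    data: "EmgMatrix | np.ndarray",
    threshold: float = 0.80,
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> RsqCurve:
    """Fit NMF at every order 1..M and pick the smallest reaching threshold.

    The full R^2-versus-order curve is always computed (it is itself a
    reported result); if no order reaches the threshold the full order M is
    selected with a warning.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    V = _as_values(data)
    m = V.shape[0]
    orders = tuple(range(1, m + 1))
    models: dict[int, SynergyModel] = {}
    rsq: list[float] = []
    for order in orders:
        model = nmf_decompose(
            data, order, n_restarts=n_restarts, seed=seed + order,
            tol=tol, max_iter=max_iter,
        )
        models[order] = model
        rsq.append(model.r_squared)
    selected = next((o for o, r in zip(orders, rsq) if r >= threshold), None)
    if selected is None:
        warnings.warn(
            f"no order reached R^2 >= {threshold}; selecting full order {m}"
        )
        selected = m
    return RsqCurve(orders, tuple(rsq), selected, threshold, models)
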