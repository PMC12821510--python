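"""Session analysis orchestration and report generation.

``analyze_session`` runs the full chain on in-memory recordings:
segmentation on the elbow flexion-extension trace, joint-angle profile and
ROM summaries, EMG envelope extraction, epoch assembly and synergy
extraction with order selection. ``run_pipeline`` is the file-based wrapper
that reads the three session CSVs, calls it and writes every intermediate
artifact plus a JSON run log (seeds, parameters, versions). ``run_retest``
analyzes two sessions and emits the cross-session report tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PipelineError, SynkinError
from .kinematics import (
    MeanProfile,
    RomSummary,
    SegmentationConfig,
    SegmentationEvents,
    average_profiles,
    rom_summary,
    segment_repetitions,
)
from .reliability import RetestReport, compare_sessions
from .synergy import (
    EmgMatrix,
    EnvelopeConfig,
    RsqCurve,
    SynergyModel,
    build_matrix,
    compute_envelope,
    extract_epoch,
    nmf_decompose,
    select_order,
)
from .timeseries import (
    TaskManifest,
    TimeSeries,
    butterworth_filter,
    read_manifest,
    read_timeseries,
)

__all__ = ["PipelineConfig", "SessionResult", "analyze_session", "run_pipeline", "run_retest"]

KIN_RATE_HZ = 100.0
EMG_RATE_HZ = 2000.0


@dataclass
class PipelineConfig:
    """Everything needed to analyze one session.

    ``synergy_order`` forces a fixed decomposition order (needed when two
    sessions must be compared at a common order); when None the order is
    selected from the R^2 >= ``synergy_threshold`` rule.
    """

    kinematics_path: str = ""
    emg_path: str = ""
    manifest_path: str = ""
    out_dir: str | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    analysis_lowpass_hz: float = 3.0
    elbow_channel: str = "elbow_fe"
    synergy_threshold: float = 0.80
    synergy_order: int | None = None
    n_restarts: int = 20
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        env = EnvelopeConfig(**raw.pop("envelope", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(segmentation=seg, envelope=env, **raw)


@dataclass
class SessionResult:
    """Bundle of everything computed for one session."""

    events: SegmentationEvents
    manifest: TaskManifest
    segments: dict[str, list[TimeSeries]]  # set type -> filtered repetitions
    profiles: dict[str, MeanProfile]
    rom: RomSummary
    emg_matrix: EmgMatrix | None
    rsq_curve: RsqCurve | None
    synergy_model: SynergyModel | None
    mean_coefficients: dict[str, np.ndarray]
    config: PipelineConfig

    @property
    def order(self) -> int | None:
        return self.synergy_model.order if self.synergy_model else None


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise package errors naming the stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, SynkinError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def analyze_session(
    kinematics: TimeSeries,
    emg: TimeSeries | None,
    manifest: TaskManifest,
    config: PipelineConfig | None = None,
) -> SessionResult:
    """Run segmentation, kinematic summaries and synergy extraction.

    The number of detected repetitions must match the manifest, which then
    assigns each chronological event its set type. EMG analysis is skipped
    when ``emg`` is None (kinematics-only sessions).
    """
    config = config or PipelineConfig()

    with _stage("segmentation"):
        elbow = kinematics.channel(config.elbow_channel)
        events = segment_repetitions(
            elbow, kinematics.rate_hz, config.segmentation
        )
    if len(events) != len(manifest):
        raise PipelineError(
            f"stage 'segmentation' failed: detected {len(events)} repetitions "
            f"but the manifest lists {len(manifest)}"
        )

    with _stage("kinematic summaries"):
        filtered = butterworth_filter(
            kinematics, "lowpass", config.analysis_lowpass_hz,
            config.segmentation.filter_order,
        )
        segments: dict[str, list[TimeSeries]] = {
            s: [] for s in manifest.set_types
        }
        for (set_type, _rep), (i0, i1) in zip(manifest.entries, events.pairs):
            segments[set_type].append(filtered.slice(i0, i1 + 1))
        profiles = {s: average_profiles(reps) for s, reps in segments.items()}
        rom = rom_summary(segments)

    emg_matrix = None
    curve = None
    model = None
    mean_coeffs: dict[str, np.ndarray] = {}
    if emg is not None:
        with _stage("emg envelope"):
            envelope = compute_envelope(emg, config.envelope)
        with _stage("epoch assembly"):
            onsets = events.onsets_s()
            offsets = events.offsets_s()
            epochs = {}
            for key, onset, offset in zip(manifest.entries, onsets, offsets):
                epoch, _clamped = extract_epoch(
                    envelope, float(onset), float(offset), config.envelope
                )
                epochs[key] = epoch
            emg_matrix = build_matrix(epochs, manifest)
        with _stage("synergy extraction"):
            if config.synergy_order is not None:
                model = nmf_decompose(
                    emg_matrix, config.synergy_order,
                    n_restarts=config.n_restarts, seed=config.seed,
                )
            else:
                curve = select_order(
                    emg_matrix, threshold=config.synergy_threshold,
                    n_restarts=config.n_restarts, seed=config.seed,
                )
                model = curve.selected_model
            mean_coeffs = mean_coefficients(model, emg_matrix)

    return SessionResult(
        events=events,
        manifest=manifest,
        segments=segments,
        profiles=profiles,
        rom=rom,
        emg_matrix=emg_matrix,
        rsq_curve=curve,
        synergy_model=model,
        mean_coefficients=mean_coeffs,
        config=config,
    )


def mean_coefficients(model: SynergyModel, matrix: EmgMatrix) -> dict[str, np.ndarray]:
    """Session-mean activation curve per set type: S x T, averaged over reps."""
    out: dict[str, np.ndarray] = {}
    idx = matrix.column_index
    for set_type in idx["set_type"].unique():
        cols = idx["set_type"] == set_type
        sub = model.C[:, cols.to_numpy()]
        t = int(idx.loc[cols, "sample"].max()) + 1
        n_reps = sub.shape[1] // t
        out[str(set_type)] = sub.reshape(model.order, n_reps, t).mean(axis=1)
    return out


def run_pipeline(config: PipelineConfig) -> SessionResult:
    """File-based single-session analysis with artifact output.

    Reads the kinematics, EMG and manifest CSVs named in the config, runs
    :func:`analyze_session` and, when ``out_dir`` is set, writes events,
    profiles, ROM tables, the synergy factors, the R^2 curve and a run log.
    """
    for label, path in (
        ("kinematics", config.kinematics_path),
        ("emg", config.emg_path),
        ("manifest", config.manifest_path),
    ):
        if label == "emg" and not path:
            continue  # kinematics-only run
        if not path or not Path(path).exists():
            raise ConfigError(f"{label} file not found: {path!r}")
    with _stage("input"):
        kin = read_timeseries(config.kinematics_path, rate_hz=KIN_RATE_HZ)
        emg = (
            read_timeseries(config.emg_path, rate_hz=EMG_RATE_HZ)
            if config.emg_path
            else None
        )
        manifest = read_manifest(config.manifest_path)
    result = analyze_session(kin, emg, manifest, config)
    if config.out_dir:
        write_session_artifacts(result, Path(config.out_dir))
    return result


def write_session_artifacts(result: SessionResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    events = result.events.to_frame()
    events.insert(0, "repetition", [r for _, r in result.manifest.entries])
    events.insert(0, "set_type", [s for s, _ in result.manifest.entries])
    events.to_csv(out_dir / "events.csv", index=False)
    result.rom.per_repetition.to_csv(out_dir / "rom_per_repetition.csv", index=False)
    result.rom.summary.to_csv(out_dir / "rom_summary.csv", index=False)
    for set_type, profile in result.profiles.items():
        df = pd.DataFrame(profile.mean.T, columns=list(profile.labels))
        for lab, sd_row in zip(profile.labels, profile.sd):
            df[f"{lab}_sd"] = sd_row
        df.insert(0, "time_s", np.arange(df.shape[0]) / profile.rate_hz)
        df.to_csv(out_dir / f"profile_{set_type}.csv", index=False)
    if result.synergy_model is not None:
        model = result.synergy_model
        pd.DataFrame(
            model.W,
            index=list(result.emg_matrix.muscle_labels),
            columns=[f"W{i + 1}" for i in range(model.order)],
        ).to_csv(out_dir / "synergies_W.csv")
        coeff = pd.DataFrame(
            model.C.T, columns=[f"C{i + 1}" for i in range(model.order)]
        )
        coeff = pd.concat(
            [result.emg_matrix.column_index.reset_index(drop=True), coeff], axis=1
        )
        coeff.to_csv(out_dir / "coefficients_C.csv", index=False)
        if result.rsq_curve is not None:
            result.rsq_curve.to_frame().to_csv(out_dir / "r2_curve.csv", index=False)
    log = {
        "synkin_version": __version__,
        "seed": result.config.seed,
        "n_restarts": result.config.n_restarts,
        "synergy_threshold": result.config.synergy_threshold,
        "synergy_order": result.order,
        "segmentation": asdict(result.config.segmentation),
        "envelope": asdict(result.config.envelope),
        "analysis_lowpass_hz": result.config.analysis_lowpass_hz,
        "n_events": len(result.events),
        "r_squared": (
            result.synergy_model.r_squared if result.synergy_model else None
        ),
        "restart_seeds": (
            list(result.synergy_model.restart_seeds)
            if result.synergy_model
            else None
        ),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))


def run_retest(
    config1: PipelineConfig,
    config2: PipelineConfig,
    out_dir: str | Path | None = None,
) -> RetestReport:
    """Analyze two sessions and produce the cross-session report.

    Both sessions must end up at the same synergy order; if automatic order
    selection disagrees between sessions, re-run with ``synergy_order`` set
    to a common value in both configs.
    """
    result1 = run_pipeline(config1)
    result2 = run_pipeline(config2)
    report = compare_sessions(result1, result2)
    if out_dir is not None:
        write_report(report, Path(out_dir))
    return report


def write_report(report: RetestReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.similarity.to_csv(out_dir / "similarity.csv", index=False)
    report.temporal_r.to_csv(out_dir / "temporal_pearson.csv", index=False)
    report.kinematic.to_csv(out_dir / "kinematic_reliability.csv", index=False)
    (out_dir / "retest_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=float)
    )
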