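"""Ground-truth session simulator for the full pipeline.

No public recordings of the protocol exist, so every stage is validated on
simulated sessions with known ground truth:

* joint angles (100 Hz, 6 DOF) are built from per-set templates — raised
  cosine transitions with set-specific durations (1.5-3 s) and amplitudes,
  an elbow flexion peak of 95-105 degrees — placed on a timeline with at
  least 2 s of rest between repetitions, plus smooth Gaussian angular
  variability per repetition and an optional constant inter-session offset;
* raw EMG (2000 Hz, 16 muscles) follows the standard surface-EMG
  phenomenology of an amplitude-modulated carrier: the true envelope
  W_true . C_true (sparse spatial synergy vectors times truncated-Gaussian
  activation bumps) multiplies band-limited (20-450 Hz) unit-variance
  Gaussian noise, and additive sensor noise sets the SNR.

Defaults mirror the protocol's dimensions: 16 muscles, 9 set types, 10
repetitions, 100-sample epochs and 5 ground-truth synergies whose sparse
muscle patterns and activation order (initiation -> arm raise -> wrist /
trunk stabilization -> final push) echo the synergies observed in overhead
setting movements.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .errors import ParameterError
from .timeseries import (
    DOF_LABELS,
    MUSCLES,
    SET_TYPES,
    TaskManifest,
    TimeSeries,
    filter_array,
    resample_rows,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticSession",
    "generate_ground_truth",
    "synthesize_session",
    "make_retest_pair",
]

KIN_RATE_HZ = 100.0
EMG_RATE_HZ = 2000.0

#: Rest between consecutive repetitions (>= the protocol's 2 s).
REST_S = 2.5
#: Lead-in before the first repetition.
LEAD_IN_S = 1.5

#: Per-set movement durations in seconds, spanning the 1.5-3 s range: quick
#: middle-blocker and 'two' sets are fastest, the pipe and back-row slowest.
SET_DURATIONS_S: dict[str, float] = {
    "high_ball": 2.4,
    "super_ball": 2.0,
    "pipe": 3.0,
    "quick": 1.8,
    "seven": 2.2,
    "fast": 1.6,
    "two": 1.5,
    "high_back": 2.6,
    "back_row": 2.8,
}

#: Absolute peak joint angle (degrees) per set type and DOF, ordered as
#: DOF_LABELS. Shoulder flexion-extension peaks at ~160-200 degrees (range
#: above baseline ~150-190), elbow flexion peaks between 95 and 105 degrees
#: over a 30-degree baseline.
_SET_PEAKS: dict[str, tuple[float, ...]] = {
    #            sh_fe  sh_aa  sh_rot el_fe  el_ps  wr_fe
    "high_ball": (160.0, 140.0, 75.0, 100.0, 115.0, 65.0),
    "super_ball": (165.0, 130.0, 85.0, 105.0, 100.0, 60.0),
    "pipe":      (180.0, 165.0, 60.0, 98.0, 105.0, 75.0),
    "quick":     (170.0, 130.0, 70.0, 100.0, 110.0, 70.0),
    "seven":     (120.0, 110.0, 90.0, 102.0, 112.0, 60.0),
    "fast":      (190.0, 150.0, 55.0, 101.0, 80.0, 80.0),
    "two":       (174.0, 120.0, 50.0, 95.0, 95.0, 68.0),
    "high_back": (200.0, 145.0, 110.0, 103.0, 120.0, 64.0),
    "back_row":  (198.0, 168.0, 85.0, 105.0, 108.0, 52.0),
}

#: Resting joint angles in degrees (arms along the body).
_BASELINE_DEG = np.array([10.0, 5.0, 0.0, 30.0, 10.0, 0.0])

# Ground-truth spatial patterns, muscles in MUSCLES order:
#   LD LT MT UT In AD MD PD PM TLongH TLatH BLongH BShH Br FlexCR ExCR
# S1: arm raise (trapezius, deltoids, infraspinatus, biceps long head)
# S2: final push (triceps, deltoids, wrist/forearm muscles)
# S3: wrist/ball handling (brachioradialis, carpi radialis pair)
# S4: trunk stabilization (latissimus, lower trapezius, weak arm muscles)
# S5: initiation (biceps heads, upper trapezius, weak forearm)
_BASE_PATTERNS = np.array(
    [
        # S1    S2    S3    S4    S5
        [0.00, 0.00, 0.00, 0.90, 0.00],  # LD
        [0.60, 0.00, 0.00, 0.45, 0.00],  # LT
        [0.80, 0.00, 0.00, 0.00, 0.00],  # MT
        [0.15, 0.00, 0.00, 0.00, 0.60],  # UT
        [0.70, 0.15, 0.00, 0.00, 0.00],  # In
        [0.60, 0.25, 0.00, 0.10, 0.00],  # AD
        [0.80, 0.20, 0.00, 0.00, 0.00],  # MD
        [0.25, 0.45, 0.00, 0.00, 0.00],  # PD
        [0.00, 0.00, 0.00, 0.35, 0.20],  # PM
        [0.00, 0.85, 0.00, 0.15, 0.00],  # TLongH
        [0.00, 0.85, 0.00, 0.00, 0.00],  # TLatH
        [0.30, 0.00, 0.00, 0.00, 0.70],  # BLongH
        [0.00, 0.00, 0.10, 0.00, 0.85],  # BShH
        [0.00, 0.00, 0.85, 0.00, 0.20],  # Br
        [0.00, 0.20, 0.80, 0.00, 0.15],  # FlexCR
        [0.00, 0.25, 0.75, 0.00, 0.00],  # ExCR
    ]
)

#: Activation-bump centers as fractions of the padded epoch, in the observed
#: recruitment order: initiation (S5) first, then arm raise (S1), then wrist
#: handling (S3) followed by stabilization (S4), final push (S2) last.
#: Centers are spread enough that the temporal profiles overlap only
#: moderately, keeping the factorization well-posed.
_BUMP_CENTERS = {0: 0.35, 1: 0.85, 2: 0.52, 3: 0.68, 4: 0.15}
#: Bump SD per synergy (fraction of the epoch); the wrist/ball-handling
#: synergy stays active longer than the burst-like phases around it.
_BUMP_WIDTHS = {0: 0.05, 1: 0.05, 2: 0.09, 3: 0.05, 4: 0.05}
_DEFAULT_BUMP_WIDTH = 0.05
#: SD of the per-repetition jitter on bump centers (fraction of the epoch) —
#: the timing variability between repetitions of the same set.
_CENTER_JITTER = 0.03

#: Sets in which the final-push synergy is barely recruited (the arms do not
#: reach full extension): quick middle-blocker sets and the 'two' set.
_LOW_PUSH_SETS = ("quick", "seven", "fast", "two")


@dataclass
class SimConfig:
    """Simulation conditions for one session.

    ``snr_db`` is the power ratio of the amplitude-modulated EMG carrier to
    additive sensor noise, in dB (``inf`` disables sensor noise).
    ``within_rep_noise_deg`` is the SD of the smooth angular variability
    added per repetition; ``session_offset_deg`` shifts all joint angles by
    a constant, emulating sensor re-placement between sessions.
    """

    seed: int = 0
    snr_db: float = 20.0
    n_reps: int = 10
    n_set_types: int = 9
    s_true: int = 5
    session_offset_deg: float = 0.0
    within_rep_noise_deg: float = 2.0
    rep_gain_sd: float = 0.4
    include_emg: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ParameterError("n_reps must be >= 1")
        if not 1 <= self.n_set_types <= len(SET_TYPES):
            raise ParameterError(f"n_set_types must be in 1..{len(SET_TYPES)}")
        if not 1 <= self.s_true <= len(MUSCLES):
            raise ParameterError(f"s_true must be in 1..{len(MUSCLES)}")
        if np.isnan(self.snr_db):
            raise ParameterError("snr_db must be a number or inf")
        if self.rep_gain_sd < 0:
            raise ParameterError("rep_gain_sd must be >= 0")


@dataclass
class GroundTruth:
    """Known generative state shared by the sessions of a retest pair."""

    W_true: np.ndarray  # 16 x S, unit-norm columns
    C_true: dict[tuple[str, int], np.ndarray]  # (set, rep) -> S x T
    manifest: TaskManifest
    event_times: tuple[tuple[float, float], ...]  # (onset_s, offset_s) per entry
    set_templates: dict[str, np.ndarray]  # set -> 6 x L angle template (deg)
    epoch_samples: int
    pad_s: float

    def events_by_entry(self) -> dict[tuple[str, int], tuple[float, float]]:
        return dict(zip(self.manifest.entries, self.event_times))

    def spatial_in_normalized_units(self) -> np.ndarray:
        """W_true re-expressed in the pipeline's per-muscle-max units.

        The analysis normalizes each muscle's envelope by its maximum over
        all trials, which rescales muscle m of every spatial vector by
        1 / max_m. Applying the same rescaling to the true envelopes (and
        renormalizing columns) gives the spatial vectors the pipeline should
        recover, making like-for-like cosine comparison possible.
        """
        scale = np.zeros(self.W_true.shape[0])
        for act in self.C_true.values():
            env = self.W_true @ act
            scale = np.maximum(scale, env.max(axis=1))
        scale[scale == 0] = 1.0
        W = self.W_true / scale[:, None]
        norms = np.linalg.norm(W, axis=0)
        norms[norms == 0] = 1.0
        return W / norms


@dataclass
class SyntheticSession:
    """One simulated recording session plus its ground-truth bookkeeping."""

    kinematics: TimeSeries
    emg: TimeSeries | None
    manifest: TaskManifest
    event_times: tuple[tuple[float, float], ...]


def _raised_cosine_bump(n: int) -> np.ndarray:
    """Smooth 0 -> 1 -> 0 bump over n samples (zero-slope endpoints)."""
    u = np.linspace(0.0, 1.0, n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _make_templates(rng: np.random.Generator, set_types) -> dict[str, np.ndarray]:
    """Per-set 6-DOF angle excursion templates (degrees above baseline)."""
    templates: dict[str, np.ndarray] = {}
    for set_type in set_types:
        n = int(round(SET_DURATIONS_S[set_type] * KIN_RATE_HZ))
        bump = _raised_cosine_bump(n)
        peaks = np.asarray(_SET_PEAKS[set_type]) - _BASELINE_DEG
        templates[set_type] = peaks[:, None] * bump[None, :]
    return templates


def generate_ground_truth(config: SimConfig) -> GroundTruth:
    """Draw the generative state for a (pair of) session(s).

    Deterministic for a given seed: spatial vectors are the sparse base
    patterns with mild multiplicative jitter (unit-norm columns), activation
    bumps are truncated Gaussians with per-set amplitude modulation and
    per-repetition center jitter, and the repetition order is a seeded
    shuffle of all (set type, repetition) pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6774]))
    s = config.s_true
    n_base = _BASE_PATTERNS.shape[1]
    if s <= n_base:
        W = _BASE_PATTERNS[:, :s].copy()
    else:
        extra = np.zeros((len(MUSCLES), s - n_base))
        for j in range(s - n_base):
            idx = rng.choice(len(MUSCLES), size=4, replace=False)
            extra[idx, j] = rng.uniform(0.4, 1.0, size=4)
        W = np.hstack([_BASE_PATTERNS, extra])
    W = W * (1.0 + 0.05 * rng.standard_normal(W.shape))
    W = np.clip(W, 0.0, None)
    W /= np.linalg.norm(W, axis=0, keepdims=True)

    set_types = SET_TYPES[: config.n_set_types]
    entries = [
        (set_type, rep)
        for set_type in set_types
        for rep in range(1, config.n_reps + 1)
    ]
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]
    manifest = TaskManifest(tuple(entries), session_id=f"sim-{config.seed}")

    # per-(synergy, set) amplitude modulation, frozen in the truth
    amp = 1.0 + 0.2 * rng.standard_normal((s, len(set_types)))
    amp = np.clip(amp, 0.3, None)
    for k, set_type in enumerate(set_types):
        if s > 1 and set_type in _LOW_PUSH_SETS:
            amp[1, k] = 0.15  # final-push synergy barely recruited

    t_samples = 100
    u = np.linspace(0.0, 1.0, t_samples)
    base_centers = {
        i: _BUMP_CENTERS.get(i, float(rng.uniform(0.25, 0.75))) for i in range(s)
    }
    c_true: dict[tuple[str, int], np.ndarray] = {}
    for k, set_type in enumerate(set_types):
        for rep in range(1, config.n_reps + 1):
            act = np.zeros((s, t_samples))
            for i in range(s):
                center = base_centers[i] + rng.normal(0.0, _CENTER_JITTER)
                width = _BUMP_WIDTHS.get(i, _DEFAULT_BUMP_WIDTH)
                a = amp[i, k] * (1.0 + 0.10 * rng.standard_normal())
                act[i] = a * np.exp(-0.5 * ((u - center) / width) ** 2)
            c_true[(set_type, rep)] = np.clip(act, 0.0, None)
    # Equalize each synergy's share of the signal power as seen by the
    # analysis, i.e. after the per-muscle max normalization the pipeline
    # applies. Each synergy drives a distinct movement phase and should
    # carry a comparable share of the observed EMG variance; without this
    # the normalization re-weights muscles and leaves shares uneven. A
    # short fixed-point iteration suffices (the scale of each muscle row
    # depends only weakly on the per-synergy gains).
    keys = list(c_true)
    for _ in range(8):
        cat = np.hstack([c_true[key] for key in keys])
        env = W @ cat
        scale = env.max(axis=1)
        scale[scale == 0] = 1.0
        w_eff = W / scale[:, None]
        power = (w_eff**2).sum(axis=0) * (cat**2).sum(axis=1)
        power[power == 0] = 1.0
        gain = np.sqrt(power.mean() / power)
        for key in keys:
            c_true[key] = c_true[key] * gain[:, None]

    templates = _make_templates(rng, set_types)
    event_times: list[tuple[float, float]] = []
    t = LEAD_IN_S
    for set_type, _rep in entries:
        dur = SET_DURATIONS_S[set_type]
        event_times.append((t, t + dur))
        t += dur + REST_S
    return GroundTruth(
        W_true=W,
        C_true=c_true,
        manifest=manifest,
        event_times=tuple(event_times),
        set_templates=templates,
        epoch_samples=t_samples,
        pad_s=0.25,
    )


def _angular_noise(
    rng: np.random.Generator,
    shape: tuple[int, int],
    window: np.ndarray,
    sd: float,
) -> np.ndarray:
    """Movement-windowed smooth Gaussian angular variability.

    Execution variability is concentrated in the movement itself: sensor-
    derived joint angles are essentially flat at rest, while the excursions
    vary smoothly from repetition to repetition. The noise is a 1 Hz
    band-limited Gaussian process scaled to SD ``sd`` (degrees) and
    multiplied by the normalized movement profile ``window`` (0 at rest,
    1 at peak excursion).
    """
    if sd == 0.0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = filter_array(white, KIN_RATE_HZ, "lowpass", 1.0, 4)
    std = smooth.std(axis=-1, keepdims=True)
    std[std == 0] = 1.0
    return sd * (smooth / std) * window[None, :]


def synthesize_session(truth: GroundTruth, config: SimConfig) -> SyntheticSession:
    """Render one session (kinematics + raw EMG) from the ground truth.

    Kinematics: templates on the shared event timeline, plus smooth angular
    noise per repetition and the constant session offset. EMG: the true
    envelope of each padded epoch, interpolated to 2000 Hz, modulates a
    band-limited unit-variance carrier; white sensor noise is added at
    ``config.snr_db``. Bitwise reproducible from the config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5e55]))
    last_offset = truth.event_times[-1][1]
    total_s = last_offset + REST_S
    n_kin = int(round(total_s * KIN_RATE_HZ))
    kin = np.tile(_BASELINE_DEG[:, None], (1, n_kin))
    window = np.zeros(n_kin)
    for (set_type, _rep), (onset, offset) in zip(
        truth.manifest.entries, truth.event_times
    ):
        tmpl = truth.set_templates[set_type]
        i0 = int(round(onset * KIN_RATE_HZ))
        i1 = i0 + tmpl.shape[1]
        kin[:, i0:i1] += tmpl
        window[i0:i1] = _raised_cosine_bump(tmpl.shape[1])
    kin += _angular_noise(
        rng, kin.shape, window, config.within_rep_noise_deg
    )
    kin += config.session_offset_deg
    kinematics = TimeSeries(kin, KIN_RATE_HZ, DOF_LABELS)

    emg = None
    if config.include_emg:
        n_emg = int(round(total_s * EMG_RATE_HZ))
        envelope = np.zeros((len(MUSCLES), n_emg))
        for (set_type, rep), (onset, offset) in zip(
            truth.manifest.entries, truth.event_times
        ):
            j0 = max(int(round((onset - truth.pad_s) * EMG_RATE_HZ)), 0)
            j1 = min(int(round((offset + truth.pad_s) * EMG_RATE_HZ)), n_emg)
            act = truth.C_true[(set_type, rep)]
            env = truth.W_true @ act  # 16 x T
            # trial-to-trial amplitude variability: surface-EMG amplitudes
            # fluctuate per muscle between repetitions (CV of the order of
            # rep_gain_sd) independently of the shared synergy drive
            gain = np.clip(
                1.0 + config.rep_gain_sd * rng.standard_normal(env.shape[0]),
                0.2, None,
            )
            envelope[:, j0:j1] += gain[:, None] * resample_rows(env, j1 - j0)
        carrier = rng.standard_normal(envelope.shape)
        carrier = filter_array(carrier, EMG_RATE_HZ, "highpass", 20.0, 4)
        carrier = filter_array(carrier, EMG_RATE_HZ, "lowpass", 450.0, 4)
        carrier /= carrier.std(axis=-1, keepdims=True)
        raw = envelope * carrier
        if np.isfinite(config.snr_db):
            # sensor noise is an amplifier-wide floor: the same SD on every
            # channel, set by the mean modulated-signal power across muscles
            p_signal = float(np.mean(raw**2))
            noise_sd = np.sqrt(p_signal / 10.0 ** (config.snr_db / 10.0))
            raw = raw + noise_sd * rng.standard_normal(raw.shape)
        emg = TimeSeries(raw, EMG_RATE_HZ, MUSCLES)
    return SyntheticSession(kinematics, emg, truth.manifest, truth.event_times)


def make_retest_pair(
    truth: GroundTruth, config1: SimConfig, config2: SimConfig
) -> tuple[SyntheticSession, SyntheticSession]:
    """Two independently noised sessions sharing one ground truth.

    The simulated analog of repeating the protocol a week later: the same
    movement templates and synergy model, fresh noise realizations (and
    possibly a constant angular offset) per session.
    """
    return synthesize_session(truth, config1), synthesize_session(truth, config2)
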