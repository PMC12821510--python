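"""Test-retest statistics: synergy matching, Pearson r, and ICC(3,k).

Two sessions of the same protocol, recorded a week apart, are compared on
three levels:

* spatial synergy structure — cosine similarity between optimally matched
  spatial vectors of the two sessions (bijective assignment maximizing the
  total similarity);
* synergy timing — Pearson correlation between the session-mean temporal
  activation curves of matched synergies, per set type;
* joint kinematics — Pearson correlation and ICC(3,k) between the
  session-mean joint-angle curves, per set type and degree of freedom.

ICC(3,k) is the two-way mixed-model intraclass correlation for consistency
of average measures (Shrout-Fleiss): targets are the resampled time samples
of the mean curve, raters are the two fixed sessions. Consistency is
interpreted on the conventional bands excellent (> 0.90), good
(0.75-0.90], moderate (0.50-0.75] and poor (<= 0.50).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .errors import ParameterError, StructuralError, UndefinedStatisticError
from .timeseries import resample_linear

__all__ = [
    "SynergyMatch",
    "IccResult",
    "RetestReport",
    "cosine_similarity",
    "match_synergies",
    "pearson",
    "icc_3k",
    "classify_consistency",
    "compare_sessions",
]

#: Common length every cross-session curve is resampled to before
#: correlation, so sessions of different durations are comparable.
COMMON_CURVE_SAMPLES = 100


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """cos(a, b) = a.b / (|a||b|); in [0, 1] for non-negative vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise StructuralError(f"length mismatch: {a.size} vs {b.size}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedStatisticError("cosine similarity undefined for zero vector")
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SynergyMatch:
    """Bijective pairing of session-1 to session-2 synergies.

    ``pairs[i] = j`` maps synergy i of session 1 to synergy j of session 2
    (0-based); ``similarities[i]`` is the cosine similarity of that pair.
    """

    pairs: tuple[int, ...]
    similarities: tuple[float, ...]

    def __post_init__(self) -> None:
        if sorted(self.pairs) != list(range(len(self.pairs))):
            raise StructuralError("pairing is not a bijection")


def match_synergies(W1: np.ndarray, W2: np.ndarray) -> SynergyMatch:
    """Optimal assignment between two spatial synergy sets.

    Solves the linear assignment problem maximizing the summed cosine
    similarity over all bijections (equivalent to exhaustive permutation
    search, but polynomial); ties resolve to the lowest indices.
    """
    W1 = np.atleast_2d(np.asarray(W1, dtype=float))
    W2 = np.atleast_2d(np.asarray(W2, dtype=float))
    if W1.shape != W2.shape:
        raise StructuralError(
            f"synergy sets differ in shape: {W1.shape} vs {W2.shape}"
        )
    s = W1.shape[1]
    sim = np.empty((s, s))
    for i in range(s):
        for j in range(s):
            sim[i, j] = cosine_similarity(W1[:, i], W2[:, j])
    rows, cols = linear_sum_assignment(-sim)
    pairs = tuple(int(c) for c in cols[np.argsort(rows)])
    sims = tuple(float(sim[i, j]) for i, j in enumerate(pairs))
    return SynergyMatch(pairs, sims)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value.

    The p-value comes from the exact t transform with n - 2 degrees of
    freedom. Constant inputs make the statistic undefined.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise StructuralError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ParameterError(f"need n >= 3, got {x.size}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedStatisticError("Pearson r undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class IccResult:
    """ICC(3,k) point estimate, 95 % CI and consistency band."""

    icc: float
    ci_low: float
    ci_high: float
    band: str

    def __post_init__(self) -> None:
        if not self.ci_low <= self.icc <= self.ci_high:
            raise StructuralError("CI does not bracket the ICC estimate")


def icc_3k(data: np.ndarray, confidence: float = 0.95) -> IccResult:
    """Two-way mixed consistency ICC of average measures, ICC(3,k).

    ``data`` is n targets x k raters. From the two-way ANOVA decomposition
    with BMS the between-target and EMS the residual mean square,
    ICC(3,k) = (BMS - EMS) / BMS. The CI follows Shrout-Fleiss: with
    F = BMS/EMS on (n-1) and (n-1)(k-1) degrees of freedom, the bounds are
    1 - 1/F_L and 1 - 1/F_U where F_L = F / F_crit and F_U = F * F_crit'.
    Consistency ignores additive rater offsets, so an offset copy of a
    column still yields ICC = 1.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise StructuralError("data must be a 2-D targets x raters matrix")
    n, k = X.shape
    if n < 3 or k < 2:
        raise ParameterError(f"need >= 3 targets and >= 2 raters, got {X.shape}")
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    bms = k * np.sum((row_means - grand) ** 2) / (n - 1)
    resid = X - row_means[:, None] - col_means[None, :] + grand
    ems = np.sum(resid**2) / ((n - 1) * (k - 1))
    if bms <= 0.0:
        raise UndefinedStatisticError(
            "zero between-target variance; ICC undefined"
        )
    icc = (bms - ems) / bms
    alpha = 1.0 - confidence
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ems <= 0.0:
        lo = hi = 1.0
    else:
        f_obs = bms / ems
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo, hi = 1.0 - 1.0 / f_l, 1.0 - 1.0 / f_u
    return IccResult(float(icc), float(lo), float(hi), classify_consistency(icc))


def classify_consistency(icc: float) -> str:
    """Map an ICC value to its conventional interpretation band."""
    if icc > 1.0:
        raise ParameterError(f"ICC cannot exceed 1, got {icc}")
    if icc > 0.90:
        return "excellent"
    if icc > 0.75:
        return "good"
    if icc > 0.50:
        return "moderate"
    return "poor"


@dataclass
class RetestReport:
    """Cross-session comparison tables.

    ``similarity`` — per matched synergy pair (S rows);
    ``temporal_r`` — Pearson r and p of session-mean activation curves, per
    set type x matched synergy (K x S);
    ``kinematic`` — Pearson r/p plus ICC(3,k), CI and band of session-mean
    joint-angle curves, per set type x DOF (K x D rows).
    """

    similarity: pd.DataFrame
    temporal_r: pd.DataFrame
    kinematic: pd.DataFrame
    match: SynergyMatch

    def to_dict(self) -> dict:
        return {
            "similarity": self.similarity.to_dict(orient="records"),
            "temporal_r": self.temporal_r.to_dict(orient="records"),
            "kinematic": self.kinematic.to_dict(orient="records"),
            "match": list(self.match.pairs),
        }


def _common(curve: np.ndarray) -> np.ndarray:
    return resample_linear(curve, COMMON_CURVE_SAMPLES)


def compare_sessions(session1, session2) -> RetestReport:
    """Full test-retest comparison of two analyzed sessions.

    Sessions are any objects exposing ``synergy_model`` (a
    :class:`~synkin.synergy.SynergyModel`), ``mean_coefficients`` (mapping
    set type -> S x T session-mean activation curves) and ``profiles``
    (mapping set type -> :class:`~synkin.kinematics.MeanProfile`), analyzed
    with identical configuration — e.g. the bundles produced by
    :func:`synkin.pipeline.run_pipeline`. Curves are resampled to a common
    length before correlating, since sessions may differ in duration.
    """
    m1, m2 = session1.synergy_model, session2.synergy_model
    if m1.order != m2.order:
        raise StructuralError(
            f"synergy orders differ ({m1.order} vs {m2.order}); re-run both "
            "sessions at a common fixed order before comparing"
        )
    match = match_synergies(m1.W, m2.W)
    similarity = pd.DataFrame(
        {
            "synergy_session1": np.arange(1, m1.order + 1),
            "synergy_session2": np.asarray(match.pairs) + 1,
            "cosine_similarity": match.similarities,
        }
    )

    set_types = list(session1.mean_coefficients)
    if set_types != list(session2.mean_coefficients):
        missing = set(set_types) ^ set(session2.mean_coefficients)
        raise StructuralError(f"sessions disagree on set types: {sorted(missing)}")
    temporal_rows = []
    for set_type in set_types:
        c1 = np.atleast_2d(session1.mean_coefficients[set_type])
        c2 = np.atleast_2d(session2.mean_coefficients[set_type])
        for i, j in enumerate(match.pairs):
            r, p = pearson(_common(c1[i]), _common(c2[j]))
            temporal_rows.append(
                {"set_type": set_type, "synergy": i + 1, "r": r, "p": p}
            )
    temporal_r = pd.DataFrame(temporal_rows)

    kin_rows = []
    prof_types = list(session1.profiles)
    if prof_types != list(session2.profiles):
        missing = set(prof_types) ^ set(session2.profiles)
        raise StructuralError(f"sessions disagree on set types: {sorted(missing)}")
    for set_type in prof_types:
        p1, p2 = session1.profiles[set_type], session2.profiles[set_type]
        if p1.labels != p2.labels:
            raise StructuralError(f"DOF labels differ for set {set_type!r}")
        for d, dof in enumerate(p1.labels):
            x = _common(p1.mean[d])
            y = _common(p2.mean[d])
            r, p = pearson(x, y)
            icc = icc_3k(np.column_stack([x, y]))
            kin_rows.append(
                {
                    "set_type": set_type,
                    "dof": dof,
                    "r": r,
                    "p": p,
                    "icc": icc.icc,
                    "ci_low": icc.ci_low,
                    "ci_high": icc.ci_high,
                    "band": icc.band,
                }
            )
    kinematic = pd.DataFrame(kin_rows)
    return RetestReport(similarity, temporal_r, kinematic, match)
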