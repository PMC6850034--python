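"""Preprocessing: missing-weight imputation, outlier trimming, feature
construction and z-score normalization.

The imputation rule uses the patient's average weight draft delta — the mean
discrepancy ``pre - post - uf/1000`` over complete sessions — which captures
end-of-session saline return and intradialytic excretion.  A session missing
its pre-dialysis weight is filled as ``post + uf/1000 + delta``; a missing
post-dialysis weight by the algebraic inversion ``pre - uf/1000 - delta``.
Sessions missing both weights are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .ehr_io import PatientSeries
from .errors import DataError

__all__ = [
    "ImputationStats",
    "FeatureVector",
    "NormStats",
    "compute_delta",
    "impute_missing",
    "imputation_residual",
    "trim_outliers",
    "build_features",
    "fit_norm",
    "apply_norm",
]

#: Columns with standard deviation below this are treated as constant and
#: normalize to zero.
DEGENERATE_STD = 1e-12


@dataclass(frozen=True)
class ImputationStats:
    """Average weight draft and the number of complete sessions behind it."""

    delta: float  # kg
    m: int

    def __post_init__(self) -> None:
        if self.m < 1 or not math.isfinite(self.delta):
            raise DataError(f"unusable imputation stats (delta={self.delta}, m={self.m})")


@dataclass(frozen=True)
class FeatureVector:
    """The 3k+1 predictors for one target session.

    Histories are ordered most-recent-first: position 0 is the session
    immediately before the target.
    """

    w0_pre: float
    pre_hist: tuple[float, ...]
    post_hist: tuple[float, ...]
    uf_hist: tuple[float, ...]
    target_index: int

    @property
    def k(self) -> int:
        return len(self.pre_hist)

    def to_array(self) -> np.ndarray:
        """Flatten to length 3k+1: [w0_pre, pre_hist, post_hist, uf_hist]."""
        return np.concatenate(
            ([self.w0_pre], self.pre_hist, self.post_hist, self.uf_hist)
        )

    def __len__(self) -> int:
        return 3 * self.k + 1


@dataclass(frozen=True)
class NormStats:
    """Per-feature mean and (population) standard deviation."""

    mean: np.ndarray
    std: np.ndarray


def compute_delta(series: PatientSeries) -> ImputationStats:
    """Average weight draft over the complete sessions of ``series``.

    delta = mean(pre - post - uf/1000); requires at least one complete session.
    """
    drafts = [
        s.pre_weight - s.post_weight - s.uf_volume / 1000.0
        for s in series.sessions
        if s.is_complete
    ]
    if not drafts:
        raise DataError(
            f"patient {series.patient_id!r}: no complete session, imputation impossible"
        )
    return ImputationStats(delta=float(np.mean(drafts)), m=len(drafts))


def impute_missing(series: PatientSeries, stats: ImputationStats) -> PatientSeries:
    """Fill single-missing weights from ``stats``; drop both-missing sessions.

    The result contains only complete sessions, reindexed from 0.
    """
    kept = []
    for s in series.sessions:
        if s.pre_weight is None and s.post_weight is None:
            continue
        if s.pre_weight is None:
            s = replace(s, pre_weight=s.post_weight + s.uf_volume / 1000.0 + stats.delta)
        elif s.post_weight is None:
            s = replace(s, post_weight=s.pre_weight - s.uf_volume / 1000.0 - stats.delta)
        kept.append(s)
    return series.replace_sessions(kept)


def imputation_residual(session, stats: ImputationStats) -> float:
    """Residual of the imputation relation, pre - post - uf/1000 - delta.

    Evaluated under both algebraically equivalent groupings (the one used to
    fill a missing pre-weight and the one used to fill a missing post-weight)
    and the smaller-magnitude value is returned, so the residual is exactly
    0.0 on any session either weight was imputed into.
    """
    u = session.uf_volume / 1000.0
    forward = session.pre_weight - (session.post_weight + u + stats.delta)
    inverse = session.pre_weight - u - stats.delta - session.post_weight
    return forward if abs(forward) <= abs(inverse) else inverse


def trim_outliers(series: PatientSeries, rate: float = 0.10) -> PatientSeries:
    """Drop the floor(rate*m) largest and smallest pre-post weight differences.

    Survivors keep their original temporal order; ties are broken by temporal
    order (stable sort).  Intended for training sets only.
    """
    if not (0.0 <= rate < 0.5):
        raise DataError(f"trim rate {rate} outside [0, 0.5)")
    if any(not s.is_complete for s in series.sessions):
        raise DataError("trim_outliers requires a complete (imputed) series")
    m = len(series.sessions)
    c = int(math.floor(rate * m))
    if c == 0:
        return series.replace_sessions(list(series.sessions))
    order = sorted(range(m), key=lambda i: series.sessions[i].pre_weight - series.sessions[i].post_weight)
    dropped = set(order[:c]) | set(order[-c:])
    kept = [s for i, s in enumerate(series.sessions) if i not in dropped]
    return series.replace_sessions(kept)


def build_features(series: PatientSeries, k: int, t: int) -> FeatureVector:
    """Feature vector for target session ``t`` (position in the series).

    w0_pre is the target's own pre-dialysis weight; the three histories are
    the k sessions immediately before it, most recent first.
    """
    if k < 1:
        raise DataError(f"history depth k={k} must be >= 1")
    if t < k:
        raise DataError(f"target index {t} has fewer than k={k} prior sessions")
    if t >= len(series.sessions):
        raise DataError(f"target index {t} out of range for series of length {len(series)}")
    window = series.sessions[t - k : t][::-1]  # most recent first
    target = series.sessions[t]
    if target.pre_weight is None or any(not s.is_complete for s in window):
        raise DataError("build_features requires complete sessions in the window")
    return FeatureVector(
        w0_pre=target.pre_weight,
        pre_hist=tuple(s.pre_weight for s in window),
        post_hist=tuple(s.post_weight for s in window),
        uf_hist=tuple(s.uf_volume for s in window),
        target_index=t,
    )


def fit_norm(feature_matrix: np.ndarray) -> NormStats:
    """Column means and population standard deviations of a training matrix."""
    X = np.asarray(feature_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("fit_norm requires a 2-D matrix with at least 2 rows")
    return NormStats(mean=X.mean(axis=0), std=X.std(axis=0))


def apply_norm(x: np.ndarray, stats: NormStats) -> np.ndarray:
    """Z-score ``x`` (vector or matrix) with training statistics.

    Degenerate columns (std < 1e-12) map to exactly 0.
    """
    x = np.asarray(x, dtype=float)
    safe = np.where(stats.std < DEGENERATE_STD, 1.0, stats.std)
    z = (x - stats.mean) / safe
    return np.where(stats.std < DEGENERATE_STD, 0.0, z)
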