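"""Synthetic hemodialysis cohort generator.

Generates per-patient session series with the structure the estimator
assumes: a slowly varying dry weight (drift + random walk, optionally with
regime shocks), interdialytic weight gain, prescribed ultrafiltration that
brings the patient to the current dry weight, end-of-session saline return
(so UF typically exceeds the observed weight loss), measurement noise on the
post-dialysis weight, and optional missing-weight injection.

Three presets mimic clinical groups of increasing instability:
``stabilized`` < ``intolerant`` < ``near_death`` in noise, shocks and drift.
All randomness flows through :class:`numpy.random.Generator` (PCG64) seeded
from the config, so output is fully deterministic across platforms.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace

import numpy as np

from .ehr_io import GROUPS, HDSession, PatientSeries
from .errors import DataError

__all__ = [
    "SimulationConfig",
    "GROUP_PRESETS",
    "simulate_patient",
    "simulate_cohort",
    "inject_missing",
    "simulate_ema_noise_patient",
]

#: Mon/Wed/Fri session calendar (2-3 sessions a week).
_WEEK_OFFSETS = (0, 2, 4)
_START_DATE = _dt.date(2024, 1, 1)  # a Monday


def session_dates(n_sessions: int, start: _dt.date = _START_DATE):
    """Dates on a repeating Mon/Wed/Fri pattern starting at ``start``."""
    return [
        start + _dt.timedelta(days=7 * (i // 3) + _WEEK_OFFSETS[i % 3])
        for i in range(n_sessions)
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one simulated patient."""

    group: str = "stabilized"
    n_sessions: int = 150
    dw0: float = 60.0  # initial dry weight, kg
    dw_drift: float = 0.0  # kg per session
    dw_rw_sd: float = 0.02  # dry-weight random-walk step, kg
    gain_mean: float = 2.5  # interdialytic weight gain, kg
    gain_sd: float = 0.5
    saline_mean: float = 0.2  # end-of-session fluid return, kg
    saline_sd: float = 0.1
    post_noise_sd: float = 0.15
    shock_prob: float = 0.0
    shock_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise DataError("n_sessions must be >= 1")
        for name in ("dw_rw_sd", "gain_sd", "saline_sd", "post_noise_sd", "shock_sd"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be nonnegative")
        for name in ("shock_prob", "missing_rate"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise DataError(f"{name} must be in [0, 1]")
        if self.group not in GROUPS:
            raise DataError(f"unknown group {self.group!r}")


#: Per-group overrides applied on top of SimulationConfig defaults.
GROUP_PRESETS: dict[str, dict] = {
    "stabilized": {"dw_drift": 0.0, "dw_rw_sd": 0.02, "post_noise_sd": 0.15, "shock_prob": 0.0},
    "intolerant": {"dw_drift": 0.0, "dw_rw_sd": 0.04, "post_noise_sd": 0.30, "shock_prob": 0.05},
    "near_death": {"dw_drift": -0.03, "dw_rw_sd": 0.06, "post_noise_sd": 0.45, "shock_prob": 0.15},
}

# dry weight is clipped inside the validation bounds so extreme random walks
# cannot produce out-of-range session weights
_DW_CLIP = (25.0, 190.0)


def simulate_patient(config: SimulationConfig, patient_id: str = "sim") -> PatientSeries:
    """Generate one patient's session series from ``config``.

    Per session: the dry weight takes a drift + random-walk (+ optional
    shock) step; the patient arrives at the previous post-weight plus a
    truncated-normal gain; UF is prescribed to reach the dry weight; the
    post-weight is the pre-weight minus UF plus saline return plus noise.
    """
    rng = np.random.default_rng(config.seed)
    dates = session_dates(config.n_sessions)
    dw = config.dw0
    post_prev = config.dw0
    sessions = []
    for t in range(config.n_sessions):
        dw = dw + config.dw_drift + rng.normal(0.0, config.dw_rw_sd)
        if config.shock_prob > 0 and rng.random() < config.shock_prob:
            dw += rng.normal(0.0, config.shock_sd)
        dw = float(np.clip(dw, *_DW_CLIP))
        gain = max(0.0, rng.normal(config.gain_mean, config.gain_sd))
        pre = post_prev + gain
        uf = max(0.0, (pre - dw)) * 1000.0
        saline = max(0.0, rng.normal(config.saline_mean, config.saline_sd))
        post = pre - uf / 1000.0 + saline + rng.normal(0.0, config.post_noise_sd)
        sessions.append(
            HDSession(
                patient_id=patient_id,
                date=dates[t],
                pre_weight=pre,
                post_weight=post,
                uf_volume=uf,
                session_index=t,
            )
        )
        post_prev = post
    series = PatientSeries(patient_id, sessions, config.group)
    if config.missing_rate > 0:
        # separate stream so the weight trajectory is unchanged by masking
        series = inject_missing(series, config.missing_rate, seed=config.seed + 1)
    return series


def simulate_cohort(
    group: str,
    n_patients: int,
    n_sessions: int = 150,
    seed: int = 0,
    missing_rate: float = 0.0,
    **overrides,
) -> list[PatientSeries]:
    """Generate a cohort from a group preset with per-patient sub-seeds.

    Sub-seeds are derived from ``(seed, group index, patient index)`` via
    :class:`numpy.random.SeedSequence`, so different groups and patients
    never share a random stream.
    """
    if group not in GROUP_PRESETS:
        raise DataError(f"unknown group {group!r}; expected one of {sorted(GROUP_PRESETS)}")
    params = dict(GROUP_PRESETS[group])
    params.update(overrides)
    base = np.random.SeedSequence([seed, GROUPS.index(group)])
    children = base.spawn(n_patients)
    cohort = []
    for i, child in enumerate(children):
        config = SimulationConfig(
            group=group,
            n_sessions=n_sessions,
            missing_rate=missing_rate,
            seed=int(child.generate_state(1)[0]),
            **params,
        )
        cohort.append(simulate_patient(config, patient_id=f"{group}_{i:03d}"))
    return cohort


def inject_missing(series: PatientSeries, rate: float, seed: int = 0) -> PatientSeries:
    """Independently blank the pre- OR post-weight of each session with
    probability ``rate`` (fair coin picks which); never both."""
    if not (0.0 <= rate < 1.0):
        raise DataError(f"missing rate {rate} outside [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for s in series.sessions:
        if rng.random() < rate:
            if rng.random() < 0.5:
                s = replace(s, pre_weight=None)
            else:
                s = replace(s, post_weight=None)
        out.append(s)
    return PatientSeries(series.patient_id, out, series.group)


def simulate_ema_noise_patient(
    n_sessions: int,
    sigma: float,
    seed: int = 0,
    n: int = 5,
    ema_mode: str = "normalized",
    base_weight: float = 60.0,
    gain: float = 2.5,
    patient_id: str = "ema_noise",
) -> PatientSeries:
    """Patient whose detrended post-weight is pure Gaussian noise.

    Each post-weight is the EMA of the n prior post-weights plus
    Normal(0, sigma) noise, so the detrended target is exactly the noise
    term and the irreducible rolling MAE is sigma * sqrt(2/pi).  Gain and
    UF are deterministic.  Used as a calibration test bed.
    """
    from .emd_model import ema_weights

    rng = np.random.default_rng(seed)
    w = ema_weights(n, ema_mode)
    posts = [base_weight + rng.normal(0.0, sigma) for _ in range(n)]
    for t in range(n, n_sessions):
        window = posts[t - n : t][::-1]
        posts.append(float(w.alphas @ window) + rng.normal(0.0, sigma))
    dates = session_dates(n_sessions)
    sessions = []
    post_prev = base_weight
    for t in range(n_sessions):
        pre = post_prev + gain
        uf = max(0.0, (pre - posts[t])) * 1000.0
        sessions.append(
            HDSession(patient_id, dates[t], pre, posts[t], uf, session_index=t)
        )
        post_prev = posts[t]
    return PatientSeries(patient_id, sessions, "stabilized")
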