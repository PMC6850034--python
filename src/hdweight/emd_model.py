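"""Two-stage post-dialysis weight estimator.

The post-dialysis weight series is detrended with an exponential moving
average (EMA) of the n most recent prior post-dialysis weights; the residual
series (EMD: post minus EMA) is stationary and is what gets modeled.  The
EMD estimate is the sum of a global linear baseline on normalized features
and a Gaussian-kernel locally weighted correction fitted lazily at each
query.  The predicted post-dialysis weight is EMA + estimated EMD.

Two EMA weighting modes are provided:

* ``normalized`` (default): alpha_i proportional to rho^i with sum exactly 1,
  where rho = (n-1)/(n+1) — a proper weighted average.
* ``literal``: alpha_1 = rho and alpha_i = rho^i / (1 + S) for i > 1 with
  S = sum_{j=1..n} rho^j; retained for fidelity although the weights do not
  sum to 1.

Two kernel modes for the local correction:

* ``sample_weight`` (default): training row j receives weight
  exp(-||x_j - x||^2 / (2 tau^2)) in a weighted least-squares fit of the
  baseline residuals.
* ``elementwise``: each normalized training feature value is scaled by its
  own per-feature Gaussian kernel before an unweighted fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .ehr_io import PatientSeries
from .errors import DataError
from .preprocess import (
    NormStats,
    apply_norm,
    build_features,
    compute_delta,
    fit_norm,
    impute_missing,
    trim_outliers,
    FeatureVector,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EMAWeights",
    "ModelState",
    "PredictionResult",
    "EvalConfig",
    "ema_weights",
    "ema",
    "emd_series",
    "fit",
    "predict_emd",
    "predict_post",
    "rolling_evaluate",
    "k_sweep",
]

EMA_MODES = ("normalized", "literal")
KERNEL_MODES = ("sample_weight", "elementwise")


@dataclass(frozen=True)
class EMAWeights:
    """Time-decay weight factors; position 0 of ``alphas`` is the most recent."""

    n: int
    rho: float
    alphas: np.ndarray
    mode: str


def ema_weights(n: int, mode: str = "normalized") -> EMAWeights:
    """Decay weights over an n-step window; rho = (n-1)/(n+1)."""
    if n < 2:
        raise DataError(f"EMA window n={n} gives a degenerate decay (need n >= 2)")
    if mode not in EMA_MODES:
        raise DataError(f"unknown EMA mode {mode!r}")
    rho = (n - 1) / (n + 1)
    powers = rho ** np.arange(1, n + 1)
    if mode == "normalized":
        alphas = powers / powers.sum()
    else:
        s = powers.sum()
        alphas = powers / (1.0 + s)
        alphas[0] = rho
    return EMAWeights(n=n, rho=rho, alphas=alphas, mode=mode)


def ema(values, weights: EMAWeights) -> float:
    """Weighted sum of a recent-first value window."""
    values = np.asarray(values, dtype=float)
    if values.shape != (weights.n,):
        raise DataError(
            f"EMA window length {values.shape} does not match n={weights.n}"
        )
    return float(weights.alphas @ values)


def emd_series(
    series: PatientSeries, n: int = 5, mode: str = "normalized"
) -> list[tuple[int, float, float]]:
    """(index, ema_value, emd) for every session with n strictly prior sessions.

    emd_t = post_t - EMA(post_{t-1}, ..., post_{t-n}); the target's own
    post-weight never enters its EMA.
    """
    if any(not s.is_complete for s in series.sessions):
        raise DataError("emd_series requires a complete (imputed) series")
    if len(series.sessions) <= n:
        raise DataError(f"series of length {len(series)} too short for n={n}")
    w = ema_weights(n, mode)
    posts = np.array([s.post_weight for s in series.sessions])
    out = []
    for t in range(n, len(posts)):
        window = posts[t - n : t][::-1]
        ema_val = float(w.alphas @ window)
        out.append((t, ema_val, float(posts[t] - ema_val)))
    return out


@dataclass
class ModelState:
    """Fitted artifacts for one patient's estimator."""

    k: int
    n: int
    tau: float
    ema_mode: str
    kernel_mode: str
    norm_stats: NormStats
    base_coefs: np.ndarray  # 3k+1 slopes followed by the intercept
    training_features: np.ndarray  # normalized, retained for local correction
    training_emd: np.ndarray
    training_residuals: np.ndarray = field(default=None)  # type: ignore[assignment]
    _kernel_warned: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        p = self.training_features.shape[1]
        if self.base_coefs.shape != (p + 1,):
            raise DataError("base_coefs length must be feature count + 1")
        if self.training_residuals is None:
            design = np.column_stack(
                [self.training_features, np.ones(len(self.training_emd))]
            )
            self.training_residuals = self.training_emd - design @ self.base_coefs

    @property
    def n_features(self) -> int:
        return self.training_features.shape[1]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "tau": self.tau,
            "ema_mode": self.ema_mode,
            "kernel_mode": self.kernel_mode,
            "norm_mean": self.norm_stats.mean.tolist(),
            "norm_std": self.norm_stats.std.tolist(),
            "base_coefs": self.base_coefs.tolist(),
            "training_features": self.training_features.tolist(),
            "training_emd": self.training_emd.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelState":
        return cls(
            k=int(d["k"]),
            n=int(d["n"]),
            tau=float(d["tau"]),
            ema_mode=d["ema_mode"],
            kernel_mode=d["kernel_mode"],
            norm_stats=NormStats(
                mean=np.asarray(d["norm_mean"], dtype=float),
                std=np.asarray(d["norm_std"], dtype=float),
            ),
            base_coefs=np.asarray(d["base_coefs"], dtype=float),
            training_features=np.asarray(d["training_features"], dtype=float),
            training_emd=np.asarray(d["training_emd"], dtype=float),
        )


@dataclass
class PredictionResult:
    """One rolling-origin prediction with its error decomposition."""

    target_index: int
    ema_value: float
    emd_base: float
    emd_delta: float
    emd_pred: float
    post_pred: float
    post_actual: float | None = None
    abs_error: float | None = None
    rel_error: float | None = None


def fit(
    series: PatientSeries,
    k: int = 5,
    n: int = 5,
    tau: float = 1.0,
    ema_mode: str = "normalized",
    kernel_mode: str = "sample_weight",
) -> ModelState:
    """Fit the baseline regression and retain the training set for lazy
    local correction.

    ``series`` must be complete (imputed, and typically outlier-trimmed).
    Requires at least 3k+2 usable (feature, target) pairs.  Rank-deficient
    designs are solved by minimum-norm least squares with a logged warning.
    """
    if kernel_mode not in KERNEL_MODES:
        raise DataError(f"unknown kernel mode {kernel_mode!r}")
    if any(not s.is_complete for s in series.sessions):
        raise DataError("fit requires a complete (imputed) series")
    start = max(k, n)
    p = 3 * k + 1
    targets = range(start, len(series.sessions))
    if len(targets) < p + 1:
        raise DataError(
            f"only {len(targets)} training pairs for {p} features; need >= {p + 1}"
        )
    w = ema_weights(n, ema_mode)
    posts = np.array([s.post_weight for s in series.sessions])
    X = np.array([build_features(series, k, t).to_array() for t in targets])
    y = np.array(
        [posts[t] - float(w.alphas @ posts[t - n : t][::-1]) for t in targets]
    )
    norm_stats = fit_norm(X)
    Xn = apply_norm(X, norm_stats)
    design = np.column_stack([Xn, np.ones(len(y))])
    coefs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p + 1:
        logger.warning(
            "rank-deficient design (rank %d of %d); minimum-norm solution used",
            rank,
            p + 1,
        )
    return ModelState(
        k=k,
        n=n,
        tau=tau,
        ema_mode=ema_mode,
        kernel_mode=kernel_mode,
        norm_stats=norm_stats,
        base_coefs=coefs,
        training_features=Xn,
        training_emd=y,
    )


def predict_emd(state: ModelState, x) -> tuple[float, float, float]:
    """(emd_base, emd_delta, emd_pred) for one feature vector.

    The local correction models the baseline's residuals so that the
    tau -> infinity limit coincides with a single global least-squares fit.
    A kernel whose effective sample size falls below feature count + 1
    contributes no correction (logged warning).
    """
    if isinstance(x, FeatureVector):
        x = x.to_array()
    x = np.asarray(x, dtype=float)
    if x.shape != (state.n_features,) or not np.all(np.isfinite(x)):
        raise DataError("feature vector has wrong length or non-finite entries")
    xn = apply_norm(x, state.norm_stats)
    base = float(state.base_coefs[:-1] @ xn + state.base_coefs[-1])

    Xn = state.training_features
    r = state.training_residuals
    p = state.n_features
    ones = np.ones(len(r))
    if state.kernel_mode == "sample_weight":
        d2 = np.sum((Xn - xn) ** 2, axis=1)
        wts = np.exp(-d2 / (2.0 * state.tau**2))
        if wts.sum() < p + 1:
            # warn once per fitted state, then demote to debug
            log = logger.debug if state._kernel_warned else logger.warning
            state._kernel_warned = True
            log(
                "degenerate kernel at query (effective sample size %.3g < %d); "
                "local correction skipped",
                wts.sum(),
                p + 1,
            )
            delta = 0.0
        else:
            sw = np.sqrt(wts)
            A = np.column_stack([Xn, ones]) * sw[:, None]
            g, *_ = np.linalg.lstsq(A, r * sw, rcond=None)
            delta = float(g[:-1] @ xn + g[-1])
    else:  # elementwise
        scaled = Xn * np.exp(-((Xn - xn) ** 2) / (2.0 * state.tau**2))
        A = np.column_stack([scaled, ones])
        g, *_ = np.linalg.lstsq(A, r, rcond=None)
        delta = float(g[:-1] @ xn + g[-1])
    return base, delta, base + delta


def predict_post(state: ModelState, series: PatientSeries, t: int) -> PredictionResult:
    """Predict the post-dialysis weight of session ``t``.

    post_pred = EMA(prior n post-weights) + predicted EMD, exactly.
    """
    if t < max(state.k, state.n):
        raise DataError(
            f"target {t} lacks history (need {max(state.k, state.n)} prior sessions)"
        )
    x = build_features(series, state.k, t)
    w = ema_weights(state.n, state.ema_mode)
    window = [s.post_weight for s in series.sessions[t - state.n : t]][::-1]
    if any(v is None for v in window):
        raise DataError("EMA window contains missing post-weights")
    ema_value = ema(window, w)
    base, delta, pred = predict_emd(state, x)
    post_pred = ema_value + pred
    actual = series.sessions[t].post_weight
    result = PredictionResult(
        target_index=t,
        ema_value=ema_value,
        emd_base=base,
        emd_delta=delta,
        emd_pred=pred,
        post_pred=post_pred,
        post_actual=actual,
    )
    if actual is not None:
        result.abs_error = abs(post_pred - actual)
        result.rel_error = result.abs_error / actual
    return result


@dataclass(frozen=True)
class EvalConfig:
    """Hyperparameters and protocol settings for rolling evaluation."""

    k: int = 5
    n: int = 5
    tau: float = 1.0
    ema_mode: str = "normalized"
    kernel_mode: str = "sample_weight"
    trim_rate: float = 0.10
    warmup: int = 30


def rolling_evaluate(
    series: PatientSeries, config: EvalConfig = EvalConfig()
) -> list[PredictionResult]:
    """Rolling-origin evaluation: for each t >= warmup, refit on the strict
    prefix (imputation stats, trimming, normalization and both regression
    stages recomputed from sessions before t only) and predict session t.

    Sessions missing both weights are skipped as targets; a target missing
    only its pre-weight has it filled from the prefix's imputation stats.
    """
    c = config
    min_rows = 3 * c.k + 2
    if c.warmup < max(c.k, c.n) + min_rows:
        raise DataError(
            f"warmup {c.warmup} too small; need >= {max(c.k, c.n) + min_rows}"
        )
    if len(series.sessions) <= c.warmup:
        raise DataError(f"series of length {len(series)} not longer than warmup")
    results = []
    kernel_warned = False
    for t in range(c.warmup, len(series.sessions)):
        target = series.sessions[t]
        if target.pre_weight is None and target.post_weight is None:
            continue
        prefix = series.replace_sessions(list(series.sessions[:t]))
        stats = compute_delta(prefix)
        imputed = impute_missing(prefix, stats)
        trimmed = trim_outliers(imputed, c.trim_rate)
        state = fit(trimmed, c.k, c.n, c.tau, c.ema_mode, c.kernel_mode)
        state._kernel_warned = kernel_warned  # one warning per evaluation run
        if target.pre_weight is None:
            target = replace(
                target,
                pre_weight=target.post_weight + target.uf_volume / 1000.0 + stats.delta,
            )
        pred_series = series.replace_sessions(list(imputed.sessions) + [target])
        t_local = len(pred_series.sessions) - 1
        if t_local < max(c.k, c.n):
            continue  # too many dropped sessions in the prefix
        result = predict_post(state, pred_series, t_local)
        kernel_warned = state._kernel_warned
        result.target_index = t
        results.append(result)
    return results


def k_sweep(
    series_list: list[PatientSeries],
    k_values,
    config: EvalConfig = EvalConfig(),
):
    """Rolling evaluation per k, metric quadruple averaged across patients.

    Returns a pandas DataFrame with columns (k, mae, mape, mse, r2).
    """
    import pandas as pd

    from .evaluate import metric_quad

    rows = []
    for k in k_values:
        cfg = replace(config, k=int(k))
        quads = []
        for series in series_list:
            res = [r for r in rolling_evaluate(series, cfg) if r.post_actual is not None]
            if not res:
                continue
            actual = [r.post_actual for r in res]
            pred = [r.post_pred for r in res]
            quads.append(metric_quad(actual, pred))
        if not quads:
            raise DataError(f"no scoreable predictions at k={k}")
        rows.append(
            {
                "k": int(k),
                "mae": float(np.mean([q.mae for q in quads])),
                "mape": float(np.mean([q.mape for q in quads])),
                "mse": float(np.mean([q.mse for q in quads])),
                "r2": float(np.mean([q.r2 for q in quads])),
            }
        )
    return pd.DataFrame(rows)
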