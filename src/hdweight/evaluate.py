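"""Metric suite, gamma error-distribution calibration, comparison statistics
and deviation alerting."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "MetricQuad",
    "GammaErrorFit",
    "PairwiseTest",
    "ComparisonResult",
    "metric_quad",
    "error_cdf",
    "anova_oneway",
    "holm_ttests",
    "deviation_alert",
    "cohort_report",
]


@dataclass(frozen=True)
class MetricQuad:
    """MAE (kg), MAPE (percent), MSE (kg^2) and coefficient of determination."""

    mae: float
    mape: float
    mse: float
    r2: float

    def to_dict(self) -> dict:
        return {"mae": self.mae, "mape": self.mape, "mse": self.mse, "r2": self.r2}


def metric_quad(actual, predicted, denominators=None) -> MetricQuad:
    """Error metrics on paired actual/predicted values.

    MAPE divides each absolute error by ``denominators`` (default: the actual
    values, i.e. the post-dialysis weights) and is reported in percent.
    r2 is 1 - SSE/SST about the mean of ``actual``; for constant actuals it
    is NaN with a logged warning.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    d = a if denominators is None else np.asarray(denominators, dtype=float)
    if a.ndim != 1 or a.shape != p.shape or a.shape != d.shape or a.size == 0:
        raise DataError("metric_quad requires equal-length nonempty 1-D inputs")
    err = a - p
    mae = float(np.mean(np.abs(err)))
    mape = float(np.mean(np.abs(err) / np.abs(d)) * 100.0)
    mse = float(np.mean(err**2))
    sst = float(np.sum((a - a.mean()) ** 2))
    if sst == 0.0:
        logger.warning("r2 undefined for constant actual values; reporting NaN")
        r2 = math.nan
    else:
        r2 = 1.0 - float(np.sum(err**2)) / sst
    return MetricQuad(mae=mae, mape=mape, mse=mse, r2=r2)


@dataclass(frozen=True)
class GammaErrorFit:
    """Gamma MLE (location fixed at 0) of an error sample, with the CDF at a
    clinically chosen threshold."""

    shape: float
    scale: float
    threshold: float
    cdf_at_threshold: float


def error_cdf(errors, threshold: float) -> GammaErrorFit:
    """Fit a gamma distribution to nonnegative errors and evaluate its CDF.

    Zeros are clipped to 1e-6 to keep the likelihood finite.  An all-zero
    sample is degenerate: the CDF is reported as 1.0 with a warning.
    """
    e = np.asarray(errors, dtype=float)
    if e.ndim != 1 or np.any(e < 0) or np.any(~np.isfinite(e)):
        raise DataError("error_cdf requires a 1-D nonnegative finite sample")
    if np.count_nonzero(e) == 0:
        logger.warning("all errors are zero; gamma fit degenerate, CDF = 1.0")
        return GammaErrorFit(
            shape=math.nan, scale=math.nan, threshold=threshold, cdf_at_threshold=1.0
        )
    if np.count_nonzero(e > 0) < 10:
        raise DataError("error_cdf requires at least 10 positive errors")
    e = np.clip(e, 1e-6, None)
    shape, _, scale = sps.gamma.fit(e, floc=0.0)
    cdf = float(sps.gamma.cdf(threshold, shape, loc=0.0, scale=scale))
    return GammaErrorFit(
        shape=float(shape), scale=float(scale), threshold=threshold, cdf_at_threshold=cdf
    )


def anova_oneway(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F-statistic and p-value across >= 2 groups."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise DataError("anova_oneway requires >= 2 groups with >= 2 values each")
    f, p = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


@dataclass(frozen=True)
class PairwiseTest:
    name: str
    t_stat: float
    p_raw: float
    p_adj: float
    reject: bool

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "t_stat": self.t_stat,
            "p_raw": self.p_raw,
            "p_adj": self.p_adj,
            "reject": self.reject,
        }


@dataclass(frozen=True)
class ComparisonResult:
    f_stat: float
    anova_p: float
    pairwise: list[PairwiseTest]

    def to_dict(self) -> dict:
        return {
            "f_stat": self.f_stat,
            "anova_p": self.anova_p,
            "pairwise": [t.to_dict() for t in self.pairwise],
        }


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def holm_ttests(
    reference, others: dict, alpha: float = 0.05, paired: bool = True
) -> list[PairwiseTest]:
    """t-test of a reference method against each competitor, with Holm
    step-down multiple-testing adjustment.

    Tests are paired by default (one metric value per patient per method,
    same patients throughout); ``paired=False`` uses Welch's test instead.
    """
    ref = np.asarray(reference, dtype=float)
    names = list(others)
    t_stats, p_raws = [], []
    for name in names:
        other = np.asarray(others[name], dtype=float)
        if paired:
            if other.shape != ref.shape:
                raise DataError(f"paired t-test vs {name!r}: length mismatch")
            if np.allclose(other, ref):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(ref, other)
        else:
            t, p = sps.ttest_ind(ref, other, equal_var=False)
        t_stats.append(float(t))
        p_raws.append(float(p))
    p_adj = holm_adjust(p_raws)
    return [
        PairwiseTest(
            name=name,
            t_stat=t,
            p_raw=p,
            p_adj=float(pa),
            reject=bool(pa <= alpha),
        )
        for name, t, p, pa in zip(names, t_stats, p_raws, p_adj)
    ]


def deviation_alert(
    results, abs_threshold: float = 0.5, rel_threshold: float = 0.01
) -> list:
    """Sessions whose prediction deviates beyond either clinical threshold.

    Flags |error| > abs_threshold kg OR relative error > rel_threshold;
    results without an actual weight are ignored.
    """
    flagged = []
    for r in results:
        if r.post_actual is None:
            continue
        if r.abs_error > abs_threshold or r.rel_error > rel_threshold:
            flagged.append(r)
    return flagged


def cohort_report(
    series_list,
    config=None,
    abs_threshold: float = 0.5,
    rel_threshold: float = 0.01,
    alpha: float = 0.05,
) -> dict:
    """Full-pipeline evaluation report for a labelled cohort.

    Runs rolling evaluation per patient, aggregates the metric quadruple per
    clinical group, fits pooled gamma error distributions per group (absolute
    errors against the kg threshold, relative errors against the fractional
    threshold), and compares groups via one-way ANOVA on per-patient MAE plus
    Holm-adjusted pairwise tests against the first group present.
    """
    from .emd_model import EvalConfig, rolling_evaluate

    config = config or EvalConfig()
    per_patient = {}
    by_group: dict[str, dict] = {}
    for series in series_list:
        res = [r for r in rolling_evaluate(series, config) if r.post_actual is not None]
        if not res:
            continue
        actual = [r.post_actual for r in res]
        pred = [r.post_pred for r in res]
        quad = metric_quad(actual, pred)
        alerts = deviation_alert(res, abs_threshold, rel_threshold)
        per_patient[series.patient_id] = {
            "group": series.group,
            "n_predictions": len(res),
            "metrics": quad.to_dict(),
            "n_alerts": len(alerts),
        }
        g = by_group.setdefault(
            series.group, {"mae": [], "abs_errors": [], "rel_errors": []}
        )
        g["mae"].append(quad.mae)
        g["abs_errors"].extend(r.abs_error for r in res)
        g["rel_errors"].extend(r.rel_error for r in res)

    report: dict = {"per_patient": per_patient, "groups": {}}
    for group, data in by_group.items():
        entry: dict = {
            "n_patients": len(data["mae"]),
            "mean_mae": float(np.mean(data["mae"])),
        }
        if np.count_nonzero(np.asarray(data["abs_errors"]) > 0) >= 10:
            abs_fit = error_cdf(data["abs_errors"], abs_threshold)
            rel_fit = error_cdf(data["rel_errors"], rel_threshold)
            entry["abs_error_gamma"] = {
                "shape": abs_fit.shape,
                "scale": abs_fit.scale,
                "cdf_at_threshold": abs_fit.cdf_at_threshold,
            }
            entry["rel_error_gamma"] = {
                "shape": rel_fit.shape,
                "scale": rel_fit.scale,
                "cdf_at_threshold": rel_fit.cdf_at_threshold,
            }
        report["groups"][group] = entry

    group_names = [g for g in by_group if len(by_group[g]["mae"]) >= 2]
    if len(group_names) >= 2:
        f, p = anova_oneway([by_group[g]["mae"] for g in group_names])
        ref_name = group_names[0]
        pairwise = holm_ttests(
            by_group[ref_name]["mae"],
            {g: by_group[g]["mae"] for g in group_names[1:]},
            alpha=alpha,
            paired=False,
        )
        report["comparison"] = {
            "metric": "mae",
            "reference_group": ref_name,
            **ComparisonResult(f, p, pairwise).to_dict(),
        }
    return report
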