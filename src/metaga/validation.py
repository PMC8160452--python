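"""Accuracy metrics, bootstrap confidence intervals and validation reports.

The primary accuracy metric is the mean absolute error between estimated and
reference gestational age,

    MAE  = (1/n) * sum_i |GA_ref_i - GA_est_i|          (weeks)
    RMSE = sqrt((1/n) * sum_i (GA_ref_i - GA_est_i)^2)  (weeks),

together with the percentage of infants estimated within +/-7 and +/-14 days
(|residual| <= 1.0 and <= 2.0 weeks; the boundary counts as within).
Uncertainty is summarized by 95% bootstrap percentile confidence intervals
(2.5th/97.5th percentiles over the replicate statistics), resampling infants
as the unit so reference and estimate always move together.

Reports break the metrics down by the clinically relevant subgroups
(overall, preterm <37 weeks, SGA10, SGA3) and add calibration-in-the-large:
the model-estimated preterm birth rate against the rate observed from
reference GA. For cohorts whose reference GA is reported in completed weeks,
both arms are floored before residuals are formed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .preprocess import round_down_completed_weeks

__all__ = [
    "MetricSet",
    "ValidationError",
    "ValidationReport",
    "bootstrap_ci",
    "build_validation_report",
    "compute_metrics",
    "residual_by_week",
]

SUBGROUPS = ("overall", "preterm", "sga10", "sga3")


class ValidationError(ValueError):
    """Invalid metric input (length mismatch, empty data)."""


@dataclass
class MetricSet:
    """Point accuracy metrics, optionally with bootstrap CIs (weeks / %)."""

    n: int
    mae: float
    rmse: float
    pct_within_1wk: float
    pct_within_2wk: float
    mae_ci: tuple[float, float] | None = None
    rmse_ci: tuple[float, float] | None = None
    pct_within_1wk_ci: tuple[float, float] | None = None
    pct_within_2wk_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name, point, ci in (
            ("mae", self.mae, self.mae_ci),
            ("rmse", self.rmse, self.rmse_ci),
            ("pct_within_1wk", self.pct_within_1wk, self.pct_within_1wk_ci),
            ("pct_within_2wk", self.pct_within_2wk, self.pct_within_2wk_ci),
        ):
            if ci is not None and not ci[0] <= point <= ci[1]:
                # Percentile CIs very rarely exclude the point estimate;
                # treat as a warning, not an error.
                warnings.warn(
                    f"bootstrap CI for {name} excludes the point estimate",
                    stacklevel=2)

    def as_dict(self) -> dict:
        return {
            "n": self.n, "mae": self.mae, "rmse": self.rmse,
            "pct_within_1wk": self.pct_within_1wk,
            "pct_within_2wk": self.pct_within_2wk,
            "mae_ci": self.mae_ci, "rmse_ci": self.rmse_ci,
            "pct_within_1wk_ci": self.pct_within_1wk_ci,
            "pct_within_2wk_ci": self.pct_within_2wk_ci,
        }


def _point_metrics(resid: np.ndarray) -> tuple[float, float, float, float]:
    ab = np.abs(resid)
    return (
        float(ab.mean()),
        float(np.sqrt(np.mean(resid**2))),
        float(100.0 * np.mean(ab <= 1.0)),
        float(100.0 * np.mean(ab <= 2.0)),
    )


def compute_metrics(ga_ref, ga_est) -> MetricSet:
    """MAE, RMSE and +/-1/+/-2-week agreement bands (point values)."""
    ref = np.asarray(ga_ref, float)
    est = np.asarray(ga_est, float)
    if ref.shape != est.shape:
        raise ValidationError("ga_ref and ga_est must have equal length")
    if ref.size == 0:
        raise ValidationError("metrics need at least one record")
    mae, rmse, p1, p2 = _point_metrics(est - ref)
    return MetricSet(n=ref.size, mae=mae, rmse=rmse,
                     pct_within_1wk=p1, pct_within_2wk=p2)


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    ga_ref, ga_est,
    n_replicates: int = 1000,
    seed: int = 0,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """95% bootstrap percentile CI of ``statistic(ref, est)``.

    The resampling unit is the infant: each replicate draws paired
    (reference, estimate) rows with replacement. A replicate on which the
    statistic fails (raises or returns NaN) is redrawn, up to
    ``max_redraws`` extra draws in total.
    """
    if n_replicates < 2:
        raise ValidationError("need at least 2 bootstrap replicates")
    ref = np.asarray(ga_ref, float)
    est = np.asarray(ga_est, float)
    if ref.shape != est.shape or ref.size == 0:
        raise ValidationError("paired data required")
    rng = np.random.default_rng(seed)
    values = np.empty(n_replicates)
    redraws = 0
    i = 0
    while i < n_replicates:
        idx = rng.integers(0, ref.size, ref.size)
        try:
            v = float(statistic(ref[idx], est[idx]))
        except Exception:
            v = np.nan
        if np.isnan(v):
            redraws += 1
            if redraws > max_redraws:
                raise ValidationError("statistic failed on too many replicates")
            continue
        values[i] = v
        i += 1
    if redraws:
        warnings.warn(f"redrew {redraws} failed bootstrap replicates",
                      stacklevel=2)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return float(lo), float(hi)


def _bootstrap_metricset(ref: np.ndarray, est: np.ndarray,
                         n_replicates: int, rng: np.random.Generator) -> MetricSet:
    point = compute_metrics(ref, est)
    reps = np.empty((n_replicates, 4))
    for b in range(n_replicates):
        idx = rng.integers(0, ref.size, ref.size)
        reps[b] = _point_metrics(est[idx] - ref[idx])
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return MetricSet(
        n=point.n, mae=point.mae, rmse=point.rmse,
        pct_within_1wk=point.pct_within_1wk,
        pct_within_2wk=point.pct_within_2wk,
        mae_ci=(float(lo[0]), float(hi[0])),
        rmse_ci=(float(lo[1]), float(hi[1])),
        pct_within_1wk_ci=(float(lo[2]), float(hi[2])),
        pct_within_2wk_ci=(float(lo[3]), float(hi[3])),
    )


@dataclass
class ValidationReport:
    """Metrics with CIs per subgroup plus preterm-rate calibration."""

    cohort_label: str
    subgroups: dict[str, MetricSet | None]
    preterm_rate_estimated: float
    preterm_rate_estimated_ci: tuple[float, float]
    preterm_rate_observed: float
    residual_by_week: list[dict] = field(default_factory=list)
    n_replicates: int = 1000
    seed: int = 0
    ga_reporting: str = "decimal_weeks"

    def to_json(self) -> str:
        payload = {
            "cohort_label": self.cohort_label,
            "ga_reporting": self.ga_reporting,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "subgroups": {k: (v.as_dict() if v is not None else {"n": 0})
                          for k, v in self.subgroups.items()},
            "preterm_rate_estimated": self.preterm_rate_estimated,
            "preterm_rate_estimated_ci": self.preterm_rate_estimated_ci,
            "preterm_rate_observed": self.preterm_rate_observed,
            "residual_by_week": self.residual_by_week,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_frame(self) -> pd.DataFrame:
        """Flat table mirroring the usual model-performance summary layout:
        one row per subgroup, columns for each metric and its CI."""
        rows = []
        for name in SUBGROUPS:
            ms = self.subgroups.get(name)
            row = {"cohort": self.cohort_label, "subgroup": name}
            if ms is None:
                row["n"] = 0
            else:
                d = ms.as_dict()
                row.update({
                    "n": d["n"], "mae": d["mae"], "rmse": d["rmse"],
                    "pct_within_1wk": d["pct_within_1wk"],
                    "pct_within_2wk": d["pct_within_2wk"],
                    "mae_lo": d["mae_ci"][0], "mae_hi": d["mae_ci"][1],
                    "rmse_lo": d["rmse_ci"][0], "rmse_hi": d["rmse_ci"][1],
                    "pct1_lo": d["pct_within_1wk_ci"][0],
                    "pct1_hi": d["pct_within_1wk_ci"][1],
                    "pct2_lo": d["pct_within_2wk_ci"][0],
                    "pct2_hi": d["pct_within_2wk_ci"][1],
                })
            rows.append(row)
        return pd.DataFrame(rows)


def residual_by_week(cohort: pd.DataFrame, estimates) -> pd.DataFrame:
    """Per completed reference-GA week: n, mean(est - ref) and MAE."""
    ref = cohort["ga_weeks"].to_numpy(float)
    est = np.asarray(estimates, float)
    weeks = round_down_completed_weeks(ref)
    resid = est - ref
    rows = []
    for week in np.unique(weeks):
        m = weeks == week
        rows.append({
            "week": int(week),
            "n": int(m.sum()),
            "mean_residual": float(resid[m].mean()),
            "mae": float(np.abs(resid[m]).mean()),
        })
    return pd.DataFrame(rows, columns=["week", "n", "mean_residual", "mae"])


def build_validation_report(
    cohort: pd.DataFrame,
    estimates,
    subgroup_flags: pd.DataFrame,
    n_replicates: int = 1000,
    seed: int = 0,
    ga_reporting: str = "decimal_weeks",
    cohort_label: str = "cohort",
) -> ValidationReport:
    """Full validation summary for one cohort and one model's estimates.

    ``subgroup_flags`` must carry boolean ``sga10``/``sga3`` columns aligned
    to the cohort (``preterm`` is derived from reference GA if absent). For
    ``ga_reporting="completed_weeks"`` residuals are floor(est) - floor(ref),
    matching how such cohorts report reference GA. Empty subgroups are
    reported with n = 0 and absent metrics. Deterministic given ``seed``.
    """
    ref = cohort["ga_weeks"].to_numpy(float)
    est = np.asarray(estimates, float)
    if ref.shape != est.shape:
        raise ValidationError("estimates must align with the cohort")
    if ga_reporting not in ("decimal_weeks", "completed_weeks"):
        raise ValidationError("unknown ga_reporting")

    if ga_reporting == "completed_weeks":
        ref_cmp = np.floor(ref)
        est_cmp = np.floor(est)
    else:
        ref_cmp, est_cmp = ref, est

    flags = {
        "overall": np.ones(len(cohort), bool),
        "preterm": (subgroup_flags["preterm"].to_numpy(bool)
                    if "preterm" in subgroup_flags else ref < 37.0),
        "sga10": subgroup_flags["sga10"].to_numpy(bool),
        "sga3": subgroup_flags["sga3"].to_numpy(bool),
    }
    rng = np.random.default_rng(seed)
    subgroups: dict[str, MetricSet | None] = {}
    for name in SUBGROUPS:
        m = flags[name]
        if m.sum() == 0:
            subgroups[name] = None
            continue
        subgroups[name] = _bootstrap_metricset(
            ref_cmp[m], est_cmp[m], n_replicates, rng)

    preterm_est = float(100.0 * np.mean(est_cmp < 37.0))
    rate_reps = np.empty(n_replicates)
    for b in range(n_replicates):
        idx = rng.integers(0, est_cmp.size, est_cmp.size)
        rate_reps[b] = 100.0 * np.mean(est_cmp[idx] < 37.0)
    lo, hi = np.percentile(rate_reps, [2.5, 97.5])
    preterm_obs = float(100.0 * np.mean(ref_cmp < 37.0))

    rbw = residual_by_week(cohort, est)
    return ValidationReport(
        cohort_label=cohort_label,
        subgroups=subgroups,
        preterm_rate_estimated=preterm_est,
        preterm_rate_estimated_ci=(float(lo), float(hi)),
        preterm_rate_observed=preterm_obs,
        residual_by_week=rbw.to_dict("records"),
        n_replicates=n_replicates,
        seed=seed,
        ga_reporting=ga_reporting,
    )
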