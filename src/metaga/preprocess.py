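"""Cohort exclusions, data preparation, and subgroup classification.

The preparation pipeline is order-fixed and deterministic:

1. exclusions (late collection, screen positives, missing fields);
2. derived fetal:adult hemoglobin ratio;
3. Tukey-fence winsorization of each variable on its raw scale
   (fences at Q1 - 3*IQR and Q3 + 3*IQR);
4. natural log transform of analytes (not birth weight);
5. pareto scaling: subtract the mean, divide by the square root of the
   standard deviation.

Fences and scaling constants are fitted per cohort ("local
standardization") by default and can be reused across cohorts through
:class:`PreprocessParams`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import BASE_COLUMNS, HB_COLUMNS

__all__ = [
    "ExclusionLog",
    "PreprocessError",
    "PreprocessParams",
    "ScalingError",
    "VariableParams",
    "analyte_columns",
    "apply_exclusions",
    "apply_preprocess",
    "classify_subgroups",
    "compute_hb_ratio",
    "compute_reference_percentiles",
    "fit_and_apply_scaling",
    "fit_preprocess",
    "fit_tukey_fences",
    "round_down_completed_weeks",
    "winsorize",
]

HB_RATIO = "hb_ratio"


class PreprocessError(ValueError):
    """Invalid input to a preprocessing step."""


class ScalingError(PreprocessError):
    """A variable cannot be pareto-scaled (zero spread); message names it."""


def analyte_columns(cohort: pd.DataFrame) -> list[str]:
    """Analyte columns of a cohort table (everything beyond the base schema)."""
    return [c for c in cohort.columns if c not in BASE_COLUMNS]


# --- exclusions -------------------------------------------------------------

@dataclass
class ExclusionLog:
    """Counts of removed records, attributed to the first triggering rule
    (late collection -> screen positive -> missing field)."""

    late_collection: int = 0
    screen_positive: int = 0
    missing_field: int = 0
    retained: int = 0

    @property
    def total_excluded(self) -> int:
        return self.late_collection + self.screen_positive + self.missing_field


def apply_exclusions(
    cohort: pd.DataFrame,
    max_collection_hours: float = 48.0,
    panel: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove late-collected, screen-positive and incomplete records.

    ``max_collection_hours`` is 48 by convention for model derivation and 72
    for external cohorts with later sampling; any positive value is accepted.
    Records with missing sex, birth weight, GA, or any panel analyte are
    dropped. An empty input yields an empty output with zero counts.
    """
    if max_collection_hours <= 0:
        raise PreprocessError("max_collection_hours must be positive")
    if panel is None:
        panel = analyte_columns(cohort)
    log = ExclusionLog()
    if len(cohort) == 0:
        return cohort.copy(), log

    late = cohort["collection_age_hours"].to_numpy(float) > max_collection_hours
    positive = cohort["screen_positive"].to_numpy() == 1
    required = ["sex", "birth_weight_g", "ga_weeks"] + list(panel)
    missing = cohort[required].isna().any(axis=1).to_numpy()
    missing |= ~cohort["sex"].isin(["M", "F"]).to_numpy()

    log.late_collection = int(late.sum())
    log.screen_positive = int((positive & ~late).sum())
    log.missing_field = int((missing & ~positive & ~late).sum())
    keep = ~(late | positive | missing)
    log.retained = int(keep.sum())
    return cohort.loc[keep].copy(), log


# --- derived features -------------------------------------------------------

def compute_hb_ratio(hbf, hbf1, hba):
    """Fetal:adult hemoglobin ratio (HbF + HbF1) / (HbF + HbF1 + HbA).

    Accepts scalars or arrays. An all-zero denominator yields a missing value
    (NaN); negative inputs are rejected.
    """
    hbf = np.asarray(hbf, float)
    hbf1 = np.asarray(hbf1, float)
    hba = np.asarray(hba, float)
    if (hbf < 0).any() or (hbf1 < 0).any() or (hba < 0).any():
        raise PreprocessError("hemoglobin fractions must be nonnegative")
    fetal = hbf + hbf1
    denom = fetal + hba
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, fetal / np.where(denom > 0, denom, 1.0), np.nan)
    return float(ratio) if ratio.ndim == 0 else ratio


def add_hb_ratio(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append the ``hb_ratio`` column where the hemoglobin triplet is present.

    Records with an all-zero denominator get a missing ratio (and are caught
    by the missing-field exclusion if exclusions run afterwards).
    """
    if not all(c in cohort.columns for c in HB_COLUMNS):
        return cohort
    out = cohort.copy()
    out[HB_RATIO] = compute_hb_ratio(
        out["HbF"].to_numpy(float),
        out["HbF1"].to_numpy(float),
        out["HbA"].to_numpy(float),
    )
    return out


# --- winsorization and scaling ----------------------------------------------

def fit_tukey_fences(values, k: float = 3.0) -> tuple[float, float]:
    """Fences at Q1 - k*IQR and Q3 + k*IQR (k = 3 by default).

    Quartiles use linear interpolation between order statistics (the common
    "type 7" rule). Requires at least 4 non-missing values; a constant vector
    yields equal fences, making winsorization a no-op.
    """
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise PreprocessError("need at least 4 non-missing values to fit fences")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def winsorize(values, fences: tuple[float, float]) -> np.ndarray:
    """Clamp values to the fitted fences; idempotent, preserves NaN."""
    lower, upper = fences
    if lower > upper:
        raise PreprocessError("lower fence exceeds upper fence")
    return np.clip(np.asarray(values, float), lower, upper)


@dataclass
class VariableParams:
    """Fitted preparation constants for one variable."""

    lower_fence: float
    upper_fence: float
    log_applied: bool
    zero_offset: float
    pareto_mean: float
    pareto_sd: float


@dataclass
class PreprocessParams:
    """Per-variable fences and pareto-scaling constants, with provenance."""

    fitted_on: str
    variables: dict[str, VariableParams] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "fitted_on": self.fitted_on,
            "variables": {k: asdict(v) for k, v in self.variables.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessParams":
        payload = json.loads(text)
        return cls(
            fitted_on=payload["fitted_on"],
            variables={k: VariableParams(**v)
                       for k, v in payload["variables"].items()},
        )


def _prepare_column(x: np.ndarray, vp: VariableParams) -> np.ndarray:
    x = winsorize(x, (vp.lower_fence, vp.upper_fence))
    if vp.log_applied:
        x = np.where(x <= 0, vp.zero_offset, x)
        x = np.log(x)
    return (x - vp.pareto_mean) / np.sqrt(vp.pareto_sd)


def fit_preprocess(
    cohort: pd.DataFrame,
    variables: Sequence[str] | None = None,
    label: str = "cohort",
) -> PreprocessParams:
    """Fit fences and pareto constants on ``cohort``.

    Analytes (and the hemoglobin ratio) are log-transformed; birth weight is
    pareto-scaled on its raw scale. Zero analyte readings are replaced by half
    the smallest positive observed value before the log. Raises
    :class:`ScalingError` naming the variable when its spread is zero.
    """
    if variables is None:
        variables = analyte_columns(cohort) + ["birth_weight_g"]
    params = PreprocessParams(fitted_on=label)
    for name in variables:
        if name not in cohort.columns:
            raise PreprocessError(f"variable {name!r} absent from cohort")
        raw = cohort[name].to_numpy(float)
        lower, upper = fit_tukey_fences(raw)
        log_applied = name != "birth_weight_g"
        x = winsorize(raw, (lower, upper))
        zero_offset = 0.0
        if log_applied:
            positive = x[np.isfinite(x) & (x > 0)]
            zero_offset = float(positive.min()) / 2.0 if positive.size else 1e-12
            x = np.where(x <= 0, zero_offset, x)
            x = np.log(x)
        finite = x[np.isfinite(x)]
        mean = float(finite.mean())
        sd = float(finite.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ScalingError(f"variable {name!r} has zero spread; cannot scale")
        params.variables[name] = VariableParams(
            lower_fence=lower, upper_fence=upper, log_applied=log_applied,
            zero_offset=zero_offset, pareto_mean=mean, pareto_sd=sd,
        )
    return params


def apply_preprocess(cohort: pd.DataFrame, params: PreprocessParams) -> pd.DataFrame:
    """Winsorize, log and pareto-scale a cohort with previously fitted params.

    Analyte columns are replaced by their standardized values; birth weight
    keeps its raw column and gains a standardized ``birth_weight_scaled``
    column (raw grams remain available for subgroup classification).
    """
    out = cohort.copy()
    for name, vp in params.variables.items():
        if name not in out.columns:
            raise PreprocessError(f"variable {name!r} absent from cohort")
        scaled = _prepare_column(out[name].to_numpy(float), vp)
        if name == "birth_weight_g":
            out["birth_weight_scaled"] = scaled
        else:
            out[name] = scaled
    return out


def fit_and_apply_scaling(
    cohort: pd.DataFrame,
    variables: Sequence[str] | None = None,
    label: str = "cohort",
) -> tuple[pd.DataFrame, PreprocessParams]:
    """Fit the preparation constants on ``cohort`` and apply them to it."""
    params = fit_preprocess(cohort, variables=variables, label=label)
    return apply_preprocess(cohort, params), params


# --- subgroups --------------------------------------------------------------

def round_down_completed_weeks(ga_weeks):
    """Floor decimal GA to completed weeks (37 weeks 6 days -> 37)."""
    ga = np.asarray(ga_weeks, float)
    if (ga < 0).any():
        raise PreprocessError("gestational age must be nonnegative")
    floored = np.floor(ga).astype(int)
    return int(floored) if floored.ndim == 0 else floored


def compute_reference_percentiles(
    cohort: pd.DataFrame,
    min_stratum: int = 30,
) -> pd.DataFrame:
    """Empirical birth-weight centiles (3rd/10th/90th) per completed GA week
    and sex, computed from a designated reference cohort.

    These empirical sex-by-week centiles stand in for published growth
    standards, mirroring the practice of fixing the reference population once
    and applying it uniformly across cohorts. Strata with fewer than
    ``min_stratum`` records are omitted (records falling in them are flagged
    unclassifiable downstream).
    """
    weeks = round_down_completed_weeks(cohort["ga_weeks"].to_numpy(float))
    frame = pd.DataFrame({
        "week": weeks,
        "sex": cohort["sex"].to_numpy(),
        "bw": cohort["birth_weight_g"].to_numpy(float),
    })
    rows = []
    for (week, sex), grp in frame.groupby(["week", "sex"]):
        if len(grp) < min_stratum:
            continue
        p3, p10, p90 = np.percentile(grp["bw"], [3.0, 10.0, 90.0])
        rows.append({"week": int(week), "sex": sex, "p3": p3, "p10": p10, "p90": p90})
    return pd.DataFrame(rows, columns=["week", "sex", "p3", "p10", "p90"])


def classify_subgroups(
    cohort: pd.DataFrame,
    reference_percentiles: pd.DataFrame,
) -> pd.DataFrame:
    """Flag preterm (<37 weeks), SGA10, SGA3 and LGA per record.

    SGA/LGA use strict comparison against the (completed GA week x sex)
    reference centiles; SGA3 implies SGA10 by construction. Records whose
    stratum is absent from the reference are flagged ``unclassifiable``.
    Returns a DataFrame of boolean flags aligned to ``cohort``'s index.
    """
    ga = cohort["ga_weeks"].to_numpy(float)
    weeks = round_down_completed_weeks(ga)
    lookup = {
        (int(r.week), r.sex): (r.p3, r.p10, r.p90)
        for r in reference_percentiles.itertuples(index=False)
    }
    n = len(cohort)
    sga10 = np.zeros(n, bool)
    sga3 = np.zeros(n, bool)
    lga = np.zeros(n, bool)
    unclass = np.zeros(n, bool)
    bw = cohort["birth_weight_g"].to_numpy(float)
    sex = cohort["sex"].to_numpy()
    for i in range(n):
        key = (int(weeks[i]), sex[i])
        if key not in lookup:
            unclass[i] = True
            continue
        p3, p10, p90 = lookup[key]
        sga3[i] = bw[i] < p3
        sga10[i] = bw[i] < p10
        lga[i] = bw[i] > p90
    return pd.DataFrame(
        {
            "preterm": ga < 37.0,
            "sga10": sga10,
            "sga3": sga3,
            "lga": lga,
            "unclassifiable": unclass,
        },
        index=cohort.index,
    )
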