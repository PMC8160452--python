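"""Model design: cohort splitting, restricted cubic splines, rank-based
partial-correlation screening, and design-matrix construction.

The three model families share one declarative :class:`ModelSpec`:

* Model 1 — sex, birth weight (5-knot restricted cubic spline) and their
  interaction, fitted by ordinary least squares;
* Model 2 — sex plus the analyte panel, the most predictive analytes
  splined, pairwise interactions, fitted with elastic-net regularization;
* Model 3 — Model 2 plus birth weight (splined).

Spline knots sit at the 5th, 27.5th, 50th, 72.5th and 95th percentiles of the
training distribution of each splined variable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import analyte_columns
from .synthetic_cohort import HB_COLUMNS

__all__ = [
    "DesignError",
    "DesignMatrix",
    "KnotError",
    "ModelSpec",
    "SplineSpec",
    "STANDARD_KNOT_PERCENTILES",
    "build_design_matrix",
    "build_model_spec",
    "compute_knots",
    "model_predictor_pool",
    "partial_spearman_screen",
    "rcs_basis",
    "split_cohort",
]

STANDARD_KNOT_PERCENTILES = (5.0, 27.5, 50.0, 72.5, 95.0)

SEX_COLUMN = "sex_male"
BW_SCALED = "birth_weight_scaled"


class KnotError(ValueError):
    """Too few distinct values/knots for a spline basis."""


class DesignError(ValueError):
    """A model spec references columns absent from the cohort."""


# --- splitting --------------------------------------------------------------

def split_cohort(
    cohort: pd.DataFrame,
    fractions: Sequence[float] = (0.5, 0.25, 0.25),
    seed: int = 0,
    strata: Sequence[str] | None = None,
) -> list[pd.DataFrame]:
    """Stratified random partition into development / validation / test.

    Strata default to completed GA week x sex so each sub-cohort retains the
    GA and sex distribution of the whole. Allocation within a stratum follows
    the largest-remainder rule, so realized sizes match the fractions to
    within one record per stratum. Strata smaller than 3 are pooled into a
    single global lottery (with a warning). The partition is disjoint,
    exhaustive, and reproducible for a fixed seed.
    """
    fractions = np.asarray(fractions, float)
    if fractions.size == 0 or (fractions < 0).any():
        raise ValueError("fractions must be nonnegative")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(cohort)
    if strata is None:
        keys = [
            (int(np.floor(g)), s)
            for g, s in zip(cohort["ga_weeks"].to_numpy(float),
                            cohort["sex"].to_numpy())
        ]
    else:
        keys = list(map(tuple, cohort[list(strata)].to_numpy()))

    groups: dict[tuple, list[int]] = {}
    for pos, key in enumerate(keys):
        groups.setdefault(key, []).append(pos)

    lottery: list[int] = []
    parts: list[list[int]] = [[] for _ in fractions]
    for key in sorted(groups):
        idx = groups[key]
        if len(idx) < 3:
            lottery.extend(idx)
            continue
        _allocate(idx, fractions, rng, parts)
    if lottery:
        warnings.warn(
            f"{len(lottery)} records in strata smaller than 3 assigned by "
            "global lottery", stacklevel=2)
        _allocate(lottery, fractions, rng, parts)
    return [cohort.iloc[sorted(p)].copy() for p in parts]


def _allocate(idx: list[int], fractions: np.ndarray,
              rng: np.random.Generator, parts: list[list[int]]) -> None:
    perm = rng.permutation(len(idx))
    shuffled = [idx[i] for i in perm]
    quotas = fractions * len(idx)
    base = np.floor(quotas).astype(int)
    leftover = len(idx) - int(base.sum())
    order = np.argsort(-(quotas - base), kind="stable")
    counts = base.copy()
    counts[order[:leftover]] += 1
    start = 0
    for j, c in enumerate(counts):
        parts[j].extend(shuffled[start:start + c])
        start += c


# --- splines ----------------------------------------------------------------

def compute_knots(
    values,
    percentiles: Sequence[float] = STANDARD_KNOT_PERCENTILES,
) -> np.ndarray:
    """Empirical percentile knots (same linear-interpolation quantile rule as
    the Tukey fences), deduplicated; invariant to duplicating the data."""
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if np.unique(x).size < 20:
        raise KnotError("need at least 20 distinct values to place knots")
    knots = np.percentile(x, list(percentiles))
    dedup = np.unique(knots)
    if dedup.size < len(percentiles):
        warnings.warn(
            f"collapsed {len(percentiles) - dedup.size} tied knots; spline "
            "order reduced", stacklevel=2)
    if dedup.size < 3:
        raise KnotError("fewer than 3 distinct knots remain after deduplication")
    return dedup


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis with k knots -> k-1 columns.

    Column 0 is the identity term; columns 1..k-2 are truncated-power terms

        [(x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
                    + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2

    which makes the spline exactly linear beyond the boundary knots (the
    division by the squared knot range only stabilizes the scale). For all
    x at or below the first knot the nonlinear columns are exactly zero.
    Non-finite x propagates as NaN.
    """
    t = np.asarray(knots, float)
    if t.ndim != 1 or t.size < 3:
        raise KnotError("need at least 3 knots")
    if not (np.diff(t) > 0).all():
        raise KnotError("knots must be strictly increasing")
    x = np.asarray(x, float)
    k = t.size
    scale = (t[-1] - t[0]) ** 2
    denom = t[-1] - t[-2]

    def cube_plus(v: np.ndarray) -> np.ndarray:
        return np.where(v > 0, v, 0.0) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            cube_plus(x - t[j])
            - cube_plus(x - t[-2]) * (t[-1] - t[j]) / denom
            + cube_plus(x - t[-1]) * (t[-2] - t[j]) / denom
        ) / scale
        cols.append(np.where(np.isfinite(x), term, np.nan))
    return np.column_stack(cols)


@dataclass
class SplineSpec:
    """Knot scheme for one splined variable (on the preprocessed scale)."""

    variable: str
    knots: Sequence[float]
    knot_percentiles: Sequence[float] = STANDARD_KNOT_PERCENTILES

    def __post_init__(self) -> None:
        self.knots = tuple(float(k) for k in self.knots)
        if not all(b > a for a, b in zip(self.knots, self.knots[1:])):
            raise KnotError(f"knots for {self.variable!r} must be strictly increasing")

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 1


# --- screening --------------------------------------------------------------

def partial_spearman_screen(
    cohort: pd.DataFrame,
    candidates: Sequence[str],
    adjust_for: Sequence[str] = (SEX_COLUMN, BW_SCALED),
    ga_col: str = "ga_weeks",
) -> pd.Series:
    """Rank each candidate analyte by its partial Spearman correlation with
    GA, mutually adjusted for all other candidates and the clinical
    covariates.

    All variables (GA, candidates, covariates) are rank-transformed; the
    partial correlation of GA with each candidate given everything else is
    read off the precision matrix of the ranks, which equals the correlation
    of the least-squares rank residuals. Rank statistics make the scores
    invariant under strictly monotone transforms of any candidate and
    sensitive to non-linear but monotone-component associations.

    Returns a Series of signed scores indexed by candidate, sorted by
    descending absolute value. Collinear adjustment columns are handled via a
    pseudo-inverse with a warning.
    """
    candidates = list(candidates)
    names = [ga_col] + candidates + [a for a in adjust_for if a not in candidates]
    mat = np.empty((len(cohort), len(names)))
    for j, name in enumerate(names):
        if name == SEX_COLUMN and name not in cohort.columns:
            col = (cohort["sex"].to_numpy() == "M").astype(float)
        elif name in cohort.columns:
            col = cohort[name].to_numpy(float)
        else:
            raise DesignError(f"column {name!r} absent from cohort")
        mat[:, j] = stats.rankdata(col)
    corr = np.corrcoef(mat, rowvar=False)
    try:
        precision = np.linalg.inv(corr)
    except np.linalg.LinAlgError:
        warnings.warn("collinear adjustment set; using pseudo-inverse",
                      stacklevel=2)
        precision = np.linalg.pinv(corr)
    scores = {}
    for j, name in enumerate(names[1:len(candidates) + 1], start=1):
        scores[name] = -precision[0, j] / np.sqrt(precision[0, 0] * precision[j, j])
    series = pd.Series(scores, name="partial_spearman")
    return series.iloc[np.argsort(-series.abs().to_numpy(), kind="stable")]


# --- model specs and design matrices ----------------------------------------

@dataclass
class ModelSpec:
    """Declarative predictor/spline/interaction structure of one model.

    ``predictors`` are cohort column names ("sex" is encoded as a male
    indicator; birth weight enters through its standardized column).
    ``interaction_policy`` is ``"pairwise"`` (products of the scalar
    standardized predictors plus sex x each spline basis column) or
    ``"none"``.
    """

    model_id: int
    predictors: Sequence[str]
    splined: Sequence[SplineSpec] = field(default_factory=tuple)
    interaction_policy: str = "pairwise"
    panel: Sequence[str] = ()
    top_k_splined: int = 7

    def __post_init__(self) -> None:
        self.predictors = tuple(self.predictors)
        self.splined = tuple(self.splined)
        self.panel = tuple(self.panel)
        splined_vars = {s.variable for s in self.splined}
        if not splined_vars <= set(self.predictors):
            raise DesignError("splined variables must be a subset of predictors")
        if self.interaction_policy not in ("pairwise", "none"):
            raise DesignError("interaction_policy must be 'pairwise' or 'none'")

    def to_json(self) -> str:
        payload = {
            "model_id": self.model_id,
            "predictors": list(self.predictors),
            "splined": [
                {"variable": s.variable, "knots": list(s.knots),
                 "knot_percentiles": list(s.knot_percentiles)}
                for s in self.splined
            ],
            "interaction_policy": self.interaction_policy,
            "panel": list(self.panel),
            "top_k_splined": self.top_k_splined,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        p = json.loads(text)
        return cls(
            model_id=p["model_id"],
            predictors=p["predictors"],
            splined=[SplineSpec(s["variable"], s["knots"], s["knot_percentiles"])
                     for s in p["splined"]],
            interaction_policy=p["interaction_policy"],
            panel=p["panel"],
            top_k_splined=p["top_k_splined"],
        )


@dataclass
class DesignMatrix:
    """Numeric design matrix with per-column provenance.

    ``provenance`` maps each column name to ``(source variables, term type)``
    with term type one of intercept / main / spline / interaction.
    """

    column_names: list[str]
    values: np.ndarray
    provenance: dict[str, tuple[tuple[str, ...], str]]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)

    def to_csv(self, path) -> None:
        """Export for debugging, with a provenance comment header
        (``# column: term-type <- source variables``)."""
        with open(path, "w") as fh:
            for name in self.column_names:
                sources, kind = self.provenance[name]
                fh.write(f"# {name}: {kind} <- {','.join(sources) or '-'}\n")
            self.to_frame().to_csv(fh, index=False)


def model_predictor_pool(cohort: pd.DataFrame) -> list[str]:
    """Analyte predictors available in a (preprocessed) cohort: every analyte
    column except the raw hemoglobin fractions, which the derived ratio
    represents."""
    return [c for c in analyte_columns(cohort)
            if c not in HB_COLUMNS and c != "birth_weight_scaled"]


def build_model_spec(
    model_id: int,
    train_cohort: pd.DataFrame,
    screened: Sequence[str] | None = None,
    top_k_splined: int = 7,
    knot_percentiles: Sequence[float] = STANDARD_KNOT_PERCENTILES,
    interaction_policy: str = "pairwise",
) -> ModelSpec:
    """Assemble the spec for model family 1, 2 or 3 from a training cohort.

    ``screened`` is the descending analyte ranking from
    :func:`partial_spearman_screen`; its top ``top_k_splined`` entries get
    restricted cubic splines with knots placed on the training distribution.
    """
    if model_id not in (1, 2, 3):
        raise DesignError("model_id must be 1, 2 or 3")
    analytes = model_predictor_pool(train_cohort) if model_id != 1 else []
    predictors = ["sex"]
    if model_id in (1, 3):
        predictors.append(BW_SCALED)
    predictors.extend(analytes)

    splined_vars: list[str] = []
    if model_id in (1, 3):
        splined_vars.append(BW_SCALED)
    if model_id in (2, 3):
        if screened is None:
            raise DesignError("models 2 and 3 need a screened analyte ranking")
        top = [a for a in screened if a in analytes][:top_k_splined]
        splined_vars.extend(top)
    splined = [
        SplineSpec(v, compute_knots(train_cohort[v].to_numpy(float),
                                    knot_percentiles), knot_percentiles)
        for v in splined_vars
    ]
    return ModelSpec(
        model_id=model_id,
        predictors=predictors,
        splined=splined,
        interaction_policy=interaction_policy,
        panel=analytes,
        top_k_splined=top_k_splined,
    )


def build_design_matrix(cohort: pd.DataFrame, spec: ModelSpec) -> DesignMatrix:
    """Construct the design matrix for ``spec`` on a preprocessed cohort.

    Column order is deterministic: intercept, sex indicator, main effects in
    predictor order (splined variables contribute their full basis), then
    interactions. Under the ``pairwise`` policy the interactions are the
    products of every pair of scalar (pre-spline) numeric predictor columns,
    plus the sex indicator times every spline basis column and every
    non-splined numeric scalar. Missing columns raise :class:`DesignError`
    listing all absences.
    """
    numeric = [p for p in spec.predictors if p != "sex"]
    missing = [p for p in numeric if p not in cohort.columns]
    if missing:
        raise DesignError(f"cohort lacks predictor columns: {missing}")
    if "sex" in spec.predictors and "sex" not in cohort.columns:
        raise DesignError("cohort lacks predictor columns: ['sex']")
    splined = {s.variable: s for s in spec.splined}

    n = len(cohort)
    names: list[str] = ["intercept"]
    cols: list[np.ndarray] = [np.ones(n)]
    prov: dict[str, tuple[tuple[str, ...], str]] = {"intercept": ((), "intercept")}

    sex = None
    if "sex" in spec.predictors:
        sex = (cohort["sex"].to_numpy() == "M").astype(float)
        names.append(SEX_COLUMN)
        cols.append(sex)
        prov[SEX_COLUMN] = (("sex",), "main")

    scalars: dict[str, np.ndarray] = {}
    spline_cols: list[tuple[str, np.ndarray, str]] = []
    for var in numeric:
        x = cohort[var].to_numpy(float)
        scalars[var] = x
        if var in splined:
            basis = rcs_basis(x, splined[var].knots)
            for j in range(basis.shape[1]):
                cname = f"{var}_rcs{j}"
                names.append(cname)
                cols.append(basis[:, j])
                prov[cname] = ((var,), "spline")
                spline_cols.append((cname, basis[:, j], var))
        else:
            names.append(var)
            cols.append(x)
            prov[var] = ((var,), "main")

    if spec.interaction_policy == "pairwise":
        for i in range(len(numeric)):
            for j in range(i + 1, len(numeric)):
                a, b = numeric[i], numeric[j]
                cname = f"{a}:{b}"
                names.append(cname)
                cols.append(scalars[a] * scalars[b])
                prov[cname] = ((a, b), "interaction")
        if sex is not None:
            for cname, col, var in spline_cols:
                iname = f"{SEX_COLUMN}:{cname}"
                names.append(iname)
                cols.append(sex * col)
                prov[iname] = (("sex", var), "interaction")
            for var in numeric:
                if var not in splined:
                    iname = f"{SEX_COLUMN}:{var}"
                    names.append(iname)
                    cols.append(sex * scalars[var])
                    prov[iname] = (("sex", var), "interaction")

    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return DesignMatrix(column_names=names, values=values, provenance=prov)
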