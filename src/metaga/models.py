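"""Model fitting and prediction.

Model 1 (sex, birth weight and their interaction) is fitted by ordinary
least squares without selection or regularization. Models 2 and 3 are fitted
with the elastic net, which minimizes

    (1/2) * mean((y - Xb)^2)
        + penalty_strength * [ l1_fraction * ||b||_1
                               + (1 - l1_fraction)/2 * ||b||_2^2 ]

with an unpenalized intercept (scikit-learn's coordinate-descent solver uses
exactly this objective with ``alpha = penalty_strength`` and
``l1_ratio = l1_fraction``). Hyperparameters are chosen by validation-set
mean squared error over a grid of (l1_fraction, penalty) points, warm-started
along each descending penalty path; ties prefer the larger penalty.

Coefficients are stored against standardized predictors, so prediction on a
new cohort requires a declared preprocessing-parameter label — making the
local-vs-training scaling contract explicit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .design import BW_SCALED, DesignMatrix, ModelSpec, build_design_matrix
from .preprocess import HB_RATIO
from .synthetic_cohort import HB_COLUMNS

__all__ = [
    "ElasticNetConvergenceError",
    "FittedModel",
    "ModelError",
    "PenaltyPath",
    "default_penalty_grid",
    "fit_baseline_model",
    "fit_elastic_net",
    "predict_ga",
    "restrict_model_spec",
    "select_hyperparameters",
    "train_elastic_net_model",
]


class ModelError(ValueError):
    """Invalid model specification or fitting input."""


class ElasticNetConvergenceError(RuntimeError):
    """Coordinate descent did not converge; carries iteration diagnostics."""

    def __init__(self, n_iter: int, max_iter: int, tol: float):
        self.n_iter, self.max_iter, self.tol = n_iter, max_iter, tol
        super().__init__(
            f"elastic net did not converge: {n_iter} iterations "
            f"(max_iter={max_iter}, tol={tol})"
        )


@dataclass
class FittedModel:
    """Estimated coefficients (weeks per unit of standardized predictor) plus
    the declarative spec and scaling provenance they are valid for."""

    spec: ModelSpec
    column_names: list[str]
    intercept: float
    coefficients: dict[str, float]
    hyperparameters: dict[str, float]
    preprocess_ref: str = ""
    training_n: int = 0

    def __post_init__(self) -> None:
        expected = [c for c in self.column_names if c != "intercept"]
        if sorted(self.coefficients) != sorted(expected):
            raise ModelError("coefficient keys must match the design columns")
        if self.hyperparameters.get("penalty_strength", 0.0) < 0:
            raise ModelError("penalty_strength must be nonnegative")
        l1 = self.hyperparameters.get("l1_fraction", 0.0)
        if not 0.0 <= l1 <= 1.0:
            raise ModelError("l1_fraction must be in [0, 1]")

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in self.column_names
                         if c != "intercept"])

    def to_json(self) -> str:
        payload = {
            "spec": json.loads(self.spec.to_json()),
            "column_names": self.column_names,
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "hyperparameters": self.hyperparameters,
            "preprocess_ref": self.preprocess_ref,
            "training_n": self.training_n,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FittedModel":
        p = json.loads(text)
        return cls(
            spec=ModelSpec.from_json(json.dumps(p["spec"])),
            column_names=p["column_names"],
            intercept=p["intercept"],
            coefficients=p["coefficients"],
            hyperparameters=p["hyperparameters"],
            preprocess_ref=p["preprocess_ref"],
            training_n=p["training_n"],
        )


def _split_intercept(design: DesignMatrix) -> tuple[np.ndarray, list[str]]:
    if design.column_names and design.column_names[0] == "intercept":
        return design.values[:, 1:], design.column_names[1:]
    return design.values, list(design.column_names)


def fit_baseline_model(design: DesignMatrix, ga: np.ndarray,
                       spec: ModelSpec | None = None,
                       preprocess_ref: str = "") -> FittedModel:
    """Ordinary least squares (Model 1); penalty recorded as zero.

    Rank-deficient designs are solved with the minimum-norm least-squares
    solution (dependent columns effectively dropped) with a warning.
    """
    y = np.asarray(ga, float)
    X, names = _split_intercept(design)
    Z = np.column_stack([np.ones(len(y)), X])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < Z.shape[1]:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {Z.shape[1]}); dependent "
            "columns resolved by minimum-norm solution", stacklevel=2)
    return FittedModel(
        spec=spec if spec is not None else ModelSpec(1, ()),
        column_names=list(design.column_names),
        intercept=float(beta[0]),
        coefficients={n: float(b) for n, b in zip(names, beta[1:])},
        hyperparameters={"l1_fraction": 0.0, "penalty_strength": 0.0},
        preprocess_ref=preprocess_ref,
        training_n=len(y),
    )


def fit_elastic_net(design: DesignMatrix, ga: np.ndarray,
                    l1_fraction: float, penalty_strength: float,
                    spec: ModelSpec | None = None,
                    preprocess_ref: str = "",
                    max_iter: int = 20_000, tol: float = 1e-4) -> FittedModel:
    """Elastic-net fit at one (l1_fraction, penalty_strength) point.

    ``penalty_strength = 0`` falls back to the least-squares solution.
    Non-convergence raises :class:`ElasticNetConvergenceError`.
    """
    if penalty_strength < 0:
        raise ModelError("penalty_strength must be nonnegative")
    if not 0.0 <= l1_fraction <= 1.0:
        raise ModelError("l1_fraction must be in [0, 1]")
    y = np.asarray(ga, float)
    if penalty_strength == 0.0:
        model = fit_baseline_model(design, y, spec=spec,
                                   preprocess_ref=preprocess_ref)
        model.hyperparameters = {"l1_fraction": float(l1_fraction),
                                 "penalty_strength": 0.0}
        return model
    X, names = _split_intercept(design)
    est = ElasticNet(alpha=penalty_strength, l1_ratio=l1_fraction,
                     fit_intercept=True, precompute=X.shape[0] > X.shape[1],
                     max_iter=max_iter, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            est.fit(X, y)
        except ConvergenceWarning:
            raise ElasticNetConvergenceError(int(max_iter), max_iter, tol)
    return FittedModel(
        spec=spec if spec is not None else ModelSpec(3, ()),
        column_names=list(design.column_names),
        intercept=float(est.intercept_),
        coefficients={n: float(b) for n, b in zip(names, est.coef_)},
        hyperparameters={"l1_fraction": float(l1_fraction),
                         "penalty_strength": float(penalty_strength)},
        preprocess_ref=preprocess_ref,
        training_n=len(y),
    )


def elastic_net_objective(design: DesignMatrix, ga: np.ndarray,
                          model: FittedModel) -> float:
    """Evaluate the penalized objective of a fitted model on a design."""
    X, _ = _split_intercept(design)
    beta = model.coefficient_vector()
    resid = np.asarray(ga, float) - (model.intercept + X @ beta)
    h = model.hyperparameters
    lam, l1 = h["penalty_strength"], h["l1_fraction"]
    return float(0.5 * np.mean(resid**2)
                 + lam * (l1 * np.abs(beta).sum()
                          + 0.5 * (1 - l1) * np.sum(beta**2)))


# --- hyperparameter selection -----------------------------------------------

@dataclass
class PathPoint:
    l1_fraction: float
    penalty_strength: float
    val_mse: float


@dataclass
class PenaltyPath:
    """Validation MSE over the hyperparameter grid; the chosen point
    minimizes validation MSE with ties resolved toward the larger penalty."""

    points: list[PathPoint] = field(default_factory=list)
    chosen: PathPoint | None = None

    def to_json(self) -> str:
        payload = {
            "points": [vars(p) for p in self.points],
            "chosen": vars(self.chosen) if self.chosen else None,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def default_penalty_grid(design: DesignMatrix, ga: np.ndarray,
                         l1_fractions: Sequence[float] = (0.1, 0.5, 0.9),
                         n_penalties: int = 50,
                         alpha_min_ratio: float = 1e-3) -> list[tuple[float, float]]:
    """Log-spaced penalty paths per l1 fraction, starting at the smallest
    penalty that zeroes every slope (the usual max |X'y|/(n*l1) rule)."""
    X, _ = _split_intercept(design)
    y = np.asarray(ga, float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    grad0 = np.abs(Xc.T @ yc).max() / len(y)
    grid: list[tuple[float, float]] = []
    for l1 in l1_fractions:
        amax = grad0 / max(l1, 1e-3)
        for alpha in np.geomspace(amax, amax * alpha_min_ratio, n_penalties):
            grid.append((float(l1), float(alpha)))
    return grid


def select_hyperparameters(
    dev_design: DesignMatrix, dev_ga: np.ndarray,
    val_design: DesignMatrix, val_ga: np.ndarray,
    grid: Sequence[tuple[float, float]] | None = None,
    l1_fractions: Sequence[float] = (0.1, 0.5, 0.9),
    n_penalties: int = 50,
    alpha_min_ratio: float = 1e-3,
    max_iter: int = 20_000, tol: float = 1e-4,
) -> PenaltyPath:
    """Fit each grid point on the development design, score its mean squared
    error on the validation design, and record the chosen point.

    Fits are warm-started down each descending penalty path. The result is
    independent of the grid ordering (points are re-sorted internally).
    """
    if grid is None:
        grid = default_penalty_grid(dev_design, dev_ga, l1_fractions,
                                    n_penalties, alpha_min_ratio)
    grid = list(grid)
    if not grid:
        raise ModelError("hyperparameter grid is empty")
    Xd, _ = _split_intercept(dev_design)
    Xv, _ = _split_intercept(val_design)
    yd = np.asarray(dev_ga, float)
    yv = np.asarray(val_ga, float)

    by_l1: dict[float, list[float]] = {}
    for l1, alpha in grid:
        by_l1.setdefault(l1, []).append(alpha)

    # Center once and share the Gram matrix across every fit on the path;
    # with centered data the intercept is recovered in closed form.
    x_mean = Xd.mean(axis=0)
    y_mean = float(yd.mean())
    Xc = np.asfortranarray(Xd - x_mean)
    yc = yd - y_mean
    precompute: bool | np.ndarray = Xc.shape[0] > Xc.shape[1]
    if precompute:
        precompute = np.dot(Xc.T, Xc)

    path = PenaltyPath()
    for l1 in sorted(by_l1):
        est = ElasticNet(l1_ratio=l1, fit_intercept=False, warm_start=True,
                         precompute=precompute, max_iter=max_iter, tol=tol)
        for alpha in sorted(by_l1[l1], reverse=True):
            est.set_params(alpha=alpha)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                est.fit(Xc, yc)
            pred = y_mean + (Xv - x_mean) @ est.coef_
            mse = float(np.mean((yv - pred) ** 2))
            path.points.append(PathPoint(float(l1), float(alpha), mse))
    path.chosen = min(path.points,
                      key=lambda p: (p.val_mse, -p.penalty_strength))
    return path


def train_elastic_net_model(
    dev_cohort: pd.DataFrame, val_cohort: pd.DataFrame,
    spec: ModelSpec, ga_col: str = "ga_weeks",
    preprocess_ref: str = "", **grid_kwargs,
) -> tuple[FittedModel, PenaltyPath]:
    """Select hyperparameters on the validation sub-cohort, then refit the
    final model on the development sub-cohort at the chosen point."""
    dev_design = build_design_matrix(dev_cohort, spec)
    val_design = build_design_matrix(val_cohort, spec)
    path = select_hyperparameters(
        dev_design, dev_cohort[ga_col].to_numpy(float),
        val_design, val_cohort[ga_col].to_numpy(float), **grid_kwargs)
    model = fit_elastic_net(
        dev_design, dev_cohort[ga_col].to_numpy(float),
        l1_fraction=path.chosen.l1_fraction,
        penalty_strength=path.chosen.penalty_strength,
        spec=spec, preprocess_ref=preprocess_ref)
    return model, path


# --- panel restriction and prediction ----------------------------------------

def restrict_model_spec(spec: ModelSpec, available_panel: Sequence[str]) -> ModelSpec:
    """Restrict a spec to the analytes measurable in an external cohort.

    ``available_panel`` lists raw analyte names; the hemoglobin ratio survives
    only when all three hemoglobin fractions are available. Dropped analytes
    take their spline specs (so a site without hemoglobins retains six splined
    analytes) and every interaction referencing them (interactions are derived
    from the predictor list at design time). The restricted model must be
    retrained from scratch on the training cohort.
    """
    available = set(available_panel)
    def keep(name: str) -> bool:
        if name in ("sex", BW_SCALED):
            return True
        if name == HB_RATIO:
            return all(c in available for c in HB_COLUMNS)
        return name in available

    predictors = [p for p in spec.predictors if keep(p)]
    if not [p for p in predictors if p != "sex"]:
        raise ModelError("restriction removed every numeric predictor")
    splined = [s for s in spec.splined if keep(s.variable)]
    panel = [a for a in spec.panel if keep(a)]
    return ModelSpec(
        model_id=spec.model_id,
        predictors=predictors,
        splined=splined,
        interaction_policy=spec.interaction_policy,
        panel=panel,
        top_k_splined=len([s for s in splined if s.variable != BW_SCALED]),
    )


def predict_ga(model: FittedModel, cohort: pd.DataFrame) -> np.ndarray:
    """Estimated GA in decimal weeks: intercept + sum(coefficient * column).

    The cohort must already be preprocessed under the scaling contract named
    by ``model.preprocess_ref``. Estimates are not clipped; for
    completed-weeks cohorts the caller floors the estimates before
    comparison. Prediction is invariant to record order.
    """
    design = build_design_matrix(cohort, model.spec)
    if design.column_names != model.column_names:
        raise ModelError("design columns do not match the fitted model")
    X, _ = _split_intercept(design)
    return model.intercept + X @ model.coefficient_vector()
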