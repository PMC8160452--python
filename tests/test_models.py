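"""Model fitting: OLS baseline, elastic net, hyperparameter selection,
panel restriction and prediction."""

import numpy as np
import pandas as pd
import pytest

from metaga.design import DesignMatrix, ModelSpec, SplineSpec, build_design_matrix
from metaga.models import (
    FittedModel,
    ModelError,
    elastic_net_objective,
    fit_baseline_model,
    fit_elastic_net,
    predict_ga,
    restrict_model_spec,
    select_hyperparameters,
)
from metaga.preprocess import HB_RATIO
from metaga.synthetic_cohort import CHINA_PANEL


def _design(X, names=None):
    n, p = X.shape
    names = names or [f"x{i}" for i in range(p)]
    cols = ["intercept"] + names
    values = np.column_stack([np.ones(n), X])
    prov = {c: ((c,), "main") for c in cols}
    prov["intercept"] = ((), "intercept")
    return DesignMatrix(column_names=cols, values=values, provenance=prov)


class TestBaseline:
    def test_exact_interpolation_without_noise(self, rng):
        X = rng.normal(size=(100, 5))
        beta = rng.normal(size=5)
        y = 2.0 + X @ beta
        model = fit_baseline_model(_design(X), y)
        resid = y - (model.intercept + X @ model.coefficient_vector())
        assert np.abs(resid).max() < 1e-8

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(200, 10))
        y = rng.normal(size=200)
        model = fit_baseline_model(_design(X), y)
        Z = np.column_stack([np.ones(200), X])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(model.coefficient_vector(), beta[1:], atol=1e-8)

    def test_record_order_invariance(self, rng):
        X = rng.normal(size=(150, 4))
        y = rng.normal(size=150)
        perm = rng.permutation(150)
        a = fit_baseline_model(_design(X), y)
        b = fit_baseline_model(_design(X[perm]), y[perm])
        assert np.allclose(a.coefficient_vector(), b.coefficient_vector())

    def test_rank_deficiency_warns(self, rng):
        X = rng.normal(size=(50, 3))
        X = np.column_stack([X, X[:, 0]])  # duplicated column
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit_baseline_model(_design(X), rng.normal(size=50))


class TestElasticNet:
    def test_zero_penalty_reproduces_ols(self, rng):
        X = rng.normal(size=(500, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=500)
        model = fit_elastic_net(_design(X), y, l1_fraction=0.5,
                                penalty_strength=0.0)
        Z = np.column_stack([np.ones(500), X])
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        assert np.allclose(model.coefficient_vector(), beta[1:], atol=1e-6)

    def test_huge_penalty_fully_shrinks(self, rng):
        X = rng.normal(size=(200, 5))
        y = rng.normal(size=200) + 39.0
        model = fit_elastic_net(_design(X), y, l1_fraction=0.5,
                                penalty_strength=1e6)
        assert np.allclose(model.coefficient_vector(), 0.0)
        assert model.intercept == pytest.approx(y.mean())

    def test_optimum_objective_monotone_along_path(self, rng):
        X = rng.normal(size=(300, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=300)
        design = _design(X)
        # descending penalties: the optimum of the penalized objective is
        # non-increasing as the penalty decreases
        objectives = []
        for lam in np.geomspace(10.0, 1e-4, 20):
            model = fit_elastic_net(design, y, 0.5, lam)
            objectives.append(elastic_net_objective(design, y, model))
        diffs = np.diff(objectives)
        assert (diffs <= 1e-10).all()

    def test_invalid_hyperparameters_rejected(self, rng):
        d = _design(np.ones((10, 1)))
        with pytest.raises(ModelError):
            fit_elastic_net(d, np.ones(10), l1_fraction=1.5, penalty_strength=1.0)
        with pytest.raises(ModelError):
            fit_elastic_net(d, np.ones(10), l1_fraction=0.5, penalty_strength=-1.0)


class TestSelection:
    def test_single_point_grid_chosen(self, rng):
        X = rng.normal(size=(100, 3))
        y = rng.normal(size=100)
        path = select_hyperparameters(_design(X), y, _design(X), y,
                                      grid=[(0.5, 0.3)])
        assert (path.chosen.l1_fraction, path.chosen.penalty_strength) == (0.5, 0.3)

    def test_chosen_point_beats_exhaustive_scoring(self, rng):
        X = rng.normal(size=(400, 6))
        beta = np.array([1.0, -0.5, 0.0, 0.0, 0.3, 0.0])
        y = X @ beta + rng.normal(0, 0.5, 400)
        Xv = rng.normal(size=(300, 6))
        yv = Xv @ beta + rng.normal(0, 0.5, 300)
        grid = [(l1, a) for l1 in (0.2, 0.8)
                for a in np.geomspace(1.0, 1e-3, 10)]
        path = select_hyperparameters(_design(X), y, _design(Xv), yv, grid=grid)
        # exhaustive re-scoring oracle
        best = np.inf
        for l1, a in grid:
            m = fit_elastic_net(_design(X), y, l1, a)
            mse = np.mean((yv - (m.intercept + Xv @ m.coefficient_vector()))**2)
            best = min(best, mse)
        assert path.chosen.val_mse <= best * 1.05
        assert path.chosen.val_mse == min(p.val_mse for p in path.points)

    def test_grid_order_independent(self, rng):
        X = rng.normal(size=(120, 4))
        y = rng.normal(size=120)
        grid = [(0.5, a) for a in (0.5, 0.05, 0.005)]
        a = select_hyperparameters(_design(X), y, _design(X), y, grid=grid)
        b = select_hyperparameters(_design(X), y, _design(X), y, grid=grid[::-1])
        assert vars(a.chosen) == vars(b.chosen)

    def test_empty_grid_rejected(self, rng):
        d = _design(np.ones((10, 1)))
        with pytest.raises(ModelError):
            select_hyperparameters(d, np.ones(10), d, np.ones(10), grid=[])


class TestRestriction:
    def _full_spec(self):
        knots = [-2.0, -1.0, 0.0, 1.0, 2.0]
        splined = [SplineSpec("birth_weight_scaled", knots),
                   SplineSpec(HB_RATIO, knots),
                   SplineSpec("17OHP", knots), SplineSpec("C4DC", knots),
                   SplineSpec("TYR", knots), SplineSpec("ALA", knots),
                   SplineSpec("C5", knots), SplineSpec("C5DC", knots)]
        predictors = (["sex", "birth_weight_scaled", HB_RATIO]
                      + ["17OHP", "C4DC", "TYR", "ALA", "C5", "C5DC", "GALT"])
        return ModelSpec(3, predictors, splined=splined,
                         panel=predictors[2:], top_k_splined=7)

    def test_full_panel_is_identity(self):
        spec = self._full_spec()
        out = restrict_model_spec(
            spec, list(spec.panel) + ["HbF", "HbF1", "HbA"])
        assert out.predictors == spec.predictors
        assert [s.variable for s in out.splined] == [s.variable for s in spec.splined]

    def test_no_hemoglobin_panel_drops_ratio_and_keeps_six_splines(self):
        out = restrict_model_spec(self._full_spec(), list(CHINA_PANEL))
        assert HB_RATIO not in out.predictors
        assert "GALT" not in out.predictors
        splined_analytes = [s.variable for s in out.splined
                            if s.variable != "birth_weight_scaled"]
        assert len(splined_analytes) == 6
        assert out.top_k_splined == 6

    def test_restriction_removes_interactions_naming_dropped_analyte(self, rng):
        spec = self._full_spec()
        out = restrict_model_spec(spec, list(CHINA_PANEL))
        df = pd.DataFrame({
            "sex": rng.choice(["M", "F"], 50),
            "birth_weight_scaled": rng.normal(size=50),
        })
        for a in spec.panel:
            df[a] = rng.normal(size=50)
        design = build_design_matrix(df, out)
        assert not any(HB_RATIO in c or "GALT" in c for c in design.column_names)

    def test_everything_dropped_is_error(self):
        spec = ModelSpec(2, ["sex", "X"], panel=["X"])
        with pytest.raises(ModelError):
            restrict_model_spec(spec, [])


class TestPredict:
    def _model(self):
        spec = ModelSpec(3, ["sex", "A", "B"], interaction_policy="none")
        cols = ["intercept", "sex_male", "A", "B"]
        return FittedModel(
            spec=spec, column_names=cols, intercept=39.0,
            coefficients={"sex_male": 0.2, "A": 1.5, "B": 0.0},
            hyperparameters={"l1_fraction": 0.5, "penalty_strength": 0.1})

    def test_hand_set_coefficients_dot_product(self):
        df = pd.DataFrame({"sex": ["M"], "A": [2.0], "B": [5.0]})
        est = predict_ga(self._model(), df)
        assert est[0] == pytest.approx(39.0 + 0.2 * 1 + 1.5 * 2.0)

    def test_zero_row_returns_intercept(self):
        df = pd.DataFrame({"sex": ["F"], "A": [0.0], "B": [0.0]})
        assert predict_ga(self._model(), df)[0] == pytest.approx(39.0)

    def test_row_order_invariance(self, rng):
        df = pd.DataFrame({
            "sex": rng.choice(["M", "F"], 40),
            "A": rng.normal(size=40), "B": rng.normal(size=40)})
        est = predict_ga(self._model(), df)
        perm = rng.permutation(40)
        est_perm = predict_ga(self._model(), df.iloc[perm])
        assert np.allclose(est_perm, est[perm])

    def test_missing_column_raises(self):
        df = pd.DataFrame({"sex": ["M"], "A": [1.0]})
        with pytest.raises(Exception, match="B"):
            predict_ga(self._model(), df)


class TestNoOverfitGuard:
    def test_pure_noise_analytes_do_not_beat_baseline(self):
        """With only null analytes, the regularized analyte model cannot do
        meaningfully better than sex + birth weight alone."""
        from metaga import SyntheticConfig, generate_cohort, fit_and_apply_scaling
        from metaga.design import build_design_matrix, build_model_spec, \
            model_predictor_pool, partial_spearman_screen, split_cohort
        from metaga.models import train_elastic_net_model
        from metaga.synthetic_cohort import AnalyteEffect
        from metaga.validation import compute_metrics
        import warnings

        panel = ("TSH", "ALA", "TYR", "C0", "C2", "C3", "C4", "C5")
        effects = {a: AnalyteEffect(baseline=1.0, slope=0.0, log_sd=0.3)
                   for a in panel}
        cfg = SyntheticConfig(n_infants=5000, seed=11, analyte_panel=panel,
                              analyte_effects=effects,
                              ga_observation_noise_sd=0.3)
        cohort = generate_cohort(cfg)
        prepped, _ = fit_and_apply_scaling(cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dev, val, test = split_cohort(prepped, seed=1)
        ranking = list(partial_spearman_screen(dev, model_predictor_pool(dev)).index)
        spec1 = build_model_spec(1, dev)
        m1 = fit_baseline_model(build_design_matrix(dev, spec1),
                                dev["ga_weeks"].to_numpy(), spec=spec1)
        spec3 = build_model_spec(3, dev, screened=ranking, top_k_splined=3)
        m3, _ = train_elastic_net_model(dev, val, spec3,
                                        l1_fractions=[0.5], n_penalties=10)
        y = test["ga_weeks"].to_numpy()
        mae1 = compute_metrics(y, predict_ga(m1, test)).mae
        mae3 = compute_metrics(y, predict_ga(m3, test)).mae
        assert mae3 >= mae1 - 0.05
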