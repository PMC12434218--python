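"""Logistic fitting, odds-ratio transforms, ROC and design construction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from nutriscore.regression import (
    DesignError,
    DesignSpec,
    SeparationError,
    bivariable_screen,
    build_design,
    fit_logistic,
    forest_plot_data,
    or_per_scale,
    roc_curve,
)
from nutriscore.scoring import ValidationError, compute_patient_auc
from nutriscore.synthetic_cohort import (
    CohortConfig,
    LogisticOutcomeSpec,
    attach_logistic_outcomes,
    generate_cohort,
)


def allo_cohort(n=109, seed=13, outcome_spec=None):
    cfg = CohortConfig(
        n_patients=n, seed=seed, p_allogeneic=1.0, p_car_t=0.0, p_gene_therapy=0.0
    )
    records = generate_cohort(cfg)
    if outcome_spec is not None:
        attach_logistic_outcomes(
            records, outcome_spec, rng=np.random.default_rng(seed + 1)
        )
    scores = [compute_patient_auc(r) for r in records]
    return records, scores


OUTCOME = LogisticOutcomeSpec(intercept=-2.6, auc_coefficient=0.009)


class TestFit:
    def test_intercept_only_balanced_outcome(self):
        X = pd.DataFrame({"intercept": np.ones(40)})
        y = np.array([0.0, 1.0] * 20)
        fit = fit_logistic(X, y)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-10)
        assert fit.predict(X)[0] == pytest.approx(0.5)

    def test_two_by_two_matches_closed_form_odds_ratio(self):
        """Counts ((39,6),(29,35)): OR = 39*35/(6*29), Woolf CI."""
        x = np.repeat([1.0, 0.0], [45, 64])
        y = np.concatenate([np.ones(39), np.zeros(6), np.ones(29), np.zeros(35)])
        X = pd.DataFrame({"intercept": 1.0, "malignant": x})
        fit = fit_logistic(X, y)
        or_hat = 39 * 35 / (6 * 29)
        row = fit.summary.loc["malignant"]
        assert row["odds_ratio"] == pytest.approx(or_hat, abs=1e-6)
        se_woolf = np.sqrt(1 / 39 + 1 / 6 + 1 / 29 + 1 / 35)
        z = stats.norm.ppf(0.975)
        assert row["ci_low"] == pytest.approx(or_hat * np.exp(-z * se_woolf), rel=1e-6)
        assert row["ci_high"] == pytest.approx(or_hat * np.exp(z * se_woolf), rel=1e-6)

    def test_matches_statsmodels_on_random_data(self, rng):
        """IRLS MLE agrees with statsmodels' fit and with a generic optimiser."""
        from scipy.optimize import minimize
        from scipy.special import expit

        for _ in range(5):
            n = 150
            X = pd.DataFrame(
                {
                    "intercept": 1.0,
                    "x1": rng.normal(size=n),
                    "x2": rng.integers(0, 2, n).astype(float),
                }
            )
            eta = 0.2 + 0.9 * X["x1"] - 0.7 * X["x2"]
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            fit = fit_logistic(X, y)
            ref = sm.Logit(y, X).fit(disp=0)
            np.testing.assert_allclose(fit.params.values, ref.params.values, atol=1e-6)
            np.testing.assert_allclose(
                fit.summary["std_error"].values, ref.bse.values, atol=1e-6
            )
            Xm = X.to_numpy()

            def negll(beta):
                z = Xm @ beta
                return -np.sum(y * z - np.logaddexp(0.0, z))

            def grad(beta):
                return -Xm.T @ (y - expit(Xm @ beta))

            opt = minimize(
                negll, np.zeros(3), jac=grad, method="BFGS",
                options={"gtol": 1e-10, "maxiter": 1000},
            )
            np.testing.assert_allclose(fit.params.values, opt.x, atol=1e-6)
            assert fit.log_likelihood == pytest.approx(-opt.fun, abs=1e-6)

    def test_mean_fitted_probability_equals_prevalence(self, rng):
        records, scores = allo_cohort(200, seed=31, outcome_spec=OUTCOME)
        X, y = build_design(records, scores)
        fit = fit_logistic(X, y)
        assert fit.predict(X).mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_separation_raises_and_firth_recovers(self):
        x = np.repeat([0.0, 1.0], 20)
        y = x.copy()
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        with pytest.raises(SeparationError):
            fit_logistic(X, y)
        firth = fit_logistic(X, y, firth=True)
        assert firth.converged
        assert np.all(np.isfinite(firth.params.values))

    def test_single_class_outcome_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(10)})
        with pytest.raises(ValidationError, match="single class"):
            fit_logistic(X, np.ones(10))


class TestDesign:
    def test_allogeneic_design_shape(self):
        records, scores = allo_cohort(109, outcome_spec=OUTCOME)
        X, y = build_design(records, scores)
        assert X.shape == (109, 8)  # intercept + 7 terms
        assert list(X.columns[:1]) == ["intercept"]
        assert len(y) == 109

    def test_constant_column_rejected(self):
        records, scores = allo_cohort(60, seed=17, outcome_spec=OUTCOME)
        for rec in records:
            object.__setattr__(rec.covariates, "gender", "female")
        with pytest.raises(DesignError, match="male"):
            build_design(records, scores)

    def test_intercept_only_spec(self):
        records, scores = allo_cohort(30, outcome_spec=OUTCOME)
        X, y = build_design(records, scores, DesignSpec(terms=()))
        assert list(X.columns) == ["intercept"]

    def test_non_allogeneic_records_dropped(self):
        cfg = CohortConfig(n_patients=80, seed=23)
        records = generate_cohort(cfg)
        attach_logistic_outcomes(records, OUTCOME, rng=np.random.default_rng(0))
        scores = [compute_patient_auc(r) for r in records]
        X, _ = build_design(records, scores)
        n_allo = sum(
            1 for r in records if r.covariates.transplant_type == "allogeneic"
        )
        assert X.shape[0] == n_allo


class TestOrScale:
    def test_zero_coefficient_gives_unit_or(self):
        X = pd.DataFrame({"intercept": np.ones(40), "x": [0.0, 1.0] * 20})
        y = np.array([0, 1, 1, 0] * 10, dtype=float)  # x independent of y
        fit = fit_logistic(X, y)
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-10)
        res = or_per_scale(fit, "x", 100.0)
        assert res["odds_ratio"] == pytest.approx(1.0, abs=1e-8)

    def test_per_100_units_closed_form(self):
        assert np.exp(100 * 0.009) == pytest.approx(2.4596, abs=1e-4)

    def test_scale_one_is_identity(self):
        records, scores = allo_cohort(150, seed=41, outcome_spec=OUTCOME)
        X, y = build_design(records, scores, DesignSpec(terms=("auc",)))
        fit = fit_logistic(X, y)
        res = or_per_scale(fit, "auc", 1.0)
        row = fit.summary.loc["auc"]
        assert res["odds_ratio"] == pytest.approx(row["odds_ratio"], rel=1e-12)
        assert res["ci_low"] == pytest.approx(row["ci_low"], rel=1e-9)


class TestBivariable:
    def test_single_term_matches_direct_fit(self):
        records, scores = allo_cohort(150, seed=41, outcome_spec=OUTCOME)
        table = bivariable_screen(records, scores)
        X, y = build_design(records, scores, DesignSpec(terms=("auc",)))
        direct = fit_logistic(X, y).summary.loc["auc"]
        assert table.loc["auc", "estimate"] == pytest.approx(
            direct["estimate"], rel=1e-10
        )
        assert (table["error"] == "").all()

    def test_null_predictor_or_near_one(self):
        records, scores = allo_cohort(2000, seed=47, outcome_spec=OUTCOME)
        table = bivariable_screen(records, scores, DesignSpec(terms=("male",)))
        # gender does not enter the outcome model: OR ~ 1, CI covers 1
        assert table.loc["male", "ci_low"] < 1.0 < table.loc["male", "ci_high"]

    def test_failed_term_flagged_others_returned(self):
        records, scores = allo_cohort(60, seed=17, outcome_spec=OUTCOME)
        # make gender constant -> that term fails, others survive
        for rec in records:
            object.__setattr__(rec.covariates, "gender", "female")
        table = bivariable_screen(records, scores)
        assert table.loc["male", "error"] != ""
        assert np.isnan(table.loc["male", "estimate"])
        assert table.loc["auc", "error"] == ""


class TestROC:
    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1], dtype=float)
        p = np.array([0.1, 0.2, 0.8, 0.9])
        assert roc_curve(p, y).auc_roc == 1.0

    def test_constant_scores_auc_half(self):
        y = np.array([0, 1, 0, 1], dtype=float)
        p = np.full(4, 0.5)
        assert roc_curve(p, y).auc_roc == pytest.approx(0.5)

    def test_trapezoidal_equals_mann_whitney_u(self, rng):
        """Tie-grouped trapezoidal AUC is the U statistic / (n1*n0)."""
        for _ in range(20):
            n = int(rng.integers(10, 60))
            y = rng.integers(0, 2, n).astype(float)
            if len(np.unique(y)) < 2:
                continue
            p = np.round(rng.random(n), 2)  # coarse grid forces ties
            auc = roc_curve(p, y).auc_roc
            u = stats.mannwhitneyu(p[y == 1], p[y == 0]).statistic
            expected = u / ((y == 1).sum() * (y == 0).sum())
            assert auc == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        y[:2] = [0, 1]
        p = rng.random(100)
        assert roc_curve(p, y).auc_roc == pytest.approx(
            roc_curve(p**3, y).auc_roc, abs=1e-12
        )

    def test_curve_anchored_and_monotone(self, rng):
        y = rng.integers(0, 2, 50).astype(float)
        y[:2] = [0, 1]
        res = roc_curve(rng.random(50), y)
        assert res.fpr[0] == 0.0 and res.tpr[0] == 0.0
        assert res.fpr[-1] == 1.0 and res.tpr[-1] == 1.0
        assert np.all(np.diff(res.fpr) >= 0) and np.all(np.diff(res.tpr) >= 0)

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_curve([0.5, 0.6], [1.0, 1.0])


@pytest.fixture(scope="module")
def fit():
    records, scores = allo_cohort(250, seed=53, outcome_spec=OUTCOME)
    X, y = build_design(records, scores)
    return fit_logistic(X, y)


class TestForest:
    def test_seven_rows_without_intercept(self, fit):
        table = forest_plot_data(fit)
        assert len(table) == 7
        assert "intercept" not in set(table["term"])
        assert table.attrs["log_scale"] is True

    def test_eight_rows_with_intercept(self, fit):
        assert len(forest_plot_data(fit, include_intercept=True)) == 8

    def test_or_is_exp_estimate(self, fit):
        table = forest_plot_data(fit, include_intercept=True)
        est = fit.summary.loc[table["term"], "estimate"].to_numpy()
        np.testing.assert_allclose(table["odds_ratio"].to_numpy(), np.exp(est))
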