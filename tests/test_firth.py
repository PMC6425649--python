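"""Firth penalized logistic regression: closed forms, separation, designs."""

import warnings

import numpy as np
import pytest
from scipy import optimize
from scipy.special import expit

from breedgwas.firth import (
    FirthLogisticRegression,
    SingularDesignError,
    build_design,
    detect_separation,
    fit_firth,
    odds_ratios,
    penalized_lrt,
    wald_ci,
)
from breedgwas.io import MISSING

from conftest import make_cohort


def quasi_separated_2x2():
    """(y=1,x=1)=5, (y=1,x=0)=0, (y=0,x=1)=5, (y=0,x=0)=10."""
    X = np.array([[1.0]] * 10 + [[0.0]] * 10)
    y = np.array([1] * 5 + [0] * 5 + [0] * 10)
    return X, y


class TestFit:
    def test_saturated_2x2_equals_haldane_correction(self):
        """On a saturated 2x2 design the Firth estimate equals the
        add-half-to-each-cell (Haldane) log odds ratio: ln 21 here."""
        X, y = quasi_separated_2x2()
        fit = FirthLogisticRegression(fit_intercept=True).fit(X, y)
        assert fit.converged_
        assert fit.coef_[0] == pytest.approx(np.log(21.0), abs=1e-4)
        # intercept: logit of the corrected x=0 cell, ln(0.5/10.5)
        assert fit.intercept_ == pytest.approx(np.log(0.5 / 10.5), abs=1e-4)

    def test_balanced_null_no_intercept(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]] * 5)
        y = np.array([1, 0] * 10)
        fit = FirthLogisticRegression().fit(X, y)
        assert np.allclose(fit.coef_, 0.0, atol=1e-8)
        assert np.allclose(fit.fitted_prob_, 0.5, atol=1e-8)

    def test_finite_under_separation_where_ml_diverges(self, rng):
        """Firth stays finite on quasi-separated data; unpenalized ML
        drifts without bound as iterations increase."""
        X, y = quasi_separated_2x2()
        fit = FirthLogisticRegression(fit_intercept=True).fit(X, y)
        assert np.all(np.isfinite(fit.coef_))

        # plain Newton ML on the same data: coefficient keeps growing
        Xd = np.column_stack([X[:, 0], np.ones(len(y))])
        beta = np.zeros(2)
        norms = []
        for _ in range(30):
            pi = expit(Xd @ beta)
            W = pi * (1 - pi)
            M = Xd.T @ (Xd * W[:, None])
            beta = beta + np.linalg.solve(M, Xd.T @ (y - pi))
            norms.append(np.abs(beta[0]))
        assert norms[-1] > norms[5] > np.abs(fit.coef_[0])

    def test_hat_diag_sums_to_column_count(self, rng):
        X = rng.normal(size=(80, 4))
        y = (rng.uniform(size=80) < expit(X @ np.array([0.5, -1, 0.2, 0]))).astype(int)
        fit = FirthLogisticRegression().fit(X, y)
        assert fit.hat_diag_.sum() == pytest.approx(4.0, abs=1e-6)
        assert ((fit.hat_diag_ >= 0) & (fit.hat_diag_ <= 1)).all()

    def test_agrees_with_derivative_free_maximizer(self, rng):
        """Nelder-Mead on the penalized log-likelihood lands on the same
        optimum for random small designs."""
        for trial in range(20):
            n = int(rng.integers(20, 61))
            p = int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            fit = FirthLogisticRegression().fit(X, y)

            def neg_pll(beta, X=X, y=y, est=fit):
                return -est._pll(X, y.astype(float), beta)

            res = optimize.minimize(
                neg_pll, np.zeros(p), method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            assert np.allclose(fit.coef_, res.x, atol=1e-4), f"trial {trial}"

    def test_singular_design_names_columns(self):
        X = np.column_stack([np.ones(20), np.ones(20)])
        y = np.array([0, 1] * 10)
        with pytest.raises(SingularDesignError, match="collinear"):
            FirthLogisticRegression().fit(X, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            FirthLogisticRegression().fit(np.ones((5, 1)), np.ones(5))

    def test_empty_design_is_null_model(self):
        fit = FirthLogisticRegression().fit(np.empty((6, 0)), [1, 0, 1, 0, 1, 0])
        assert fit.loglik_ == pytest.approx(6 * np.log(0.5))
        assert fit.coef_.size == 0

    def test_sklearn_params_roundtrip(self):
        est = FirthLogisticRegression(tol=1e-6, max_iter=10)
        assert est.get_params()["tol"] == 1e-6
        est.set_params(max_iter=20)
        assert est.max_iter == 20

    def test_predict_proba_matches_training_probs(self, rng):
        X = rng.normal(size=(60, 2))
        y = rng.integers(0, 2, size=60)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        fit = FirthLogisticRegression().fit(X, y)
        np.testing.assert_allclose(fit.predict_proba(X)[:, 1], fit.fitted_prob_)


class TestWaldCI:
    def test_standard_normal_quantile(self):
        fit = FirthLogisticRegression()
        fit.coef_ = np.array([0.0])
        fit.cov_ = np.array([[1.0]])
        fit.converged_ = True
        ci = wald_ci(fit, level=0.95)
        assert ci["ci_low"].iloc[0] == pytest.approx(-1.959964, abs=1e-5)
        assert ci["ci_high"].iloc[0] == pytest.approx(1.959964, abs=1e-5)

    def test_zero_variance_zero_width(self):
        fit = FirthLogisticRegression()
        fit.coef_ = np.array([0.7])
        fit.cov_ = np.array([[0.0]])
        fit.converged_ = True
        ci = wald_ci(fit)
        assert ci["ci_low"].iloc[0] == ci["ci_high"].iloc[0] == pytest.approx(0.7)

    def test_requires_convergence(self):
        fit = FirthLogisticRegression()
        fit.coef_ = np.array([0.0])
        fit.cov_ = np.array([[1.0]])
        fit.converged_ = False
        with pytest.raises(ValueError, match="converged"):
            wald_ci(fit)


class TestDetectSeparation:
    def test_complete(self):
        X = np.array([[2.0]] * 5 + [[0.0]] * 5)
        y = np.array([1] * 5 + [0] * 5)
        assert detect_separation(X - 1.0, y)[0] == "complete"

    def test_quasi_on_zero_cell_table(self):
        X, y = quasi_separated_2x2()
        Xd = np.column_stack([X[:, 0], np.ones(len(y))])
        flags = detect_separation(Xd, y)
        assert "quasi" in flags and "complete" not in flags

    def test_none_on_overlap(self, rng):
        X = rng.normal(size=(100, 2))
        y = rng.integers(0, 2, 100)
        assert (detect_separation(X, y) == "none").all()


class TestBuildDesign:
    def test_only_observed_levels_get_columns(self):
        c = make_cohort([[0], [2], [0], [2]], [1, 0, 1, 0])
        d = build_design(c, ["M0"])
        assert [(col.term, col.level) for col in d.columns] == [("M0", "BB")]

    def test_no_missing_column_without_missing_calls(self):
        c = make_cohort([[0], [1], [2], [1]], [1, 0, 1, 0])
        d = build_design(c, ["M0"], include_missing_level=True)
        assert [col.level for col in d.columns] == ["AB", "BB"]

    def test_missing_level_column(self):
        c = make_cohort([[0], [1], [MISSING], [2]], [1, 0, 1, 0])
        d = build_design(c, ["M0"])
        assert [col.level for col in d.columns] == ["AB", "BB", "missing"]
        assert len(d.y) == 4

    def test_drop_missing_samples_when_disabled(self):
        c = make_cohort([[0], [1], [MISSING], [2]], [1, 0, 1, 0])
        d = build_design(c, ["M0"], include_missing_level=False)
        assert len(d.y) == 3

    def test_generalized_design_column_count(self, small_cohorts):
        """Markers contribute per observed level; cohort adds k-1 columns,
        sex adds 1 - verified against a hand count."""
        from breedgwas.io import merge_cohorts

        _, cohorts, _ = small_cohorts
        merged = merge_cohorts(list(cohorts.values()))
        terms = merged.marker_ids[:3]
        d = build_design(merged, terms, covariates=("cohort", "sex"))
        hand = 0
        for t in terms:
            g = merged.genotypes[:, merged.marker_ids.index(t)]
            hand += len({int(v) for v in g if v != 0})  # non-reference levels seen
        hand += 2  # three cohorts -> 2 indicators
        hand += 1  # sex -> 1 indicator
        assert len(d.columns) == hand
        assert not any("duplicate" in s for s in d.pruned)

    def test_absent_term_errors(self, small_cohorts):
        _, cohorts, _ = small_cohorts
        with pytest.raises(ValueError, match="not present"):
            build_design(cohorts["Greyhound"], ["NOPE"])

    def test_all_reference_marker_dropped_with_warning(self):
        c = make_cohort([[0, 1], [0, 2], [0, 1], [0, 0]], [1, 0, 1, 0])
        with pytest.warns(UserWarning, match="term dropped"):
            d = build_design(c, ["M0", "M1"])
        assert all(col.term == "M1" for col in d.columns)

    def test_samples_with_missing_phenotype_excluded(self):
        c = make_cohort([[0], [1], [2]], [1, 0, -1])
        d = build_design(c, ["M0"])
        assert len(d.y) == 2


class TestOddsRatios:
    def test_null_data_or_near_one(self):
        c = make_cohort([[0], [1], [2], [0], [1], [2]], [1, 1, 1, 0, 0, 0])
        d = build_design(c, ["M0"])
        fit = FirthLogisticRegression().fit(d.X, d.y)
        table = odds_ratios(fit, d)
        assert np.allclose(table["or"], 1.0, atol=1e-6)
        assert (table["separation"] == "none").all()

    def test_reported_per_zygosity_ors_are_exp_beta(self):
        """Coefficients ln(2.92) and ln(7.47) exponentiate to the per-
        zygosity odds ratios 2.92 (het) and 7.47 (hom)."""
        fit = FirthLogisticRegression()
        fit.coef_ = np.array([np.log(2.92), np.log(7.47)])
        fit.cov_ = np.eye(2) * 0.04
        fit.converged_ = True
        ci = wald_ci(fit)
        assert ci["or"].iloc[0] == pytest.approx(2.92)
        assert ci["or"].iloc[1] == pytest.approx(7.47)

    def test_separated_term_flagged_not_silently_reported(self):
        # all cases BB, all controls AA -> complete separation at the term
        c = make_cohort([[2]] * 5 + [[0]] * 5, [1] * 5 + [0] * 5)
        d = build_design(c, ["M0"])
        fit = FirthLogisticRegression().fit(d.X, d.y)
        table = odds_ratios(fit, d)
        assert (table["separation"] != "none").any()
        flagged = table[table["separation"] != "none"]
        assert (~flagged["estimable"]).all()
        assert (flagged["note"] == "suggestive of large effects").all()


def test_penalized_lrt_nested_improvement(rng):
    X = rng.normal(size=(150, 3))
    y = (rng.uniform(size=150) < expit(1.2 * X[:, 0])).astype(int)
    full = fit_firth(X, y)
    reduced = fit_firth(X[:, 1:], y)
    stat, p = penalized_lrt(full, reduced, df=1)
    assert stat > 0 and p < 0.01
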