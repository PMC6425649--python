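"""Stepwise-forward Firth selection and the LASSO/AIC path."""

import numpy as np
import pytest
from scipy.special import expit

import statsmodels.api as sm

from breedgwas.firth import build_design
from breedgwas.io import Cohort
from breedgwas.selection import (
    LassoAICLogistic,
    StepwiseFirthSelector,
    lasso_path,
    refit_selected,
    select_by_aic,
    stepwise_forward,
)
from breedgwas.simulate import BreedSpec, PlantedLocus, SimConfig, simulate_cohort


@pytest.fixture(scope="module")
def greyhound_with_signal():
    cfg = SimConfig(
        seed=314,
        breeds=(BreedSpec("Greyhound", 153, 114),),
        n_markers=20,
        planted=(PlantedLocus(0, {"Greyhound": (5**0.5, 5.0)}),),
    )
    return simulate_cohort(cfg)[0]["Greyhound"]


class TestStepwise:
    def test_alpha_in_zero_selects_nothing(self, greyhound_with_signal):
        spec, fit, _ = stepwise_forward(
            greyhound_with_signal, greyhound_with_signal.marker_ids, alpha_in=0.0
        )
        assert spec.selected_terms == []
        assert fit.coef_.size == 0

    def test_planted_marker_selected(self, greyhound_with_signal):
        spec, _, _ = stepwise_forward(
            greyhound_with_signal, greyhound_with_signal.marker_ids
        )
        assert "SNP000000" in spec.selected_terms

    def test_trace_replays_to_selected_terms(self, greyhound_with_signal):
        spec, _, _ = stepwise_forward(
            greyhound_with_signal, greyhound_with_signal.marker_ids
        )
        assert spec.replay() == spec.selected_terms

    def test_invariant_to_sample_order(self, greyhound_with_signal, rng):
        c = greyhound_with_signal
        perm = rng.permutation(c.n_samples)
        shuffled = Cohort(
            markers=list(c.markers),
            samples=[c.samples[i] for i in perm],
            genotypes=c.genotypes[perm],
        )
        a, _, _ = stepwise_forward(c, c.marker_ids)
        b, _, _ = stepwise_forward(shuffled, c.marker_ids)
        assert a.selected_terms == b.selected_terms

    def test_deterministic_rerun(self, greyhound_with_signal):
        a, _, _ = stepwise_forward(greyhound_with_signal, greyhound_with_signal.marker_ids)
        b, _, _ = stepwise_forward(greyhound_with_signal, greyhound_with_signal.marker_ids)
        assert a.selected_terms == b.selected_terms
        assert a.selection_trace == b.selection_trace

    def test_empty_pool_warns(self, greyhound_with_signal):
        with pytest.warns(UserWarning, match="empty candidate pool"):
            sel = StepwiseFirthSelector().fit(
                np.empty((greyhound_with_signal.n_samples, 0)),
                greyhound_with_signal.phenotype_array(),
                groups=np.empty(0, dtype=object),
            )
        assert sel.selected_groups_ == []

    def test_null_pool_selects_few(self):
        """All-null candidates: average selected count stays small (the
        per-candidate inclusion chance is about alpha)."""
        counts = []
        for r in range(60):
            cfg = SimConfig(seed=7000 + r, n_markers=20,
                            breeds=(BreedSpec("B", 80, 80),))
            c = simulate_cohort(cfg)[0]["B"]
            spec, _, _ = stepwise_forward(c, c.marker_ids)
            counts.append(len(spec.selected_terms))
        assert np.mean(counts) <= 2.0


class TestLasso:
    def test_all_zero_at_lambda_max(self, greyhound_with_signal):
        path, design = lasso_path(greyhound_with_signal,
                                  greyhound_with_signal.marker_ids[:8])
        assert np.allclose(path.coef_path[0], 0.0)

    def test_support_grows_roughly_with_smaller_lambda(self, greyhound_with_signal):
        path, _ = lasso_path(greyhound_with_signal,
                             greyhound_with_signal.marker_ids[:8])
        k = (path.coef_path != 0).sum(axis=1)
        assert k[0] == 0 and k[-1] >= k[0]
        # planted marker enters the path before most nulls
        assert k[-1] > 0

    def test_lambda_to_zero_approaches_unpenalized_ml(self, rng):
        """With a vanishing penalty the path endpoint matches the plain
        no-intercept logistic ML fit (statsmodels oracle)."""
        n = 400
        X = np.column_stack([
            rng.integers(0, 2, n).astype(float),
            rng.integers(0, 2, n).astype(float),
            rng.normal(size=n) > 0,
        ]).astype(float)
        beta_true = np.array([0.8, -0.5, 0.3])
        y = (rng.uniform(size=n) < expit(X @ beta_true)).astype(float)
        est = LassoAICLogistic(lambda_min_ratio=1e-6, tol=1e-10).fit(X, y)
        ml = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(est.coef_path_[-1], ml.params, atol=1e-3)

    def test_aic_hand_computed(self, rng):
        X = np.column_stack([
            rng.integers(0, 3, 120).astype(float),
            rng.integers(0, 2, 120).astype(float),
            rng.normal(size=120),
        ])
        y = (rng.uniform(size=120) < expit(0.7 * X[:, 0] - 0.4 * X[:, 2])).astype(float)
        est = LassoAICLogistic().fit(X, y)
        i = est.chosen_index_
        beta = est.coef_path_[i]
        eta = X @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0, eta)))
        k = int((beta != 0).sum())
        assert est.aic_[i] == pytest.approx(2 * k - 2 * ll, abs=1e-10)

    def test_tie_breaks_toward_sparser_model(self):
        # identical AIC at two grid points: argmin picks the earlier
        # (larger lambda) index by construction
        aic = np.array([10.0, 8.0, 8.0, 9.0])
        assert int(np.argmin(np.round(aic, 10))) == 1

    def test_select_by_aic_maps_columns_to_terms(self, greyhound_with_signal):
        path, design = lasso_path(greyhound_with_signal,
                                  greyhound_with_signal.marker_ids)
        terms = select_by_aic(path, design)
        assert "SNP000000" in terms
        assert len(terms) == len(set(terms))

    def test_increasing_grid_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        y = rng.integers(0, 2, 50).astype(float)
        with pytest.raises(ValueError, match="decreasing"):
            LassoAICLogistic().fit(X, y, lambda_grid=np.array([0.01, 0.1]))


class TestRefit:
    def test_refit_of_stepwise_support_matches_stepwise_fit(self, greyhound_with_signal):
        spec, fit, _ = stepwise_forward(
            greyhound_with_signal, greyhound_with_signal.marker_ids
        )
        rfit, rdesign, _ = refit_selected(greyhound_with_signal, spec.selected_terms)
        # same term set, same design -> same fit up to column ordering
        assert rfit.penalized_loglik_ == pytest.approx(fit.penalized_loglik_, abs=1e-6)
        assert sorted(np.round(rfit.coef_, 6)) == pytest.approx(
            sorted(np.round(fit.coef_, 6)), abs=1e-4
        )

    def test_empty_support_errors(self, greyhound_with_signal):
        with pytest.raises(ValueError, match="null model"):
            refit_selected(greyhound_with_signal, [])
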