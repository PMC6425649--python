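"""Risk-model selection: stepwise-forward Firth and L1 (LASSO) with AIC.

Two routes to a parsimonious multi-marker risk model over a pool of
candidate markers, both on the no-intercept genotype-class design:

* stepwise forward selection under Firth estimation, entering and removing
  whole marker blocks (all genotype-level columns of a marker together) by
  penalized likelihood-ratio tests at 0.05 in / 0.05 out;
* an L1-penalized logistic path over a descending lambda grid, the model
  chosen by lowest AIC (2k - 2*l at the penalized estimate, k = nonzero
  coefficients), then refitted by plain Firth on the selected support.

Both are deterministic given the data and candidate order (ties break
toward the earlier candidate / the sparser model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_array, check_is_fitted

from .firth import (
    DesignMatrix,
    FirthLogisticRegression,
    build_design,
    constrained_firth_pll,
    odds_ratios,
)
from scipy import stats
from .io import Cohort


@dataclass
class ModelSpec:
    """Outcome of a selection run: the terms and the add/remove trace."""

    selected_terms: list[str]
    selection_method: str
    selection_trace: list[dict] = field(default_factory=list)

    def replay(self) -> list[str]:
        """Apply the recorded events to an empty model (sanity check)."""
        terms: list[str] = []
        for ev in self.selection_trace:
            if ev["action"] == "add":
                terms.append(ev["term"])
            elif ev["action"] == "remove":
                terms.remove(ev["term"])
        return terms


class StepwiseFirthSelector(BaseEstimator):
    """Stepwise-forward selection of column blocks under Firth estimation.

    Operates on a numeric design plus a ``groups`` vector labelling which
    columns form each candidate block (a marker's genotype levels enter
    and leave together).  Entry/removal decisions use the penalized
    likelihood-ratio test between nested Firth fits, df = block width.
    """

    def __init__(
        self,
        alpha_enter: float = 0.05,
        alpha_remove: float = 0.05,
        fit_intercept: bool = False,
        tol: float = 1e-8,
        max_iter: int = 50,
    ):
        self.alpha_enter = alpha_enter
        self.alpha_remove = alpha_remove
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def _fit_subset(self, X, y, cols) -> FirthLogisticRegression:
        key = tuple(cols)
        if key not in self._cache:
            est = FirthLogisticRegression(
                fit_intercept=self.fit_intercept, tol=self.tol, max_iter=self.max_iter
            )
            self._cache[key] = est.fit(X[:, list(cols)], y)
        return self._cache[key]

    def _block_p(self, X, y, cols_full, block) -> float:
        """Penalized LRT p-value of one term block within a column set.

        The constrained fit zeroes the block's coefficients while keeping
        the full design's Jeffreys penalty, so the statistic is free of the
        penalty's dimension bias.
        """
        key = (tuple(cols_full), tuple(block))
        if key not in self._p_cache:
            fit_full = self._fit_subset(X, y, cols_full)
            Xs = X[:, list(cols_full)]
            free = [i for i, c in enumerate(cols_full) if c not in set(block)]
            pll0 = constrained_firth_pll(Xs, y, free, tol=self.tol,
                                         max_iter=self.max_iter)
            stat = max(2.0 * (fit_full.penalized_loglik_ - pll0), 0.0)
            self._p_cache[key] = float(stats.chi2.sf(stat, df=len(block)))
        return self._p_cache[key]

    def fit(self, X, y, groups: Sequence | None = None):
        X = check_array(X, dtype=np.float64, ensure_min_features=0)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if groups is None:
            groups = np.arange(p)
        groups = np.asarray(groups, dtype=object)
        if groups.shape[0] != p:
            raise ValueError("groups must label every column")
        order: list = list(dict.fromkeys(groups.tolist()))
        block_cols = {g: tuple(np.flatnonzero(groups == g)) for g in order}

        self._cache: dict[tuple, FirthLogisticRegression] = {}
        self._p_cache: dict[tuple, float] = {}
        selected: list = []
        trace: list[dict] = []
        if not order:
            warnings.warn("empty candidate pool; returning the null model", stacklevel=2)
        seen_states: set[tuple] = set()
        while True:
            state = tuple(sorted(map(str, selected)))
            if state in seen_states:
                break  # add/remove cycle guard
            seen_states.add(state)
            cur_cols = tuple(c for g in selected for c in block_cols[g])
            # entry step
            best_g, best_p = None, None
            for g in order:
                if g in selected:
                    continue
                cols = cur_cols + block_cols[g]
                try:
                    pval = self._block_p(X, y, cols, block_cols[g])
                except np.linalg.LinAlgError:
                    continue
                if best_p is None or pval < best_p:
                    best_g, best_p = g, pval
            added = False
            if best_g is not None and best_p < self.alpha_enter:
                selected.append(best_g)
                trace.append({"action": "add", "term": best_g, "p": best_p})
                added = True
            # removal sweep: drop terms whose block p rose above alpha_remove
            removed_any = True
            while removed_any and selected:
                removed_any = False
                cur_cols = tuple(c for g in selected for c in block_cols[g])
                worst_g, worst_p = None, -1.0
                for g in selected:
                    pval = self._block_p(X, y, cur_cols, block_cols[g])
                    if pval > worst_p:
                        worst_g, worst_p = g, pval
                if worst_p >= self.alpha_remove:
                    selected.remove(worst_g)
                    trace.append({"action": "remove", "term": worst_g, "p": worst_p})
                    removed_any = True
            if not added:
                break

        self.selected_groups_ = list(selected)
        cols = tuple(c for g in selected for c in block_cols[g])
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[list(cols)] = True
        self.trace_ = trace
        self.estimator_ = self._fit_subset(X, y, cols)
        del self._cache, self._p_cache
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_


@dataclass
class LassoPath:
    """L1 logistic path with per-lambda AIC."""

    lambda_grid: np.ndarray  # decreasing
    coef_path: np.ndarray  # (n_lambda, p), original scale
    aic: np.ndarray
    loglik: np.ndarray  # unpenalized log-likelihood at each estimate
    converged: np.ndarray
    chosen_index: int

    @property
    def chosen_lambda(self) -> float:
        return float(self.lambda_grid[self.chosen_index])

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(np.abs(self.coef_path[self.chosen_index]) > 0)


class LassoAICLogistic(BaseEstimator):
    """No-intercept L1-penalized logistic path with AIC model choice.

    Minimizes ``-l(beta)/n + lambda * ||beta||_1`` over a log-spaced grid
    from ``lambda_max`` (the smallest lambda with empty support, from the
    gradient at beta = 0) down to ``lambda_max * lambda_min_ratio``, with
    warm starts from large to small lambda.  Columns are standardized to
    unit variance before penalization and coefficients returned on the
    original scale.  AIC(lambda) = 2k - 2l with k the nonzero count and l
    the *unpenalized* log-likelihood at the penalized estimate; ties break
    toward larger lambda (the sparser model).
    """

    def __init__(
        self,
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-4,
        standardize: bool = True,
        tol: float = 1e-8,
        max_iter: int = 20000,
    ):
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.standardize = standardize
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _loglik(X, y, beta) -> float:
        eta = X @ beta
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    def fit(self, X, y, lambda_grid: np.ndarray | None = None):
        X = check_array(X, dtype=np.float64)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        scale = X.std(axis=0)
        if self.standardize:
            if (scale == 0).any():
                raise ValueError("constant column in design; prune before fitting")
            Xs = X / scale
        else:
            Xs, scale = X, np.ones(p)

        if lambda_grid is None:
            # subgradient condition at beta = 0 (pi = 1/2, no intercept)
            lam_max = np.max(np.abs(Xs.T @ (y - 0.5))) / n
            lam_max = max(lam_max, 1e-12)
            lambda_grid = np.geomspace(
                lam_max, lam_max * self.lambda_min_ratio, self.n_lambdas
            )
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        if (np.diff(lambda_grid) > 0).any():
            raise ValueError("lambda_grid must be decreasing")

        est = LogisticRegression(
            penalty="l1",
            solver="saga",
            fit_intercept=False,
            warm_start=True,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        coefs = np.zeros((lambda_grid.size, p))
        loglik = np.zeros(lambda_grid.size)
        converged = np.ones(lambda_grid.size, dtype=bool)
        for i, lam in enumerate(lambda_grid):
            est.set_params(C=1.0 / (n * lam))
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                est.fit(Xs, y)
            if any("onverge" in str(w.message) for w in caught):
                converged[i] = False
            beta_std = est.coef_.ravel().copy()
            beta_std[np.abs(beta_std) < 1e-10] = 0.0
            beta = beta_std / scale
            coefs[i] = beta
            loglik[i] = self._loglik(X, y, beta)
        k = (coefs != 0).sum(axis=1)
        aic = 2.0 * k - 2.0 * loglik
        # argmin with ties toward larger lambda (earlier index)
        chosen = int(np.argmin(np.round(aic, 10)))

        self.lambda_grid_ = lambda_grid
        self.coef_path_ = coefs
        self.aic_ = aic
        self.loglik_ = loglik
        self.converged_ = converged
        self.chosen_index_ = chosen
        self.coef_ = coefs[chosen]
        self.support_ = np.abs(coefs[chosen]) > 0
        self.n_features_in_ = p
        return self

    def path(self) -> LassoPath:
        check_is_fitted(self, "coef_path_")
        return LassoPath(
            lambda_grid=self.lambda_grid_,
            coef_path=self.coef_path_,
            aic=self.aic_,
            loglik=self.loglik_,
            converged=self.converged_,
            chosen_index=self.chosen_index_,
        )


# -- cohort-level wrappers --------------------------------------------------

def stepwise_forward(
    cohort: Cohort,
    candidate_markers: Sequence[str],
    covariates: Sequence[str] = (),
    alpha_in: float = 0.05,
    alpha_out: float = 0.05,
    include_missing_level: bool = True,
) -> tuple[ModelSpec, FirthLogisticRegression, DesignMatrix]:
    """Stepwise-forward Firth selection of whole markers on a cohort.

    Candidate markers (and any cohort/sex covariates) enter as blocks of
    genotype-level indicator columns; returns the model spec with its
    trace, the final Firth fit, and the full candidate design.
    """
    design = build_design(
        cohort,
        list(candidate_markers) + [],
        covariates=covariates,
        include_missing_level=include_missing_level,
    )
    groups = np.array([c.term for c in design.columns], dtype=object)
    sel = StepwiseFirthSelector(alpha_enter=alpha_in, alpha_remove=alpha_out)
    sel.fit(design.X, design.y, groups=groups)
    spec = ModelSpec(
        selected_terms=list(sel.selected_groups_),
        selection_method="stepwise",
        selection_trace=sel.trace_,
    )
    return spec, sel.estimator_, design


def lasso_path(
    cohort: Cohort,
    candidate_markers: Sequence[str],
    covariates: Sequence[str] = (),
    lambda_grid: np.ndarray | None = None,
    include_missing_level: bool = True,
    **lasso_kwargs,
) -> tuple[LassoPath, DesignMatrix]:
    """L1 logistic path over the candidate-marker class design."""
    design = build_design(
        cohort,
        list(candidate_markers),
        covariates=covariates,
        include_missing_level=include_missing_level,
    )
    est = LassoAICLogistic(**lasso_kwargs)
    est.fit(design.X, design.y, lambda_grid=lambda_grid)
    return est.path(), design


def select_by_aic(path: LassoPath, design: DesignMatrix) -> list[str]:
    """Marker terms selected at the AIC-optimal lambda.

    A marker counts as selected when any of its genotype-level columns is
    nonzero at the chosen lambda.
    """
    support_cols = path.support
    terms: list[str] = []
    for j in support_cols:
        t = design.columns[j].term
        if t not in terms:
            terms.append(t)
    return terms


def refit_selected(
    cohort: Cohort,
    support: Sequence[str],
    covariates: Sequence[str] = (),
    include_missing_level: bool = True,
    level: float = 0.95,
):
    """Plain Firth refit of a selected term set (no further selection).

    Returns ``(fit, design, or_table)``; empty support is an error (use
    the null model explicitly instead).
    """
    terms = [t for t in support if t not in ("cohort", "sex")]
    covs = list(covariates) + [t for t in support if t in ("cohort", "sex") and t not in covariates]
    if not terms and not covs:
        raise ValueError("empty support: nothing to refit (null model)")
    design = build_design(
        cohort, terms, covariates=covs, include_missing_level=include_missing_level
    )
    fit = FirthLogisticRegression().fit(design.X, design.y)
    table = odds_ratios(fit, design, level=level)
    return fit, design, table
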