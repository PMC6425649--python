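"""Firth penalized-likelihood logistic regression on genotype-class designs.

Fits logistic models (by default with *no intercept*, matching the
risk-model convention used throughout this package) by maximizing the
Jeffreys-penalized log-likelihood

    l*(beta) = l(beta) + 1/2 * ln det I(beta),

where ``I`` is the Fisher information.  Newton iterations use the modified
score

    U*_r = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ir,

with ``h_i`` the hat-matrix diagonal of W^{1/2} X (X'WX)^{-1} X' W^{1/2}
and ``W = diag(pi_i (1 - pi_i))``; step-halving enforces a non-decreasing
penalized log-likelihood.  The penalized estimate exists and is finite for
any design with both outcome classes present — including completely or
quasi-completely separated data, where ordinary maximum likelihood
diverges.  Separation is diagnosed explicitly by linear programming and
flagged on the affected terms.

Genotype terms enter as class (indicator) variables: one 0/1 column per
non-reference genotype level (AB, BB and, when requested, an explicit
"missing" level), with the 0 (AA) genotype as reference, so each
coefficient is the log odds ratio of that genotype level versus AA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .io import MISSING, Cohort

SeparationFlag = Literal["none", "quasi", "complete"]

_LEVEL_NAME = {0: "AA", 1: "AB", 2: "BB", MISSING: "missing"}


class SingularDesignError(np.linalg.LinAlgError):
    pass


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of columns not in a pivoted-QR basis (candidates for collinearity)."""
    if X.shape[1] == 0:
        return []
    from scipy.linalg import qr

    r = np.linalg.matrix_rank(X)
    _, _, piv = qr(X, pivoting=True, mode="economic")
    return sorted(piv[r:].tolist())


class FirthLogisticRegression(BaseEstimator, ClassifierMixin):
    """Logistic regression with Firth's bias-reducing penalty.

    Parameters
    ----------
    fit_intercept : bool, default False
        The genotype-class risk models are fitted with no intercept; set
        True for conventional designs.
    tol : float
        Convergence on both the max modified-score component and the step
        norm.
    max_iter, max_halvings : int
        Newton iteration and step-halving budgets.

    Attributes (after ``fit``)
    --------------------------
    coef_ : (p,) coefficients on the log-odds scale (intercept excluded).
    intercept_ : float (0.0 when ``fit_intercept=False``).
    cov_ : (p*, p*) inverse Fisher information at the estimate (intercept
        column last when fitted).
    hat_diag_, fitted_prob_ : per-training-sample leverages and probabilities.
    loglik_, penalized_loglik_ : unpenalized / penalized log-likelihood.
    n_iter_, converged_ : Newton bookkeeping.
    """

    def __init__(
        self,
        fit_intercept: bool = False,
        tol: float = 1e-8,
        max_iter: int = 50,
        max_halvings: int = 25,
        check_separation: bool = False,
    ):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.max_halvings = max_halvings
        self.check_separation = check_separation

    # -- core numerics ---------------------------------------------------
    @staticmethod
    def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
        # numerically safe Bernoulli log-likelihood: sum y*eta - log(1+e^eta)
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    @staticmethod
    def _penalty(Xw: np.ndarray) -> float:
        M = Xw.T @ Xw
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf
        return 0.5 * logdet

    def _pll(self, X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
        eta = X @ beta
        pi = expit(eta)
        w = np.sqrt(pi * (1.0 - pi))
        return self._loglik(y, eta) + self._penalty(X * w[:, None])

    def fit(self, X, y):
        if hasattr(X, "columns"):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        X = check_array(X, dtype=np.float64, ensure_min_features=0)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"y must have exactly 2 classes, got {classes}")
        self.classes_ = classes
        yb = (y == classes[1]).astype(float)
        n, p = X.shape
        self.n_features_in_ = p
        Xd = np.hstack([X, np.ones((n, 1))]) if self.fit_intercept else X
        k = Xd.shape[1]

        beta = np.zeros(k)
        if k == 0:
            # degenerate no-term model: all probabilities 1/2
            self.coef_ = np.zeros(0)
            self.intercept_ = 0.0
            self.cov_ = np.zeros((0, 0))
            self.fitted_prob_ = np.full(n, 0.5)
            self.hat_diag_ = np.zeros(n)
            self.loglik_ = self._loglik(yb, np.zeros(n))
            self.penalized_loglik_ = self.loglik_
            self.n_iter_ = 0
            self.converged_ = True
            self.separation_ = np.zeros(0, dtype=object)
            return self

    # Newton iterations with modified score and step-halving
        pll = self._pll(Xd, yb, beta)
        if not np.isfinite(pll):
            bad = _collinear_columns(Xd)
            raise SingularDesignError(
                f"singular information matrix; collinear columns: {bad}"
            )
        converged = False
        it = 0
        stalled = 0
        for it in range(1, self.max_iter + 1):
            eta = Xd @ beta
            pi = expit(eta)
            w = pi * (1.0 - pi)
            Xw = Xd * w[:, None]
            M = Xd.T @ Xw
            try:
                Minv_Xt = np.linalg.solve(M, Xd.T)
            except np.linalg.LinAlgError as err:
                bad = _collinear_columns(Xd)
                raise SingularDesignError(
                    f"singular information matrix; collinear columns: {bad}"
                ) from err
            h = w * np.einsum("ij,ji->i", Xd, Minv_Xt)
            score = Xd.T @ (yb - pi + h * (0.5 - pi))
            step = np.linalg.solve(M, score)
            s = 1.0
            for _ in range(self.max_halvings + 1):
                new_beta = beta + s * step
                new_pll = self._pll(Xd, yb, new_beta)
                if new_pll >= pll - 1e-12:
                    break
                s *= 0.5
            pll_change = abs(new_pll - pll)
            beta, pll = new_beta, new_pll
            grad = np.max(np.abs(score))
            if grad < self.tol and (
                np.linalg.norm(s * step) < self.tol or pll_change < 1e-12
            ):
                converged = True
                break
            # Ill-conditioned class designs can pin the achievable gradient
            # above tol in double precision while the penalized
            # log-likelihood is already stationary; accept the numerical
            # optimum once it has been stationary for several iterations
            # and the gradient is below a floor comparable to standard
            # Firth implementations.
            stalled = stalled + 1 if pll_change < 1e-12 else 0
            if stalled >= 3 and grad < 1e-5:
                converged = True
                break

        eta = Xd @ beta
        pi = expit(eta)
        w = pi * (1.0 - pi)
        M = Xd.T @ (Xd * w[:, None])
        Minv = np.linalg.inv(M)
        h = w * np.einsum("ij,jk,ik->i", Xd, Minv, Xd)

        self.converged_ = converged
        self.n_iter_ = it
        if self.fit_intercept:
            self.coef_ = beta[:-1].copy()
            self.intercept_ = float(beta[-1])
        else:
            self.coef_ = beta.copy()
            self.intercept_ = 0.0
        self.cov_ = Minv
        self.fitted_prob_ = pi
        self.hat_diag_ = h
        self.loglik_ = self._loglik(yb, eta)
        self.penalized_loglik_ = float(pll)
        self.separation_ = detect_separation(X, yb) if self.check_separation else None
        if not converged:
            warnings.warn(
                f"Firth fit did not converge in {self.max_iter} iterations",
                stacklevel=2,
            )
        return self

    # -- prediction ------------------------------------------------------
    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=np.float64, ensure_min_features=0)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p1 = expit(self.decision_function(X))
        return np.where(p1 > 0.5, self.classes_[1], self.classes_[0])


def fit_firth(X, y, **kwargs) -> FirthLogisticRegression:
    """Functional wrapper over :class:`FirthLogisticRegression`."""
    return FirthLogisticRegression(**kwargs).fit(X, y)


def penalized_lrt(
    fit_full: FirthLogisticRegression,
    fit_reduced: FirthLogisticRegression,
    df: int,
) -> tuple[float, float]:
    """Penalized likelihood-ratio test between two already-fitted models.

    Note: comparing penalized log-likelihoods of designs with *different*
    column counts carries a dimension bias from the Jeffreys penalty; for
    testing a block of columns within a model use :func:`firth_block_test`,
    which evaluates the constrained model under the full design's penalty.
    """
    stat = 2.0 * (fit_full.penalized_loglik_ - fit_reduced.penalized_loglik_)
    stat = max(stat, 0.0)
    return stat, float(stats.chi2.sf(stat, df=df))


def constrained_firth_pll(
    X: np.ndarray,
    y: np.ndarray,
    free_cols,
    tol: float = 1e-8,
    max_iter: int = 50,
    max_halvings: int = 25,
) -> float:
    """Maximum penalized log-likelihood with some coefficients fixed at 0.

    The Jeffreys penalty (and the hat diagonals in the modified score) are
    always evaluated on the *full* design ``X``, while only ``free_cols``
    coefficients are updated.  This is the constrained fit needed by the
    penalized likelihood-ratio test: both hypotheses share the same penalty
    structure, so its dimension dependence cancels from the statistic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    free = np.asarray(sorted(free_cols), dtype=int)
    beta = np.zeros(k)

    def pll(b):
        eta = X @ b
        pi = expit(eta)
        w = np.sqrt(pi * (1.0 - pi))
        M = (X * w[:, None]).T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * logdet)

    cur = pll(beta)
    if not np.isfinite(cur):
        raise SingularDesignError(
            f"singular information matrix; collinear columns: {_collinear_columns(X)}"
        )
    if free.size == 0:
        return cur
    Xf = X[:, free]
    stalled = 0
    for _ in range(max_iter):
        eta = X @ beta
        pi = expit(eta)
        w = pi * (1.0 - pi)
        M_full = X.T @ (X * w[:, None])
        h = w * np.einsum("ij,ji->i", X, np.linalg.solve(M_full, X.T))
        score = Xf.T @ (y - pi + h * (0.5 - pi))
        M_free = Xf.T @ (Xf * w[:, None])
        step = np.linalg.solve(M_free, score)
        s = 1.0
        for _ in range(max_halvings + 1):
            new_beta = beta.copy()
            new_beta[free] += s * step
            new_pll = pll(new_beta)
            if new_pll >= cur - 1e-12:
                break
            s *= 0.5
        change = abs(new_pll - cur)
        beta, cur = new_beta, new_pll
        grad = np.max(np.abs(score))
        if grad < tol and (np.linalg.norm(s * step) < tol or change < 1e-12):
            break
        stalled = stalled + 1 if change < 1e-12 else 0
        if stalled >= 3 and grad < 1e-5:
            break
    return cur


def firth_block_test(
    X: np.ndarray,
    y: np.ndarray,
    block_cols,
    fit_full: FirthLogisticRegression | None = None,
    **fit_kwargs,
) -> tuple[float, float]:
    """Penalized likelihood-ratio test of a column block within a design.

    Compares the full Firth fit of ``X`` against the constrained maximum
    with the block's coefficients fixed at 0 (penalty evaluated on the full
    design in both cases); the statistic is referred to chi-square with
    df = block width.
    """
    block = set(int(c) for c in block_cols)
    if fit_full is None:
        fit_full = FirthLogisticRegression(**fit_kwargs).fit(X, y)
    free = [j for j in range(X.shape[1]) if j not in block]
    pll0 = constrained_firth_pll(X, y, free)
    stat = max(2.0 * (fit_full.penalized_loglik_ - pll0), 0.0)
    return stat, float(stats.chi2.sf(stat, df=len(block)))


def wald_ci(
    fit: FirthLogisticRegression, level: float = 0.95
) -> pd.DataFrame:
    """Wald confidence intervals for the fitted coefficients (and their ORs)."""
    check_is_fitted(fit, "coef_")
    if not fit.converged_:
        raise ValueError("confidence intervals require a converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    k = fit.coef_.size
    se = np.sqrt(np.diag(fit.cov_))[:k]
    lo = fit.coef_ - z * se
    hi = fit.coef_ + z * se
    return pd.DataFrame(
        {
            "beta": fit.coef_,
            "se": se,
            "ci_low": lo,
            "ci_high": hi,
            "or": np.exp(fit.coef_),
            "or_ci_low": np.exp(lo),
            "or_ci_high": np.exp(hi),
        }
    )


# -- separation diagnostics ----------------------------------------------

def detect_separation(X, y, tol: float = 1e-7) -> np.ndarray:
    """Per-column separation flags ('none' / 'quasi' / 'complete').

    Linear-feasibility check: *complete* separation exists when some
    direction ``b`` gives a strictly positive margin ``z_i x_i b`` for
    every sample (``z = +-1`` by class); *quasi* when the margins can be
    made non-negative with at least one strictly positive.  Flags attach
    to the columns supporting the separating direction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    flags = np.array(["none"] * p, dtype=object)
    if p == 0 or n == 0:
        return flags
    z = 2.0 * y - 1.0
    Z = z[:, None] * X

    # LP 1: maximize worst margin t subject to Z b >= t, |b| <= 1
    c = np.zeros(p + 1)
    c[-1] = -1.0
    A_ub = np.hstack([-Z, np.ones((n, 1))])
    b_ub = np.zeros(n)
    bounds = [(-1, 1)] * p + [(None, 1)]
    res = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status == 0 and -res.fun > tol:
        b = res.x[:p]
        flags[np.abs(b) > tol] = "complete"
        return flags

    # LP 2: maximize total margin subject to Z b >= 0, |b| <= 1
    c2 = -Z.sum(axis=0)
    res2 = optimize.linprog(
        c2, A_ub=-Z, b_ub=np.zeros(n), bounds=[(-1, 1)] * p, method="highs"
    )
    if res2.status == 0 and -res2.fun > tol:
        b = res2.x
        flags[np.abs(b) > tol] = "quasi"
    return flags


# -- genotype-class design matrices ----------------------------------------

@dataclass
class DesignColumn:
    term: str  # marker_id or covariate name
    level: str  # genotype level (AB/BB/missing) or covariate level


@dataclass
class DesignMatrix:
    """No-intercept indicator design over genotype-class terms."""

    X: np.ndarray
    y: np.ndarray
    columns: list[DesignColumn]
    sample_ids: list[str]
    pruned: list[str] = field(default_factory=list)

    @property
    def column_labels(self) -> list[str]:
        return [f"{c.term}[{c.level}]" for c in self.columns]

    def term_blocks(self) -> dict[str, list[int]]:
        """Column indices grouped by term, in column order."""
        blocks: dict[str, list[int]] = {}
        for j, c in enumerate(self.columns):
            blocks.setdefault(c.term, []).append(j)
        return blocks

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.column_labels)


def build_design(
    cohort: Cohort,
    terms: Sequence[str],
    covariates: Sequence[str] = (),
    include_missing_level: bool = True,
    reference_level: int | None = 0,
) -> DesignMatrix:
    """Indicator (class-variable) design for the listed marker terms.

    Each marker contributes one 0/1 column per observed non-reference
    genotype level; missing calls get their own "missing" level when
    ``include_missing_level`` (otherwise samples missing any term genotype
    are dropped).  ``cohort`` and ``sex`` covariates enter as class
    indicators against their first observed level.  Constant and duplicate
    columns are pruned with a log record.  No intercept column is added.

    ``reference_level=None`` keeps a column for *every* observed level
    (full-rank only for a single marker with no intercept); under
    case/control ascertainment the odds ratio versus the reference is then
    the estimable level contrast exp(beta_level - beta_reference), free of
    the sampling offset the reference-dropped coding absorbs.
    """
    if reference_level not in (0, 1, 2, None):
        raise ValueError("reference_level must be a genotype code 0, 1, 2 or None")
    marker_pos = {m.marker_id: j for j, m in enumerate(cohort.markers)}
    absent = [t for t in terms if t not in marker_pos]
    if absent:
        raise ValueError(f"terms not present in cohort: {absent}")

    pheno = cohort.phenotype_array()
    keep = pheno != MISSING
    if not include_missing_level and terms:
        cols_idx = [marker_pos[t] for t in terms]
        keep &= (cohort.genotypes[:, cols_idx] != MISSING).all(axis=1)
    idx = np.flatnonzero(keep)
    y = pheno[idx].astype(float)
    G = cohort.genotypes[idx]

    columns: list[DesignColumn] = []
    data: list[np.ndarray] = []
    pruned: list[str] = []
    ref_name = "(none)" if reference_level is None else _LEVEL_NAME[reference_level]

    for t in terms:
        g = G[:, marker_pos[t]]
        added = 0
        for level in (0, 1, 2, MISSING):
            if level == reference_level:
                continue
            if level == MISSING and not include_missing_level:
                continue
            col = (g == level).astype(float)
            if col.sum() == 0:
                continue
            if col.sum() == len(col):
                pruned.append(f"{t}[{_LEVEL_NAME.get(level, str(level))}]: constant")
                continue
            columns.append(DesignColumn(t, _LEVEL_NAME.get(level, str(level))))
            data.append(col)
            added += 1
        if added == 0:
            warnings.warn(
                f"marker {t}: all samples at reference level {ref_name}; term dropped",
                stacklevel=2,
            )

    for cov in covariates:
        if cov == "cohort":
            values = np.array([cohort.samples[i].cohort for i in idx])
        elif cov == "sex":
            values = np.array([cohort.samples[i].sex for i in idx])
        else:
            raise ValueError(f"unknown covariate {cov!r} (use 'cohort' or 'sex')")
        levels = list(dict.fromkeys(values))
        for lev in levels[1:]:
            col = (values == lev).astype(float)
            if 0 < col.sum() < len(col):
                columns.append(DesignColumn(cov, str(lev)))
                data.append(col)
            else:
                pruned.append(f"{cov}[{lev}]: constant")

    X = np.column_stack(data) if data else np.empty((len(idx), 0))
    # duplicate-column pruning
    keep_cols, seen = [], {}
    for j in range(X.shape[1]):
        key = X[:, j].tobytes()
        if key in seen:
            pruned.append(
                f"{columns[j].term}[{columns[j].level}]: duplicate of "
                f"{columns[seen[key]].term}[{columns[seen[key]].level}]"
            )
        else:
            seen[key] = j
            keep_cols.append(j)
    X = X[:, keep_cols]
    columns = [columns[j] for j in keep_cols]
    return DesignMatrix(
        X=X,
        y=y,
        columns=columns,
        sample_ids=[cohort.samples[i].sample_id for i in idx],
        pruned=pruned,
    )


def level_contrast_ci(
    fit: FirthLogisticRegression,
    design: DesignMatrix,
    term: str,
    level: str,
    reference: str = "AA",
    conf: float = 0.95,
) -> tuple[float, float, float]:
    """Wald CI for the log odds ratio of one genotype level vs another.

    For an all-levels (``reference_level=None``) design the contrast
    ``beta_level - beta_reference`` is the estimable log OR under
    case/control ascertainment (both coefficients share the sampling
    offset, which cancels).  Returns ``(log_or, ci_low, ci_high)``.
    """
    labels = [(c.term, c.level) for c in design.columns]
    j = labels.index((term, level))
    k = labels.index((term, reference))
    diff = fit.coef_[j] - fit.coef_[k]
    var = fit.cov_[j, j] + fit.cov_[k, k] - 2.0 * fit.cov_[j, k]
    z = stats.norm.ppf(0.5 + conf / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(diff), float(diff - half), float(diff + half)


def odds_ratios(
    fit: FirthLogisticRegression, design: DesignMatrix, level: float = 0.95
) -> pd.DataFrame:
    """Per-level odds-ratio table with Wald CIs and separation annotation.

    Each coefficient is the OR of its genotype level versus the reference,
    holding the other terms constant.  Rows whose columns support a
    separating direction are flagged: their finite Firth estimate is kept
    but marked as suggestive of large effects and not reliably estimable.
    """
    ci = wald_ci(fit, level=level)
    flags = detect_separation(design.X, design.y)
    rows = []
    for j, col in enumerate(design.columns):
        flag = flags[j] if j < len(flags) else "none"
        rows.append(
            {
                "term": col.term,
                "level": col.level,
                "beta": ci["beta"].iloc[j],
                "or": ci["or"].iloc[j],
                "ci_low": ci["or_ci_low"].iloc[j],
                "ci_high": ci["or_ci_high"].iloc[j],
                "separation": flag,
                "estimable": flag == "none",
                "note": "" if flag == "none" else "suggestive of large effects",
            }
        )
    return pd.DataFrame(rows)
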