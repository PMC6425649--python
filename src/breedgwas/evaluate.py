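"""Fit statistics, calibration and independent-cohort validation.

Model quality is summarized the way clinical logistic risk models usually
are: Cox-Snell R2 and its max-rescaled (Nagelkerke) version, AIC, the
Hosmer-Lemeshow calibration chi-square over deciles of fitted risk, and
the percent of correct calls at a 0.5 probability cutoff.  All likelihoods
entering R2 and AIC are *unpenalized* log-likelihoods evaluated at the
(Firth) estimate, and the null model for the no-intercept convention is
beta = 0, i.e. all fitted probabilities 1/2.

Validation against an independent cohort is refit-validation: the fixed
selected term set is refitted by Firth on the new cohort (no selection)
and the same statistics reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .firth import FirthLogisticRegression, build_design
from .io import Cohort
from .selection import ModelSpec


@dataclass
class EvalReport:
    cox_snell_r2: float
    max_rescaled_r2: float
    aic: float
    hl_statistic: float
    hl_df: int
    hl_p: float
    percent_correct: float
    n_used: int
    n_parameters: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def null_loglik_no_intercept(n: int) -> float:
    """Unpenalized log-likelihood of the no-intercept null (all pi = 1/2)."""
    return n * np.log(0.5)


def max_rescaled_r2(
    loglik_fitted: float, null_loglik: float, n: int
) -> tuple[float, float]:
    """Cox-Snell and max-rescaled (Nagelkerke) R2.

    ``cox_snell = 1 - exp(-(2/n)(l1 - l0))``; the rescaling divides by the
    maximum attainable Cox-Snell value ``1 - exp((2/n) l0)``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    cs = 1.0 - np.exp(-(2.0 / n) * (loglik_fitted - null_loglik))
    denom = 1.0 - np.exp((2.0 / n) * null_loglik)
    return float(cs), float(cs / denom)


def hosmer_lemeshow(
    fitted_prob: np.ndarray, y: np.ndarray, groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration test over deciles of fitted risk.

    Samples are sorted by fitted probability and cut into ``groups``
    near-equal groups, keeping tied probabilities together.  The statistic
    is ``sum_g (O_g - E_g)^2 / (E_g (1 - E_g / n_g))`` with df = groups - 2
    after merging any group whose expected count is degenerate (E = 0 or
    E = n) into its neighbor.
    """
    p = np.asarray(fitted_prob, dtype=float)
    y = np.asarray(y, dtype=float)
    n = p.size
    if n < groups:
        raise ValueError(f"need at least {groups} samples")
    order = np.argsort(p, kind="stable")
    p_s, y_s = p[order], y[order]
    # target cut points; shift boundaries forward so ties stay together
    bounds = [round(n * g / groups) for g in range(1, groups)]
    cuts = [0]
    for b in bounds:
        while 0 < b < n and p_s[b] == p_s[b - 1]:
            b += 1
        if b > cuts[-1] and b < n:
            cuts.append(b)
    cuts.append(n)

    obs, exp, sizes = [], [], []
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        obs.append(y_s[lo:hi].sum())
        exp.append(p_s[lo:hi].sum())
        sizes.append(hi - lo)
    obs, exp, sizes = map(np.asarray, (obs, exp, sizes))

    # merge degenerate groups (E = 0 or E = n) with a neighbor
    while len(obs) > 2:
        bad = np.flatnonzero((exp <= 1e-12) | (exp >= sizes - 1e-12))
        if bad.size == 0:
            break
        i = bad[0]
        j = i - 1 if i > 0 else i + 1
        warnings.warn(
            "degenerate Hosmer-Lemeshow group merged with neighbor", stacklevel=2
        )
        keep = np.ones(len(obs), dtype=bool)
        keep[i] = False
        obs[j] += obs[i]
        exp[j] += exp[i]
        sizes[j] += sizes[i]
        obs, exp, sizes = obs[keep], exp[keep], sizes[keep]

    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (obs - exp) ** 2 / (exp * (1.0 - exp / sizes))
    stat = float(np.nansum(contrib))
    df = max(len(obs) - 2, 1)
    return stat, df, float(stats.chi2.sf(stat, df=df))


def percent_correct(
    fitted_prob: np.ndarray, y: np.ndarray, cutoff: float = 0.5
) -> float:
    """Percent of correct case/control calls (predicted case iff p > cutoff)."""
    p = np.asarray(fitted_prob, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.size == 0:
        raise ValueError("no samples")
    pred = (p > cutoff).astype(float)
    return float(100.0 * np.mean(pred == y))


def evaluate_fit(
    fit: FirthLogisticRegression,
    y: np.ndarray | None = None,
    fitted_prob: np.ndarray | None = None,
    groups: int = 10,
    cutoff: float = 0.5,
) -> EvalReport:
    """Full evaluation report for a fitted risk model on its own data."""
    if fitted_prob is None:
        fitted_prob = fit.fitted_prob_
    if y is None:
        raise ValueError("y is required")
    y = np.asarray(y, dtype=float)
    n = y.size
    k = fit.coef_.size + (1 if fit.fit_intercept else 0)
    l0 = null_loglik_no_intercept(n)
    cs, mr = max_rescaled_r2(fit.loglik_, l0, n)
    hl_stat, hl_df, hl_p = hosmer_lemeshow(fitted_prob, y, groups=groups)
    return EvalReport(
        cox_snell_r2=cs,
        max_rescaled_r2=mr,
        aic=2.0 * k - 2.0 * fit.loglik_,
        hl_statistic=hl_stat,
        hl_df=hl_df,
        hl_p=hl_p,
        percent_correct=percent_correct(fitted_prob, y, cutoff=cutoff),
        n_used=n,
        n_parameters=k,
    )


def validate(
    model: ModelSpec | Sequence[str],
    new_cohort: Cohort,
    covariates: Sequence[str] = (),
    include_missing_level: bool = True,
) -> tuple[EvalReport, FirthLogisticRegression]:
    """Refit-validate a selected model on an independent cohort.

    The fixed term set is refitted by Firth on the new cohort (no selection
    step) and evaluated there.  All model terms must exist in the new
    cohort's marker map.
    """
    terms = list(model.selected_terms) if isinstance(model, ModelSpec) else list(model)
    marker_terms = [t for t in terms if t not in ("cohort", "sex")]
    present = set(new_cohort.marker_ids)
    absent = [t for t in marker_terms if t not in present]
    if absent:
        raise ValueError(f"validation cohort lacks model terms: {absent}")
    covs = list(covariates) + [t for t in terms if t in ("cohort", "sex")]
    design = build_design(
        new_cohort,
        marker_terms,
        covariates=list(dict.fromkeys(covs)),
        include_missing_level=include_missing_level,
    )
    fit = FirthLogisticRegression().fit(design.X, design.y)
    report = evaluate_fit(fit, y=design.y)
    return report, fit
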