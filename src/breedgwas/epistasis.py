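"""Pairwise marker-marker epistasis scan over a candidate set.

For each unordered marker pair, case/control status is regressed (ordinary
maximum-likelihood logistic, with intercept) on the two allele-dosage
codes and their product; the reported p-value is the Wald test of the
product (interaction) coefficient.  Samples missing either genotype are
excluded pairwise.  Pairs with a degenerate design (monomorphic member,
constant product, separation) are flagged untestable and excluded from the
Bonferroni denominator, which is alpha over the number of testable pairs.

All pairs are fitted simultaneously by a batched Newton solver; a per-pair
ordinary logistic fit gives identical results and serves as the
cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .io import MISSING, Cohort

#: |beta| beyond which an ML interaction fit is treated as divergent
_DIVERGENCE_BOUND = 30.0


def _batched_logistic(
    X: np.ndarray, y: np.ndarray, mask: np.ndarray, max_iter: int = 40, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Newton ML logistic over a (pairs, samples, k) design stack.

    ``mask`` zero-weights excluded samples per pair.  Returns
    ``(beta, se, ok)`` where ``ok`` marks pairs with a converged,
    non-degenerate fit.
    """
    P, n, k = X.shape
    beta = np.zeros((P, k))
    ok = np.ones(P, dtype=bool)
    eye = np.eye(k)
    cov = np.tile(eye, (P, 1, 1))
    for _ in range(max_iter):
        eta = np.einsum("pnk,pk->pn", X, beta)
        pi = expit(eta)
        w = mask * pi * (1.0 - pi)
        XtWX = np.einsum("pnk,pn,pnl->pkl", X, w, X)
        sign, logdet = np.linalg.slogdet(XtWX)
        degenerate = (sign <= 0) | (logdet < -25.0)
        ok &= ~degenerate
        XtWX[degenerate] = eye  # keep the batch solvable
        score = np.einsum("pnk,pn->pk", X, mask * (y[None, :] - pi))
        step = np.linalg.solve(XtWX, score[..., None])[..., 0]
        step[~ok] = 0.0
        beta = beta + step
        if np.max(np.abs(score[ok])) < tol if ok.any() else True:
            break
    # final information for Wald standard errors
    eta = np.einsum("pnk,pk->pn", X, beta)
    pi = expit(eta)
    w = mask * pi * (1.0 - pi)
    XtWX = np.einsum("pnk,pn,pnl->pkl", X, w, X)
    sign, logdet = np.linalg.slogdet(XtWX)
    degenerate = (sign <= 0) | (logdet < -25.0)
    ok &= ~degenerate
    XtWX[degenerate] = eye
    cov = np.linalg.inv(XtWX)
    se = np.sqrt(np.maximum(np.einsum("pkk->pk", cov), 0.0))
    # divergence (separation) and residual non-convergence
    eta2 = np.einsum("pnk,pk->pn", X, beta)
    score = np.einsum("pnk,pn->pk", X, mask * (y[None, :] - expit(eta2)))
    ok &= np.max(np.abs(beta), axis=1) < _DIVERGENCE_BOUND
    ok &= np.max(np.abs(score), axis=1) < 1e-4
    return beta, se, ok


def pairwise_interaction(
    cohort: Cohort, markers: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Interaction scan over all unordered pairs of the listed markers.

    Returns one row per pair with the interaction coefficient, its Wald
    p-value, the testable flag, the Bonferroni threshold over testable
    pairs, and the significance call (p <= threshold).
    """
    markers = list(markers)
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    pos = {m.marker_id: j for j, m in enumerate(cohort.markers)}
    absent = [m for m in markers if m not in pos]
    if absent:
        raise ValueError(f"markers not in cohort: {absent}")
    pheno = cohort.phenotype_array()
    keep = pheno != MISSING
    y = pheno[keep].astype(float)
    if len(np.unique(y)) != 2:
        raise ValueError("both phenotype classes required")
    G = cohort.genotypes[keep][:, [pos[m] for m in markers]].astype(float)
    G[G == MISSING] = np.nan

    pairs = [(i, j) for i in range(len(markers)) for j in range(i + 1, len(markers))]
    P, n = len(pairs), len(y)
    X = np.zeros((P, n, 4))
    mask = np.zeros((P, n))
    for p_idx, (i, j) in enumerate(pairs):
        gi, gj = G[:, i], G[:, j]
        m = ~np.isnan(gi) & ~np.isnan(gj)
        mask[p_idx] = m
        gi0 = np.where(m, gi, 0.0)
        gj0 = np.where(m, gj, 0.0)
        X[p_idx, :, 0] = m.astype(float)  # intercept (masked)
        X[p_idx, :, 1] = gi0
        X[p_idx, :, 2] = gj0
        X[p_idx, :, 3] = gi0 * gj0

    beta, se, ok = _batched_logistic(X, y, mask)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta[:, 3] / se[:, 3]
        pvals = stats.chi2.sf(z**2, df=1)
    pvals = np.where(ok, pvals, np.nan)
    n_testable = int(ok.sum())
    threshold = alpha / n_testable if n_testable else np.nan
    out = pd.DataFrame(
        {
            "marker_i": [markers[i] for i, _ in pairs],
            "marker_j": [markers[j] for _, j in pairs],
            "interaction_beta": np.where(ok, beta[:, 3], np.nan),
            "se": np.where(ok, se[:, 3], np.nan),
            "p_value": pvals,
            "testable": ok,
            "n_pairs_tested": n_testable,
            "bonferroni_threshold": threshold,
        }
    )
    out["significant"] = out["testable"] & (out["p_value"] <= threshold)
    return out
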