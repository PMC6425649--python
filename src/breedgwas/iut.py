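"""Intersection-union-test (IUT) meta-analysis over breed subsets.

For every subset of two or more breeds, each marker's per-breed allelic
p-values are combined two ways: the IUT omnibus p-value (the maximum of
the component p-values — the intersection-union test rejects only when
every component rejects) and Fisher's combined probability
(X = -2 * sum(ln p_i) ~ chi-square with 2k df under the global null for k
independent cohorts).  A marker is a *valid* IUT test for a set only when
every member breed yields a defined association p-value; significance is
called on the Fisher-combined p-value against a per-set Bonferroni
threshold alpha / n_valid, with comparison "<=".
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class BreedSet:
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a breed set needs at least 2 members")

    @property
    def label(self) -> str:
        return "∩".join(sorted(self.members))

    def __iter__(self):
        return iter(sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class IUTThreshold:
    breed_set: BreedSet
    n_valid: int
    alpha: float

    def __post_init__(self) -> None:
        if self.n_valid < 1:
            raise ValueError("n_valid must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_valid


def enumerate_sets(breeds: Sequence[str]) -> list[BreedSet]:
    """All breed subsets of size >= 2, ordered by size then label."""
    labels = list(dict.fromkeys(breeds))
    if len(labels) < 2:
        raise ValueError("need at least 2 breeds")
    out = []
    for k in range(2, len(labels) + 1):
        for combo in itertools.combinations(sorted(labels), k):
            out.append(BreedSet(frozenset(combo)))
    return out


def fisher_combine(ps: Iterable[float]) -> float:
    """Fisher's combined probability of independent p-values.

    ``X = -2 sum(ln p_i)`` referred to the chi-square upper tail with 2k
    degrees of freedom.  A component p of exactly 0 makes the statistic
    diverge; the combined p is then 0 (with a warning).
    """
    p = np.asarray(list(ps), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must be in (0, 1]")
    if (p == 0).any():
        warnings.warn("component p-value of 0; combined p set to 0", stacklevel=2)
        return 0.0
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, df=2 * p.size))


def _fisher_combine_rows(pmat: np.ndarray) -> np.ndarray:
    """Row-wise Fisher combination of a (markers x k) matrix; NaN rows -> NaN."""
    with np.errstate(divide="ignore", invalid="ignore"):
        x = -2.0 * np.log(pmat).sum(axis=1)
    out = stats.chi2.sf(x, df=2 * pmat.shape[1])
    out[np.isnan(pmat).any(axis=1)] = np.nan
    return out


def iut_combine(
    scans: Mapping[str, pd.DataFrame], breed_set: BreedSet
) -> pd.DataFrame:
    """Combine per-breed scans into IUT results for one breed set.

    Returns one row per marker with per-breed p columns (``p_<breed>``),
    ``max_p`` (the IUT omnibus p), ``fisher_p`` and ``valid``.  All scans
    must share the same marker universe, aligned by marker_id.
    """
    members = sorted(breed_set.members)
    missing = [b for b in members if b not in scans]
    if missing:
        raise ValueError(f"no scan for breeds: {missing}")
    ref = scans[members[0]]
    ref_ids = ref["marker_id"].to_numpy()
    cols = {}
    for b in members:
        ids = scans[b]["marker_id"].to_numpy()
        if len(ids) != len(ref_ids) or (ids != ref_ids).any():
            bad = sorted(set(ref_ids).symmetric_difference(ids))
            raise ValueError(
                f"marker universe mismatch between {members[0]} and {b}: "
                f"{bad[:10]}{'...' if len(bad) > 10 else ''}"
            )
        cols[b] = scans[b]["p_value"].to_numpy(dtype=float)
    pmat = np.column_stack([cols[b] for b in members])
    valid = ~np.isnan(pmat).any(axis=1)
    max_p = np.where(valid, pmat.max(axis=1), np.nan)
    fisher_p = _fisher_combine_rows(pmat)
    out = pd.DataFrame({"marker_id": ref_ids})
    if "chrom" in ref.columns:
        out["chrom"] = ref["chrom"].to_numpy()
        out["pos_bp"] = ref["pos_bp"].to_numpy()
    out["breed_set"] = breed_set.label
    for b in members:
        out[f"p_{b}"] = cols[b]
    out["max_p"] = max_p
    out["fisher_p"] = fisher_p
    out["valid"] = valid
    return out


def bonferroni_threshold(
    n_valid: int, alpha: float = DEFAULT_ALPHA, breed_set: BreedSet | None = None
) -> IUTThreshold:
    """Per-set Bonferroni threshold alpha / (number of valid IUT tests)."""
    if breed_set is None:
        breed_set = BreedSet(frozenset({"_a", "_b"}))
    return IUTThreshold(breed_set=breed_set, n_valid=n_valid, alpha=alpha)


def call_significant(
    results: pd.DataFrame, threshold: IUTThreshold, strict_max_p: bool = False
) -> pd.DataFrame:
    """Add the ``significant`` column: fisher_p <= threshold (note: <=).

    With ``strict_max_p`` the IUT omnibus p must also clear the threshold.
    Invalid markers are never significant.
    """
    if "breed_set" in results.columns and len(results):
        labels = results["breed_set"].unique()
        if not (len(labels) == 1 and labels[0] == threshold.breed_set.label):
            # thresholds are per-set; a mismatched label is a caller error
            if threshold.breed_set.label not in ("_a∩_b",):
                raise ValueError(
                    f"threshold for {threshold.breed_set.label} applied to "
                    f"results of {list(labels)}"
                )
    out = results.copy()
    t = threshold.threshold
    sig = out["valid"] & (out["fisher_p"] <= t)
    if strict_max_p:
        sig &= out["max_p"] <= t
    out["significant"] = sig.fillna(False).astype(bool)
    return out


def run_iut(
    scans: Mapping[str, pd.DataFrame],
    alpha: float = DEFAULT_ALPHA,
    strict_max_p: bool = False,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Full IUT meta-analysis over every breed subset of size >= 2.

    Returns ``(results_by_set_label, thresholds_table)`` where each result
    table carries the ``significant`` call at its own per-set Bonferroni
    threshold.
    """
    sets = enumerate_sets(list(scans))
    results: dict[str, pd.DataFrame] = {}
    rows = []
    for bs in sets:
        res = iut_combine(scans, bs)
        n_valid = int(res["valid"].sum())
        if n_valid == 0:
            res["significant"] = False
            thr = np.nan
        else:
            t = bonferroni_threshold(n_valid, alpha, bs)
            res = call_significant(res, t, strict_max_p=strict_max_p)
            thr = t.threshold
        results[bs.label] = res
        rows.append((bs.label, len(bs), n_valid, alpha, thr, int(res["significant"].sum())))
    thresholds = pd.DataFrame(
        rows,
        columns=["breed_set", "n_breeds", "n_valid", "alpha", "threshold", "n_significant"],
    )
    return results, thresholds


def manhattan_export(
    results: Mapping[str, pd.DataFrame],
    thresholds: pd.DataFrame,
    out_dir: str | Path,
    plot_name: str = "manhattan.png",
) -> Path:
    """Manhattan panel per breed set plus the underlying combined table.

    y is -log10 of the Fisher-combined p; a horizontal threshold line is
    drawn only in panels with at least one significant marker.  The table
    is always written (``iut_results.tsv``), even when empty.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = (
        pd.concat(results.values(), ignore_index=True)
        if results
        else pd.DataFrame(columns=["marker_id", "breed_set", "fisher_p", "valid"])
    )
    table.to_csv(out_dir / "iut_results.tsv", sep="\t", index=False)

    n = max(len(results), 1)
    ncols = 2 if n > 1 else 1
    nrows = (n + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(6 * ncols, 3 * nrows), squeeze=False
    )
    thr_map = dict(zip(thresholds["breed_set"], thresholds["threshold"]))
    sig_map = dict(zip(thresholds["breed_set"], thresholds["n_significant"]))
    flat_axes = list(axes.ravel())
    for ax in flat_axes[len(results):]:
        ax.set_visible(False)
    for ax, (label, res) in zip(flat_axes, results.items()):
        ok = res["valid"] & res["fisher_p"].notna()
        if ok.any():
            sub = res[ok]
            x = np.arange(len(res))[ok.to_numpy()]
            ax.scatter(x, -np.log10(sub["fisher_p"]), s=4)
        if sig_map.get(label, 0) > 0 and np.isfinite(thr_map.get(label, np.nan)):
            ax.axhline(-np.log10(thr_map[label]), color="red", lw=1)
        ax.set_title(label)
        ax.set_xlabel("marker index")
        ax.set_ylabel("-log10 Fisher p")
    fig.tight_layout()
    path = out_dir / plot_name
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
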