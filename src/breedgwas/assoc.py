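"""Per-breed single-marker case/control allelic association test.

The test is the 1-df Pearson chi-square on the 2x2 allele-count table
(case/control x allele B/A), with no continuity correction — the basic
allelic case/control association test.  Monomorphic markers and tables
with an empty margin are retained with ``valid = False`` (their p-value is
undefined), because the count of valid tests propagates into downstream
Bonferroni thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, Cohort


def allelic_test(case_B, case_A, control_B, control_A):
    """1-df allelic chi-square on a 2x2 allele-count table.

    Accepts scalars or equal-length arrays.  Returns ``(chi2, p, OR)``
    where the allelic odds ratio is ``(case_B*control_A)/(case_A*control_B)``;
    entries with any zero row or column margin are invalid and returned as
    NaN in all three outputs.
    """
    a = np.asarray(case_B, dtype=float)
    b = np.asarray(case_A, dtype=float)
    c = np.asarray(control_B, dtype=float)
    d = np.asarray(control_A, dtype=float)
    if (a < 0).any() or (b < 0).any() or (c < 0).any() or (d < 0).any():
        raise ValueError("allele counts must be non-negative")
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    valid = (r1 > 0) & (r2 > 0) & (c1 > 0) & (c2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(valid, n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2), np.nan)
        p = np.where(valid, stats.chi2.sf(chi2, df=1), np.nan)
        cells_ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        orr = np.where(cells_ok, (a * d) / (b * c), np.nan)
    if np.ndim(case_B) == 0 and np.ndim(case_A) == 0:
        return float(chi2), float(p), float(orr)
    return chi2, p, orr


def allele_count_table(cohort: Cohort, mask: np.ndarray | None = None):
    """Vectorized per-marker allele counts split by phenotype.

    Returns ``(case_B, case_A, control_B, control_A)`` arrays over markers;
    missing genotypes are skipped and unphenotyped samples ignored.
    """
    pheno = cohort.phenotype_array()
    keep = pheno != MISSING
    if mask is not None:
        keep &= np.asarray(mask)
    G = cohort.genotypes[keep]
    y = pheno[keep]
    obs = G != MISSING
    Gz = np.where(obs, G, 0).astype(np.int64)
    case = y == 1
    case_B = Gz[case].sum(axis=0)
    case_A = 2 * obs[case].sum(axis=0) - case_B
    ctrl_B = Gz[~case].sum(axis=0)
    ctrl_A = 2 * obs[~case].sum(axis=0) - ctrl_B
    return case_B, case_A, ctrl_B, ctrl_A


def scan_breed(cohort: Cohort, breed: str) -> pd.DataFrame:
    """Allelic association scan of one breed; one row per marker.

    Columns: marker_id, chrom, pos_bp, breed, case_B, case_A, control_B,
    control_A, chi2, p_value, allelic_or, valid.  Marker order preserved.
    """
    mask = cohort.breed_mask(breed)
    if not mask.any():
        raise ValueError(f"breed {breed!r} not present in cohort")
    pheno = cohort.phenotype_array()
    n_case = int(((pheno == 1) & mask).sum())
    n_ctrl = int(((pheno == 0) & mask).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError(
            f"breed {breed!r} needs at least 1 case and 1 control "
            f"(got {n_case}/{n_ctrl})"
        )
    a, b, c, d = allele_count_table(cohort, mask)
    chi2, p, orr = allelic_test(a, b, c, d)
    return pd.DataFrame(
        {
            "marker_id": cohort.marker_ids,
            "chrom": [m.chrom for m in cohort.markers],
            "pos_bp": [m.pos_bp for m in cohort.markers],
            "breed": breed,
            "case_B": a,
            "case_A": b,
            "control_B": c,
            "control_A": d,
            "chi2": chi2,
            "p_value": p,
            "allelic_or": orr,
            "valid": ~np.isnan(p),
        }
    )


def scan_all_breeds(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Run :func:`scan_breed` for every breed label in the cohort."""
    return {breed: scan_breed(cohort, breed) for breed in cohort.breeds}


def write_assoc_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
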