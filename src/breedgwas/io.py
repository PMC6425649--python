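"""Multi-cohort SNP genotype containers and PLINK text (PED/MAP) I/O.

Genotypes are held as a samples x markers integer matrix coded by the
number of B alleles: 0 = AA, 1 = AB, 2 = BB, with ``MISSING`` (-1) for a
failed call.  Allele A is the first allele encountered in file order when
reading, and the reference/major allele by construction when simulating,
so the coding is deterministic and self-contained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

VALID_ALLELES = frozenset("ACGT0")

_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}
_CODE_TO_SEX = {"1": "male", "2": "female"}
_PHENO_TO_CODE = {"control": "1", "case": "2", "missing": "0"}


class PlinkParseError(ValueError):
    """Malformed PED/MAP content."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP with its map position and allele labels."""

    marker_id: str
    chrom: str
    pos_bp: int
    allele_A: str = "A"
    allele_B: str = "B"

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValueError("marker_id must be non-empty")
        if self.pos_bp < 1:
            raise ValueError(f"{self.marker_id}: pos_bp must be >= 1")
        if self.allele_A == self.allele_B:
            raise ValueError(f"{self.marker_id}: allele_A == allele_B")


@dataclass(frozen=True)
class Sample:
    sample_id: str
    cohort: str = "cohort"
    sex: Literal["male", "female", "unknown"] = "unknown"
    phenotype: Literal["case", "control", "missing"] = "missing"


@dataclass
class Cohort:
    """Samples x markers genotype matrix with marker map and phenotypes."""

    markers: list[Marker]
    samples: list[Sample]
    genotypes: np.ndarray  # int8, entries in {0, 1, 2, MISSING}

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotypes must be in {0, 1, 2, MISSING}")
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate marker_id in cohort")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate sample_id in cohort")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.cohort, None)
        return list(seen)

    def phenotype_array(self) -> np.ndarray:
        """1 = case, 0 = control, MISSING for unphenotyped samples."""
        code = {"case": 1, "control": 0, "missing": MISSING}
        return np.array([code[s.phenotype] for s in self.samples], dtype=np.int8)

    def breed_mask(self, breed: str) -> np.ndarray:
        return np.array([s.cohort == breed for s in self.samples])

    def subset_samples(self, mask: np.ndarray) -> "Cohort":
        idx = np.flatnonzero(np.asarray(mask))
        return Cohort(
            markers=list(self.markers),
            samples=[self.samples[i] for i in idx],
            genotypes=self.genotypes[idx],
        )


def _sex_from_code(code: str) -> str:
    return _CODE_TO_SEX.get(code, "unknown")


def _phenotype_from_code(code: str) -> str:
    # PLINK 1/2 coding; 0 and -9 both mean missing.
    if code == "1":
        return "control"
    if code == "2":
        return "case"
    return "missing"


def read_cohort(ped_path: str | Path, map_path: str | Path) -> Cohort:
    """Read a PLINK text fileset into a :class:`Cohort`.

    The map file may be a plain 3/4-column MAP (chrom, id, [cM], pos) or a
    6-column BIM-style map that additionally carries allele_A and allele_B.
    With a plain MAP, alleles are assigned deterministically: at each
    marker, allele A is the first non-missing allele symbol encountered in
    file order (rows scanned top to bottom, left allele before right).
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    markers_raw: list[tuple[str, str, int]] = []
    map_alleles: list[list[str]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4, 6):
                raise PlinkParseError(
                    f"{map_path}:{lineno}: expected 3, 4 or 6 columns, "
                    f"got {len(parts)}"
                )
            chrom, marker_id = parts[0], parts[1]
            if len(parts) == 6:
                pos = int(parts[3])
                map_alleles.append([parts[4], parts[5]])
            else:
                pos = int(parts[-1])
                map_alleles.append([])
            markers_raw.append((marker_id, chrom, pos))

    n_markers = len(markers_raw)
    expected_len = 6 + 2 * n_markers
    samples: list[Sample] = []
    # allele registry per marker: first seen -> A, second seen -> B,
    # pre-seeded from a BIM-style map when allele columns are present
    alleles: list[list[str]] = map_alleles
    rows: list[np.ndarray] = []

    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != expected_len:
                raise PlinkParseError(
                    f"{ped_path}:{lineno}: expected {expected_len} fields "
                    f"(6 + 2x{n_markers}), got {len(parts)}"
                )
            fid, iid, _pat, _mat, sex_code, pheno_code = parts[:6]
            samples.append(
                Sample(
                    sample_id=iid,
                    cohort=fid,
                    sex=_sex_from_code(sex_code),
                    phenotype=_phenotype_from_code(pheno_code),
                )
            )
            geno_row = np.empty(n_markers, dtype=np.int8)
            allele_fields = parts[6:]
            for j in range(n_markers):
                a1, a2 = allele_fields[2 * j], allele_fields[2 * j + 1]
                for a in (a1, a2):
                    if a not in VALID_ALLELES:
                        raise PlinkParseError(
                            f"{ped_path}:{lineno}: invalid allele symbol {a!r} "
                            f"at marker {markers_raw[j][0]}"
                        )
                if a1 == "0" or a2 == "0":
                    geno_row[j] = MISSING
                    continue
                reg = alleles[j]
                code = 0
                for a in (a1, a2):
                    if a not in reg:
                        reg.append(a)
                        if len(reg) > 2:
                            raise PlinkParseError(
                                f"marker {markers_raw[j][0]}: more than 2 "
                                f"distinct alleles ({', '.join(reg)})"
                            )
                    code += reg.index(a)  # B allele contributes 1
                geno_row[j] = code
            rows.append(geno_row)

    markers = []
    for (marker_id, chrom, pos), reg in zip(markers_raw, alleles):
        a = reg[0] if len(reg) > 0 else "A"
        b = reg[1] if len(reg) > 1 else ("B" if a != "B" else "A")
        markers.append(Marker(marker_id, chrom, pos, a, b))
    genotypes = (
        np.vstack(rows) if rows else np.empty((0, n_markers), dtype=np.int8)
    )
    return Cohort(markers=markers, samples=samples, genotypes=genotypes)


def write_cohort(
    cohort: Cohort,
    ped_path: str | Path,
    map_path: str | Path,
    extended_map: bool = True,
) -> None:
    """Write a cohort as a PLINK text fileset (missing genotype -> ``0 0``).

    By default the map is BIM-style (6 columns including both alleles), so
    a read/write round trip preserves the genotype coding exactly; pass
    ``extended_map=False`` for a strict 4-column MAP, in which case the
    reader re-derives allele orientation from the PED rows.
    """
    with open(map_path, "w") as fh:
        for m in cohort.markers:
            if extended_map:
                fh.write(
                    f"{m.chrom}\t{m.marker_id}\t0\t{m.pos_bp}"
                    f"\t{m.allele_A}\t{m.allele_B}\n"
                )
            else:
                fh.write(f"{m.chrom}\t{m.marker_id}\t0\t{m.pos_bp}\n")
    with open(ped_path, "w") as fh:
        for i, s in enumerate(cohort.samples):
            fields = [
                s.cohort,
                s.sample_id,
                "0",
                "0",
                _SEX_TO_CODE[s.sex],
                _PHENO_TO_CODE[s.phenotype],
            ]
            row = cohort.genotypes[i]
            for j, m in enumerate(cohort.markers):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [m.allele_A, m.allele_A]
                elif g == 1:
                    fields += [m.allele_A, m.allele_B]
                else:
                    fields += [m.allele_B, m.allele_B]
            fh.write(" ".join(fields) + "\n")


def merge_cohorts(
    cohorts: Sequence[Cohort],
    on_empty: Literal["error", "allow"] = "error",
    prefix_sample_ids: bool = True,
) -> Cohort:
    """Merge cohorts on the intersection of their markers.

    Marker order follows the first cohort.  A marker whose allele pair is
    swapped relative to the first cohort is flipped (0 <-> 2) so that the
    merged coding is consistent; a different allele pair is an error.
    Sample ids are prefixed with the cohort label to keep them unique.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    common = set(cohorts[0].marker_ids)
    for c in cohorts[1:]:
        common &= set(c.marker_ids)
    if not common and on_empty == "error":
        raise ValueError("no shared markers across cohorts")

    first = cohorts[0]
    kept = [m for m in first.markers if m.marker_id in common]
    merged_samples: list[Sample] = []
    blocks: list[np.ndarray] = []
    for c in cohorts:
        pos = {m.marker_id: j for j, m in enumerate(c.markers)}
        cols = []
        for m in kept:
            j = pos[m.marker_id]
            other = c.markers[j]
            col = c.genotypes[:, j]
            if (other.allele_A, other.allele_B) == (m.allele_A, m.allele_B):
                cols.append(col)
            elif (other.allele_B, other.allele_A) == (m.allele_A, m.allele_B):
                flipped = col.copy()
                nz = flipped != MISSING
                flipped[nz] = 2 - flipped[nz]
                cols.append(flipped)
            else:
                raise ValueError(
                    f"allele mismatch at marker {m.marker_id}: "
                    f"({m.allele_A},{m.allele_B}) vs ({other.allele_A},{other.allele_B})"
                )
        blocks.append(
            np.column_stack(cols) if cols else np.empty((c.n_samples, 0), np.int8)
        )
        for s in c.samples:
            sid = f"{s.cohort}:{s.sample_id}" if prefix_sample_ids else s.sample_id
            merged_samples.append(replace(s, sample_id=sid))
    sids = [s.sample_id for s in merged_samples]
    if len(set(sids)) != len(sids):
        dup = sorted({x for x in sids if sids.count(x) > 1})
        raise ValueError(f"duplicate sample ids after merge: {dup[:5]}")
    return Cohort(markers=kept, samples=merged_samples, genotypes=np.vstack(blocks))


def allele_frequencies(
    cohort: Cohort, group_by: Literal["cohort", "phenotype", "none"] = "none"
) -> pd.DataFrame:
    """Per-group allele-B frequency table.

    Returns a data frame with columns ``group``, ``marker_id``, ``freq_B``
    and ``n`` (number of genotyped samples); missing genotypes are excluded
    from both numerator and denominator, and a group with no genotyped
    sample at a marker gets ``freq_B = NaN``.
    """
    if group_by == "cohort":
        labels = np.array([s.cohort for s in cohort.samples])
    elif group_by == "phenotype":
        labels = np.array([s.phenotype for s in cohort.samples])
    elif group_by == "none":
        labels = np.array(["all"] * cohort.n_samples)
    else:
        raise ValueError(f"unknown group_by: {group_by!r}")

    G = cohort.genotypes
    records = []
    for grp in pd.unique(labels):
        sub = G[labels == grp]
        observed = sub != MISSING
        n_geno = observed.sum(axis=0)
        b_count = np.where(observed, sub, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = np.where(n_geno > 0, b_count / (2.0 * np.maximum(n_geno, 1)), np.nan)
        for m, f, n in zip(cohort.markers, freq, n_geno):
            records.append((grp, m.marker_id, f, int(n)))
    return pd.DataFrame(records, columns=["group", "marker_id", "freq_B", "n"])


def write_frequency_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_frequency_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
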