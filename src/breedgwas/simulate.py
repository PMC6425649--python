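"""Synthetic multi-breed case/control cohort generator.

Emulates the statistical structure of a cross-breed SNP-array study:
several breed cohorts of fixed case/control size, biallelic markers with
breed-specific allele-B frequencies (including fixation in some breeds),
Hardy-Weinberg genotypes within breed, a per-genotype-level logistic
disease model at planted risk loci, case/control ascertainment by quota
sampling, and uniform random missing calls.

Markers are independent between loci by default; disease risk follows

    logit P(case) = baseline + sum over planted loci of
                    { log OR_het if genotype 1, log OR_hom if genotype 2 }

so heterozygous and homozygous carriers carry separate odds ratios
relative to the 0 (AA) genotype, matching the class-variable fitting
convention used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import beta as beta_dist

from .io import MISSING, Cohort, Marker, Sample

Fixation = Literal["segregating", "fixed_risk", "fixed_nonrisk"]

#: frequency window for planted segregating loci (keeps them testable)
SEGREGATING_RANGE = (0.05, 0.95)


class SamplingError(RuntimeError):
    """Case/control quota could not be filled in the draw budget."""


@dataclass(frozen=True)
class BreedSpec:
    label: str
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError(f"{self.label}: case/control counts must be > 0")


@dataclass(frozen=True)
class PlantedLocus:
    """A risk locus with per-breed odds ratios and fixation pattern.

    ``per_breed_effects`` maps breed label -> (OR_het, OR_hom) relative to
    genotype 0; breeds absent from the map have no effect there.  A breed
    marked ``fixed_risk``/``fixed_nonrisk`` carries allele-B frequency
    exactly 1/0 and hence contributes no genotype variance in that breed.
    ``freq`` optionally pins the risk-allele frequency per breed; breeds
    without an entry draw from the segregating prior.
    """

    marker_index: int
    per_breed_effects: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    fixation: Mapping[str, Fixation] = field(default_factory=dict)
    freq: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for breed, (orh, orx) in self.per_breed_effects.items():
            if orh <= 0 or orx <= 0:
                raise ValueError(f"locus {self.marker_index}, {breed}: ORs must be > 0")
        for breed, f in self.freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"locus {self.marker_index}, {breed}: freq in [0,1]")


# Default cohort sizes: the three-breed osteosarcoma case/control
# design (Greyhound 153/114, Irish Wolfhound 28/62, Rottweiler 80/55).
DEFAULT_BREEDS = (
    BreedSpec("Greyhound", 153, 114),
    BreedSpec("IrishWolfhound", 28, 62),
    BreedSpec("Rottweiler", 80, 55),
)


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification for one synthetic study."""

    seed: int
    breeds: tuple[BreedSpec, ...] = DEFAULT_BREEDS
    n_markers: int = 1000
    #: Beta(alpha, beta) prior for per-breed allele-B frequency of null markers
    maf_prior: tuple[float, float] = (2.0, 2.0)
    planted: tuple[PlantedLocus, ...] = ()
    baseline_log_odds: float = 0.0
    missing_rate: float = 0.0
    #: probability that a null marker is fixed (at 0 or 1) in a given breed
    null_fixation_rate: float = 0.0
    #: additive log-odds for males (0 = sex has no effect)
    sex_log_odds: float = 0.0
    #: draw budget multiplier for quota sampling
    max_draw_factor: int = 500

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.null_fixation_rate < 1):
            raise ValueError("null_fixation_rate must be in [0, 1)")
        if self.n_markers <= 0:
            raise ValueError("n_markers must be > 0")
        a, b = self.maf_prior
        if a <= 0 or b <= 0:
            raise ValueError("maf_prior parameters must be > 0")
        idx = [p.marker_index for p in self.planted]
        if len(set(idx)) != len(idx):
            raise ValueError("planted marker_index values must be distinct")
        if idx and (min(idx) < 0 or max(idx) >= self.n_markers):
            raise ValueError("planted marker_index out of range")

    @property
    def breed_labels(self) -> list[str]:
        return [b.label for b in self.breeds]


def simulate_breed_frequencies(config: SimConfig) -> dict[str, np.ndarray]:
    """Draw per-breed allele-B frequency vectors.

    Null markers draw independently per breed from the Beta prior (with
    optional breed-specific fixation at 0 or 1); planted loci are fixed
    where so marked and otherwise drawn from the prior truncated to the
    segregating window.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    a, b = config.maf_prior
    planted_by_idx = {p.marker_index: p for p in config.planted}
    freqs: dict[str, np.ndarray] = {}
    for spec in config.breeds:
        f = rng.beta(a, b, size=config.n_markers)
        if config.null_fixation_rate > 0:
            fixed = rng.random(config.n_markers) < config.null_fixation_rate
            f = np.where(fixed, np.round(rng.random(config.n_markers)), f)
        lo, hi = SEGREGATING_RANGE
        for idx, locus in planted_by_idx.items():
            state = locus.fixation.get(spec.label, "segregating")
            u = rng.random()  # one draw per locus regardless of branch
            if state == "fixed_risk":
                f[idx] = 1.0
            elif state == "fixed_nonrisk":
                f[idx] = 0.0
            elif spec.label in locus.freq:
                f[idx] = locus.freq[spec.label]
            else:
                # truncated Beta via inverse CDF
                c_lo, c_hi = beta_dist.cdf([lo, hi], a, b)
                f[idx] = beta_dist.ppf(c_lo + u * (c_hi - c_lo), a, b)
        freqs[spec.label] = f
    return freqs


def _ascertain(
    rng: np.random.Generator,
    spec: BreedSpec,
    planted_freq: np.ndarray,
    log_or: np.ndarray,
    baseline: float,
    sex_log_odds: float,
    max_draw_factor: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quota-sample genotypes at planted loci plus sex and phenotype.

    Only planted-locus genotypes are drawn before acceptance: null markers
    are independent of disease status, so they can be filled in afterwards
    without changing the sampling distribution.
    """
    quota = {1: spec.n_cases, 0: spec.n_controls}
    got = {1: 0, 0: 0}
    n_total = spec.n_cases + spec.n_controls
    kept_g: list[np.ndarray] = []
    kept_sex: list[np.ndarray] = []
    kept_y: list[np.ndarray] = []
    drawn = 0
    budget = max(max_draw_factor * n_total, 10_000)
    batch = max(2 * n_total, 200)
    while got[1] < quota[1] or got[0] < quota[0]:
        if drawn >= budget:
            raise SamplingError(
                f"{spec.label}: could not fill quota cases={quota[1]} "
                f"controls={quota[0]} within {budget} draws "
                f"(got {got[1]}/{got[0]}); adjust baseline_log_odds"
            )
        b = min(batch, budget - drawn)
        drawn += b
        g = rng.binomial(2, planted_freq, size=(b, planted_freq.size)).astype(np.int8)
        sex_male = rng.random(b) < 0.5
        eta = np.full(b, baseline, dtype=float)
        if log_or.size:
            eta += np.take_along_axis(
                np.broadcast_to(log_or, (b,) + log_or.shape), g[:, :, None], axis=2
            )[:, :, 0].sum(axis=1)
        eta += sex_log_odds * sex_male
        y = (rng.random(b) < expit(eta)).astype(np.int8)
        for cls in (1, 0):
            need = quota[cls] - got[cls]
            if need <= 0:
                continue
            sel = np.flatnonzero(y == cls)[:need]
            kept_g.append(g[sel])
            kept_sex.append(sex_male[sel])
            kept_y.append(y[sel])
            got[cls] += len(sel)
    g = np.vstack(kept_g) if kept_g else np.empty((0, planted_freq.size), np.int8)
    sex = np.concatenate(kept_sex)
    y = np.concatenate(kept_y)
    # cases first, stable
    order = np.argsort(-y, kind="stable")
    return g[order], sex[order], y[order]


def _marker_list(config: SimConfig) -> list[Marker]:
    # synthetic map: one chromosome block per 1000 markers, 10 kb spacing
    markers = []
    for j in range(config.n_markers):
        chrom = str(1 + j // 1000)
        pos = 10_000 * (j % 1000) + 10_000
        markers.append(Marker(f"SNP{j:06d}", chrom, pos, "A", "C"))
    return markers


def _generate_breed_cohort(
    rng: np.random.Generator,
    spec: BreedSpec,
    f: np.ndarray,
    config: SimConfig,
    markers: list[Marker],
    id_prefix: str | None = None,
) -> Cohort:
    """Quota-sample one breed cohort given its frequency vector."""
    planted_idx = np.array([p.marker_index for p in config.planted], dtype=int)
    planted_f = f[planted_idx] if planted_idx.size else np.empty(0)
    lor_full = np.zeros((planted_idx.size, 3))
    for k, p in enumerate(config.planted):
        eff = p.per_breed_effects.get(spec.label)
        if eff is not None:
            lor_full[k] = [0.0, np.log(eff[0]), np.log(eff[1])]
    g_planted, sex_male, y = _ascertain(
        rng, spec, planted_f, lor_full, config.baseline_log_odds,
        config.sex_log_odds, config.max_draw_factor,
    )
    n = y.size
    G = np.empty((n, config.n_markers), dtype=np.int8)
    null_mask = np.ones(config.n_markers, dtype=bool)
    if planted_idx.size:
        null_mask[planted_idx] = False
        G[:, planted_idx] = g_planted
    G[:, null_mask] = rng.binomial(
        2, f[null_mask], size=(n, int(null_mask.sum()))
    ).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(G.shape) < config.missing_rate
        G[miss] = MISSING
    prefix = id_prefix or spec.label
    samples = [
        Sample(
            sample_id=f"{prefix}_{i:05d}",
            cohort=spec.label,
            sex="male" if sex_male[i] else "female",
            phenotype="case" if y[i] else "control",
        )
        for i in range(n)
    ]
    return Cohort(markers=list(markers), samples=samples, genotypes=G)


def simulate_cohort(config: SimConfig) -> tuple[dict[str, Cohort], pd.DataFrame]:
    """Generate one cohort per breed plus the true-effect table.

    Returns ``(cohorts, truth)`` where ``truth`` has one row per planted
    locus per breed with columns ``marker_id, breed, or_het, or_hom,
    fixation, freq_B``.
    """
    freqs = simulate_breed_frequencies(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    markers = _marker_list(config)
    cohorts: dict[str, Cohort] = {}
    truth_rows = []
    for spec in config.breeds:
        f = freqs[spec.label]
        cohorts[spec.label] = _generate_breed_cohort(rng, spec, f, config, markers)
        for p in config.planted:
            eff = p.per_breed_effects.get(spec.label, (1.0, 1.0))
            truth_rows.append(
                (
                    markers[p.marker_index].marker_id,
                    spec.label,
                    eff[0],
                    eff[1],
                    p.fixation.get(spec.label, "segregating"),
                    f[p.marker_index],
                )
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["marker_id", "breed", "or_het", "or_hom", "fixation", "freq_B"],
    )
    return cohorts, truth


def simulate_validation_cohort(
    config: SimConfig,
    breed: str,
    n_cases: int,
    n_controls: int,
    draw: int = 0,
) -> Cohort:
    """An independent cohort of one breed from the same generative truth.

    Allele frequencies and planted effects are those of ``config`` for the
    named breed; genotypes and phenotypes are drawn from a fresh stream so
    the cohort is independent of :func:`simulate_cohort` output.  ``draw``
    distinguishes replicate validation cohorts.
    """
    labels = config.breed_labels
    if breed not in labels:
        raise ValueError(f"breed {breed!r} not in config ({labels})")
    freqs = simulate_breed_frequencies(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, draw]))
    spec = BreedSpec(breed, n_cases, n_controls)
    return _generate_breed_cohort(
        rng, spec, freqs[breed], config, _marker_list(config),
        id_prefix=f"{breed}_val{draw}",
    )


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
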