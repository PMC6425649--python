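"""Canonical simulation scenarios: the study conditions the package is
exercised under.

Each function returns a fully specified :class:`~breedgwas.simulate.SimConfig`
so that tests, the acceptance script and documentation all run the same
conditions.  Cohort sizes are the three-breed case/control design
(Greyhound 153/114, Irish Wolfhound 28/62, Rottweiler 80/55).  Null-marker
allele-B frequencies draw from Beta(2, 2) per breed, and a quarter of null
markers are fixed within any given breed — closed dog breeds show
extensive breed-specific fixation, which is also what makes the
valid-IUT-test count smaller than the marker count.

The shared-modest-effect locus is calibrated so each breed's expected
allelic signal is about z = 3.3 (a typical within-breed p near 1e-3):
strong enough for the Fisher-combined three-breed test, far below any
single breed's genome-wide threshold.  Per-breed allelic odds ratios that
give this signal at the three cohort sizes (computed from the 2x2 Wald
noncentrality at allele frequency 0.3) are 1.95 / 3.6 / 2.55, entered
log-additively per genotype (OR_hom = OR_het^2).
"""

from __future__ import annotations

from .simulate import BreedSpec, DEFAULT_BREEDS, PlantedLocus, SimConfig

#: per-breed allelic OR of the shared modest-effect locus (z ~ 3.3 each)
SHARED_MODEST_OR = {
    "Greyhound": 1.95,
    "IrishWolfhound": 3.6,
    "Rottweiler": 2.55,
}

#: fraction of null markers fixed within any one breed
NULL_FIXATION_RATE = 0.25

#: risk-allele frequency of planted loci in the power/recovery scenarios
#: (a representative common-variant frequency; the effect calibrations
#: above are computed at this value)
PLANTED_FREQ = 0.3


def _log_additive(or_allelic: float) -> tuple[float, float]:
    return or_allelic, or_allelic**2


def null_three_breed(seed: int, n_markers: int = 10_000) -> SimConfig:
    """Three study-sized breed cohorts with no planted effects."""
    return SimConfig(
        seed=seed,
        n_markers=n_markers,
        null_fixation_rate=NULL_FIXATION_RATE,
    )


def shared_modest_effect(seed: int, n_markers: int = 10_000) -> SimConfig:
    """One locus shared by all three breeds at the modest-signal calibration."""
    planted = PlantedLocus(
        0,
        {b: _log_additive(r) for b, r in SHARED_MODEST_OR.items()},
        freq={b: PLANTED_FREQ for b in SHARED_MODEST_OR},
    )
    return SimConfig(
        seed=seed,
        n_markers=n_markers,
        null_fixation_rate=NULL_FIXATION_RATE,
        planted=(planted,),
    )


def greyhound_strong_locus(seed: int, n_markers: int = 20) -> SimConfig:
    """A single OR_hom = 5 locus in the Greyhound among null markers.

    The candidate-pool scenario for stepwise selection and single-breed
    power: one real locus (log-additive, OR_het = sqrt(5)) among
    ``n_markers - 1`` nulls at the Greyhound cohort size.
    """
    planted = PlantedLocus(0, {"Greyhound": (5**0.5, 5.0)},
                           freq={"Greyhound": PLANTED_FREQ})
    return SimConfig(seed=seed, n_markers=n_markers, planted=(planted,))


def or3_recovery(seed: int, n_per_arm: int = 5_000) -> SimConfig:
    """Large single-breed cohort with a planted OR_hom = 3 locus.

    Used for parameter-recovery checks: n cases = n controls = 5,000 by
    default, one locus with per-genotype odds ratios (sqrt(3), 3).
    """
    planted = PlantedLocus(0, {"SimBreed": (3**0.5, 3.0)},
                           freq={"SimBreed": PLANTED_FREQ})
    return SimConfig(
        seed=seed,
        breeds=(BreedSpec("SimBreed", n_per_arm, n_per_arm),),
        n_markers=5,
        planted=(planted,),
    )


def marginal_effects_candidates(seed: int, n_candidates: int = 34) -> SimConfig:
    """Candidate-set scenario: marginal effects only, no interactions.

    Every candidate marker carries a modest log-additive marginal effect
    in every breed (allelic ORs cycling through 1.2-1.8) at the pinned
    risk-allele frequency, mirroring a mapped risk-locus panel; the
    disease model has no interaction terms, so any pairwise interaction
    signal is a false positive.  The baseline log-odds centers the total
    genetic load (its Hardy-Weinberg expectation under the pinned
    frequency), keeping population risk near 1/2 so case and control
    quotas both fill.
    """
    import numpy as np

    ors = [1.2, 1.4, 1.6, 1.8]
    q = PLANTED_FREQ
    planted = tuple(
        PlantedLocus(
            j,
            {b.label: _log_additive(ors[j % len(ors)]) for b in DEFAULT_BREEDS},
            freq={b.label: q for b in DEFAULT_BREEDS},
        )
        for j in range(n_candidates)
    )
    expected_load = sum(
        2 * q * (1 - q) * np.log(ors[j % len(ors)])
        + q**2 * 2 * np.log(ors[j % len(ors)])
        for j in range(n_candidates)
    )
    return SimConfig(
        seed=seed,
        n_markers=n_candidates,
        planted=planted,
        baseline_log_odds=-float(expected_load),
    )
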