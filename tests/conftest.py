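import numpy as np
import pytest

from breedgwas.io import Cohort, Marker, Sample
from breedgwas.simulate import BreedSpec, PlantedLocus, SimConfig, simulate_cohort


def make_cohort(genotypes, phenotypes, breed="Test", marker_prefix="M", sexes=None):
    """Small hand-built cohort from a genotype matrix and 0/1 phenotypes."""
    G = np.asarray(genotypes, dtype=np.int8)
    n, m = G.shape
    markers = [
        Marker(f"{marker_prefix}{j}", "1", 1000 * (j + 1), "A", "C") for j in range(m)
    ]
    sexes = sexes or ["female"] * n
    samples = [
        Sample(
            sample_id=f"{breed}_{i}",
            cohort=breed,
            sex=sexes[i],
            phenotype={1: "case", 0: "control", -1: "missing"}[int(phenotypes[i])],
        )
        for i in range(n)
    ]
    return Cohort(markers=markers, samples=samples, genotypes=G)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_cohorts():
    """Three small breed cohorts with one shared planted locus."""
    cfg = SimConfig(
        seed=42,
        breeds=(
            BreedSpec("Greyhound", 40, 40),
            BreedSpec("IrishWolfhound", 20, 30),
            BreedSpec("Rottweiler", 30, 25),
        ),
        n_markers=30,
        planted=(
            PlantedLocus(
                2,
                {
                    "Greyhound": (2.0, 4.0),
                    "IrishWolfhound": (2.0, 4.0),
                    "Rottweiler": (2.0, 4.0),
                },
            ),
        ),
        missing_rate=0.02,
    )
    cohorts, truth = simulate_cohort(cfg)
    return cfg, cohorts, truth
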