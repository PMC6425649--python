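"""Intersection-union test combination, Fisher's method, thresholds."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from breedgwas.assoc import scan_breed
from breedgwas.iut import (
    BreedSet,
    bonferroni_threshold,
    call_significant,
    enumerate_sets,
    fisher_combine,
    iut_combine,
    manhattan_export,
    run_iut,
)


def fake_scan(marker_ids, pvals, breed):
    p = np.asarray(pvals, dtype=float)
    return pd.DataFrame(
        {
            "marker_id": marker_ids,
            "chrom": "1",
            "pos_bp": np.arange(1, len(marker_ids) + 1) * 100,
            "breed": breed,
            "p_value": p,
            "valid": ~np.isnan(p),
        }
    )


class TestEnumerateSets:
    @pytest.mark.parametrize("k,expected", [(2, 1), (3, 4), (4, 11)])
    def test_counts(self, k, expected):
        sets = enumerate_sets([f"B{i}" for i in range(k)])
        assert len(sets) == expected
        assert len(sets) == 2**k - k - 1  # all subsets minus singletons, empty

    def test_single_breed_rejected(self):
        with pytest.raises(ValueError):
            enumerate_sets(["only"])

    def test_label_is_sorted_intersection(self):
        s = BreedSet(frozenset({"Rottweiler", "Greyhound"}))
        assert s.label == "Greyhound∩Rottweiler"


class TestFisherCombine:
    def test_even_df_closed_form(self):
        """chi-square tail at 2k df equals the truncated Poisson sum."""
        ps = (0.01, 0.02, 0.03)
        x = -2 * np.log(ps).sum()
        assert x == pytest.approx(24.0475, abs=1e-3)
        import math

        k = len(ps)
        closed = np.exp(-x / 2) * sum((x / 2) ** i / math.factorial(i)
                                      for i in range(k))
        combined = fisher_combine(ps)
        assert combined == pytest.approx(closed, rel=1e-12)
        assert combined == pytest.approx(5.1e-4, abs=0.2e-4)

    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_identity(self):
        for p in (0.7, 0.05, 1e-6):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-10)

    def test_zero_p_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="combined p set to 0"):
            assert fisher_combine([0.0, 0.5]) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            fisher_combine([1.5, 0.5])
        with pytest.raises(ValueError):
            fisher_combine([-0.1])
        with pytest.raises(ValueError):
            fisher_combine([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-10, 1.0), min_size=2, max_size=5))
    def test_symmetric_in_arguments(self, ps):
        ref = fisher_combine(ps)
        for perm in itertools.islice(itertools.permutations(ps), 6):
            assert fisher_combine(perm) == pytest.approx(ref, rel=1e-12)

    def test_uniform_under_null(self, rng):
        u = rng.uniform(size=(10_000, 3))
        fp = np.array([fisher_combine(row) for row in u])
        assert stats.kstest(fp, "uniform").pvalue > 0.001


class TestIUTCombine:
    def test_max_p_is_componentwise_max(self):
        scans = {
            "A": fake_scan(["m1"], [0.1], "A"),
            "B": fake_scan(["m1"], [0.001], "B"),
        }
        res = iut_combine(scans, BreedSet(frozenset({"A", "B"})))
        assert res["max_p"].iloc[0] == pytest.approx(0.1)

    def test_invalid_member_invalidates_marker(self):
        scans = {
            "A": fake_scan(["m1", "m2"], [0.1, np.nan], "A"),
            "B": fake_scan(["m1", "m2"], [0.2, 0.3], "B"),
        }
        res = iut_combine(scans, BreedSet(frozenset({"A", "B"})))
        assert bool(res["valid"].iloc[0]) and not bool(res["valid"].iloc[1])
        assert np.isnan(res["max_p"].iloc[1]) and np.isnan(res["fisher_p"].iloc[1])

    def test_marker_universe_mismatch(self):
        scans = {
            "A": fake_scan(["m1"], [0.1], "A"),
            "B": fake_scan(["m2"], [0.2], "B"),
        }
        with pytest.raises(ValueError, match="mismatch"):
            iut_combine(scans, BreedSet(frozenset({"A", "B"})))

    def test_monotonicity_under_set_shrinkage(self, small_cohorts):
        """max_p dominates components; dropping a breed cannot raise it."""
        _, cohorts, _ = small_cohorts
        scans = {b: scan_breed(c, b) for b, c in cohorts.items()}
        triple = iut_combine(scans, BreedSet(frozenset(scans)))
        for pair in itertools.combinations(scans, 2):
            sub = iut_combine(scans, BreedSet(frozenset(pair)))
            both = triple["valid"] & sub["valid"]
            assert (
                sub.loc[both, "max_p"].to_numpy()
                <= triple.loc[both, "max_p"].to_numpy() + 1e-15
            ).all()
        for b in scans:
            comp = triple[f"p_{b}"]
            ok = triple["valid"]
            assert (triple.loc[ok, "max_p"] >= comp[ok] - 1e-15).all()

    def test_superset_valid_count_not_larger(self, small_cohorts):
        _, cohorts, _ = small_cohorts
        scans = {b: scan_breed(c, b) for b, c in cohorts.items()}
        triple = iut_combine(scans, BreedSet(frozenset(scans)))
        for pair in itertools.combinations(scans, 2):
            sub = iut_combine(scans, BreedSet(frozenset(pair)))
            assert triple["valid"].sum() <= sub["valid"].sum()


class TestThresholdsAndCalls:
    def test_bonferroni_arithmetic(self):
        assert bonferroni_threshold(100_000).threshold == pytest.approx(5e-7)
        assert bonferroni_threshold(1).threshold == pytest.approx(0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(0)

    def test_exact_threshold_equality_is_significant(self):
        bs = BreedSet(frozenset({"A", "B"}))
        t = bonferroni_threshold(100, breed_set=bs)
        res = fake_scan(["m1"], [0.1], "A").rename(columns={"p_value": "p_A"})
        res["breed_set"] = bs.label
        res["max_p"] = 0.1
        res["fisher_p"] = t.threshold  # exactly at threshold
        res["valid"] = True
        out = call_significant(res, t)
        assert bool(out["significant"].iloc[0])

    def test_invalid_never_significant(self):
        bs = BreedSet(frozenset({"A", "B"}))
        t = bonferroni_threshold(10, breed_set=bs)
        res = pd.DataFrame(
            {"marker_id": ["m1"], "breed_set": bs.label, "max_p": [np.nan],
             "fisher_p": [np.nan], "valid": [False]}
        )
        assert not call_significant(res, t)["significant"].iloc[0]

    def test_strict_mode_requires_max_p(self):
        bs = BreedSet(frozenset({"A", "B"}))
        t = bonferroni_threshold(10, breed_set=bs)
        res = pd.DataFrame(
            {"marker_id": ["m1"], "breed_set": bs.label, "max_p": [0.2],
             "fisher_p": [t.threshold / 2], "valid": [True]}
        )
        assert call_significant(res, t)["significant"].iloc[0]
        assert not call_significant(res, t, strict_max_p=True)["significant"].iloc[0]


def test_run_iut_and_manhattan_export(small_cohorts, tmp_path):
    _, cohorts, _ = small_cohorts
    scans = {b: scan_breed(c, b) for b, c in cohorts.items()}
    results, thresholds = run_iut(scans)
    assert len(results) == 4 and len(thresholds) == 4
    path = manhattan_export(results, thresholds, tmp_path)
    assert path.exists()
    table = pd.read_csv(tmp_path / "iut_results.tsv", sep="\t")
    # exported table is self-consistent with the in-memory results
    total = sum(len(r) for r in results.values())
    assert len(table) == total
    one = results[thresholds["breed_set"].iloc[0]]
    sub = table[table["breed_set"] == thresholds["breed_set"].iloc[0]]
    np.testing.assert_allclose(
        sub["fisher_p"].to_numpy(), one["fisher_p"].to_numpy(), rtol=1e-12
    )


def test_manhattan_export_empty_results(tmp_path):
    path = manhattan_export({}, pd.DataFrame(
        columns=["breed_set", "threshold", "n_significant"]), tmp_path)
    assert path.exists()
    table = pd.read_csv(tmp_path / "iut_results.tsv", sep="\t")
    assert table.empty
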