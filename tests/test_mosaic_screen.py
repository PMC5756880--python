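import itertools
import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coevmosaic.diversity import heterozygosity_stats
from coevmosaic.mosaic_screen import (HOT, COLD, REFERENCE, FenceResult,
                                      SpeciesScreenReport, classify_locations,
                                      compare_species_gis,
                                      enumerate_label_assignments,
                                      locus_specific_divergence,
                                      outlier_permutation_test,
                                      tukey_fence_outliers, tukey_hinges,
                                      welch_t)
from coevmosaic.synthetic_data import (SimConfig, aphid_config,
                                       parasitoid_config, simulate_pair,
                                       simulate_species)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Tukey fences
# ---------------------------------------------------------------------------

def fivenum_oracle(x):
    """R-style five-number summary computed straight from its definition."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    d = (math.floor((n + 3) / 2)) / 2
    pos = [1, d, (n + 1) / 2, n + 1 - d, n]
    return [0.5 * (x[math.floor(p) - 1] + x[math.ceil(p) - 1]) for p in pos]


class TestTukeyFences:
    def test_hand_computed_example(self):
        # hinges of {1,2,3,4,100} are 2 and 4 (checked against fivenum)
        oracle = fivenum_oracle([1, 2, 3, 4, 100])
        assert oracle[1] == 2 and oracle[3] == 4
        vals = pd.Series([1, 2, 3, 4, 100], index=list("abcde"))
        res = tukey_fence_outliers(vals)
        assert res.lower_fence == pytest.approx(2 - 1.5 * 2)
        assert res.upper_fence == pytest.approx(4 + 1.5 * 2)
        assert res.high_outliers == ["e"]
        assert res.low_outliers == []

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 10, 15])
    def test_hinges_match_fivenum_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        lo, med, hi = tukey_hinges(x)
        oracle = fivenum_oracle(x)
        assert lo == pytest.approx(oracle[1])
        assert med == pytest.approx(oracle[2])
        assert hi == pytest.approx(oracle[3])

    def test_all_equal_values_no_outliers(self):
        vals = pd.Series([0.3] * 6, index=list("abcdef"))
        assert tukey_fence_outliers(vals).outliers == set()

    def test_zero_iqr_flags_any_differing_value(self):
        vals = pd.Series([0.3] * 6 + [0.31], index=list("abcdefg"))
        res = tukey_fence_outliers(vals)
        assert res.outliers == {"g"}

    def test_missing_values_excluded(self):
        vals = pd.Series([1, 2, 3, 4, 100, np.nan], index=list("abcdef"))
        res = tukey_fence_outliers(vals)
        assert res.outliers == {"e"}

    def test_too_few_values_gives_empty_set(self, caplog):
        with caplog.at_level(logging.WARNING):
            res = tukey_fence_outliers(pd.Series([1.0, 2.0, 3.0]))
        assert res.outliers == set()
        assert math.isnan(res.lower_fence)

    def test_outlier_set_invariant_under_constant_shift(self):
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.normal(size=12))
        a = tukey_fence_outliers(vals).outliers
        b = tukey_fence_outliers(vals + 7.5).outliers
        assert a == b

    @given(
        values=st.lists(
            st.floats(min_value=-1, max_value=1,
                      allow_nan=False, allow_infinity=False),
            min_size=4, max_size=20,
        ),
        shift=st.floats(min_value=-5, max_value=5, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True)
    def test_fence_properties(self, values, shift):
        """Shift invariance and tail symmetry under negation, for any
        vector the screen could see."""
        vals = pd.Series(values, index=[f"L{i}" for i in range(len(values))])
        base = tukey_fence_outliers(vals)
        shifted = tukey_fence_outliers(vals + shift)
        assert base.outliers == shifted.outliers
        negated = tukey_fence_outliers(-vals)
        assert set(base.low_outliers) == set(negated.high_outliers)
        assert set(base.high_outliers) == set(negated.low_outliers)
        # outliers lie strictly outside the fences, non-outliers inside
        for locus, v in vals.items():
            if locus in base.outliers:
                assert v < base.lower_fence or v > base.upper_fence


# ---------------------------------------------------------------------------
# Locus-specific divergence and classification
# ---------------------------------------------------------------------------

class TestScreen:
    def test_population_against_its_own_copy_is_near_zero(self):
        cfg = SimConfig(population_labels=("R",), n_individuals_per_pop=30,
                        n_loci=8, n_alleles_per_locus=4, seed=2)
        ds, _ = simulate_species(cfg)
        pop = ds.populations[0]
        twin = make_dataset({
            "R": [[tuple(g) for g in pop.genotypes[i]]
                  for i in range(pop.n_individuals)],
            "C": [[tuple(g) for g in pop.genotypes[i]]
                  for i in range(pop.n_individuals)],
        }, locus_names=ds.locus_names)
        report = locus_specific_divergence(twin, "R")
        vals = report.fst["C"].dropna()
        assert (vals.abs() < 0.05).all()

    def test_unknown_reference_rejected(self, sim_pair_small):
        ds_host, _, _ = sim_pair_small
        with pytest.raises(ValueError, match="reference"):
            locus_specific_divergence(ds_host, "Nowhere")

    def test_planted_hotspot_locus_exceeds_fence(self):
        cfg = parasitoid_config(hotspot_loci=frozenset({4}),
                                hotspot_populations=frozenset({"Escalon"}),
                                seed=0)
        ds, _ = simulate_species(cfg)
        report = locus_specific_divergence(ds, "YubaCity")
        locus = ds.locus_names[4]
        assert locus in report.fences["Escalon"].high_outliers

    def test_classification_is_reciprocal_and_symmetric(self):
        host_cfg = aphid_config(hotspot_loci=frozenset({3}),
                                hotspot_populations=frozenset({"Newark"}),
                                hotspot_theta=0.7, seed=0)
        para_cfg = parasitoid_config(hotspot_loci=frozenset({8}),
                                     hotspot_populations=frozenset({"Newark"}),
                                     hotspot_theta=0.7, seed=0)
        ds_h, ds_p, truth = simulate_pair(host_cfg, para_cfg, seed=0)
        rep_h = locus_specific_divergence(ds_h, "Linden")
        rep_p = locus_specific_divergence(ds_p, "YubaCity")
        fwd = classify_locations(rep_h, rep_p)
        rev = classify_locations(rep_p, rep_h)
        assert truth.planted_hot_locations() == {"Newark"}
        assert "Newark" in fwd.hot_spots
        assert fwd.hot_spots == rev.hot_spots
        refs = fwd.classification[
            fwd.classification["classification"] == REFERENCE
        ].index
        assert set(refs) == {"Linden", "YubaCity"}

    def test_outlier_free_reports_classify_all_cold(self):
        loci = [f"L{i}" for i in range(8)]
        flat = pd.DataFrame(0.05, index=loci, columns=["X", "Y"])
        reports = []
        for ref in ("R1", "R2"):
            rep = SpeciesScreenReport("sp", ref, flat, flat)
            for loc in flat.columns:
                rep.fences[loc] = tukey_fence_outliers(flat[loc])
            reports.append(rep)
        out = classify_locations(reports[0], reports[1])
        assert out.hot_spots == []
        assert set(out.classification["classification"]) == {COLD, REFERENCE}

    def test_location_missing_from_one_species_excluded(self, caplog):
        loci = [f"L{i}" for i in range(6)]
        a = pd.DataFrame(0.05, index=loci, columns=["X", "Y"])
        b = pd.DataFrame(0.05, index=loci, columns=["X"])
        rep_a = SpeciesScreenReport("a", "R1", a, a)
        rep_b = SpeciesScreenReport("b", "R2", b, b)
        for rep in (rep_a, rep_b):
            for loc in rep.fst.columns:
                rep.fences[loc] = tukey_fence_outliers(rep.fst[loc])
        with caplog.at_level(logging.WARNING):
            out = classify_locations(rep_a, rep_b, co_sampled=["X", "Y"])
        assert "Y" not in out.classification.index


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

class TestPermutationTest:
    def test_fixed_difference_gives_minimal_p(self):
        ds = make_dataset({"R": [[(100, 100)]] * 6, "C": [[(200, 200)]] * 6})
        p = outlier_permutation_test(ds, "R", "C", "L1", n_perm=200, seed=1)
        # only label swaps preserving the split reach the observed F_ST
        assert p <= 10 / 201

    def test_small_permutation_count_rejected(self):
        ds = make_dataset({"R": [[(1, 2)]] * 6, "C": [[(1, 1)]] * 6})
        with pytest.raises(ValueError, match="n_perm"):
            outlier_permutation_test(ds, "R", "C", "L1", n_perm=50)

    def test_agrees_with_exhaustive_enumeration_at_n6(self):
        ds = make_dataset({
            "R": [[(1, 1)], [(1, 2)], [(2, 2)]],
            "C": [[(2, 2)], [(2, 3)], [(3, 3)]],
        })
        exact = enumerate_label_assignments(ds, "R", "C", "L1")
        n_perm = 4000
        approx = outlier_permutation_test(ds, "R", "C", "L1",
                                          n_perm=n_perm, seed=5)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(approx - exact) < 3 * se + 2 / n_perm

    def test_identical_populations_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for rep in range(40):
            rows = [[tuple(sorted(rng.integers(1, 4, 2)))] for _ in range(12)]
            ds = make_dataset({"R": rows[:6], "C": rows[6:]})
            try:
                ps.append(outlier_permutation_test(ds, "R", "C", "L1",
                                                   n_perm=200, seed=rep))
            except ValueError:  # monomorphic draw
                continue
        assert np.mean([p <= 0.05 for p in ps]) <= 0.05 + 3 * math.sqrt(
            0.05 * 0.95 / len(ps)
        )


# ---------------------------------------------------------------------------
# Species comparison (Welch)
# ---------------------------------------------------------------------------

class TestWelch:
    def test_identical_vectors_give_zero_t(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        t, df, p = welch_t(v, v.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_on_random_vectors(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 9))
            b = rng.normal(0.5, 2, rng.integers(3, 9))
            t, df, p = welch_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-12)
            assert df == pytest.approx(ref.df, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_compare_species_gis_orientation(self, sim_pair_small):
        ds_host, ds_para, _ = sim_pair_small
        host = heterozygosity_stats(ds_host)
        para = heterozygosity_stats(ds_para)
        rep = compare_species_gis(host, para)
        expect_t, _, _ = welch_t(host.gis.dropna().to_numpy(),
                                 para.gis.dropna().to_numpy())
        assert rep.t == pytest.approx(expect_t)
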