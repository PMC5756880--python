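import itertools

import numpy as np
import pytest

from coevmosaic.genotype_model import MISSING
from coevmosaic.null_fst import (estimate_null_freq, fst_components, fst_ena,
                                 fst_from_components, fst_global, rho_st)
from coevmosaic.synthetic_data import SimConfig, simulate_species

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def wc_theta_anova_oracle(ds, pop_ids=None):
    """Weir-Cockerham theta via the nested gametic ANOVA route.

    Mean squares among populations (MSP), among individuals within
    populations (MSI) and between gametes within individuals (MSG) are
    computed per allele indicator; components a = (MSP - MSI) / (2 n_c),
    b = (MSI - MSG) / 2, c = MSG are summed over alleles and loci.  This
    is a deliberately different computational path from the package's
    moment-component implementation.
    """
    pop_ids = pop_ids or ds.population_ids
    sum_a = sum_b = sum_c = 0.0
    for j in range(ds.n_loci):
        pops = []
        for pid in pop_ids:
            g = ds.population(pid).genotypes[:, j, :]
            pops.append(g[g[:, 0] != MISSING])
        ns = np.array([len(g) for g in pops], dtype=float)
        if (ns > 0).sum() < 2:
            continue
        r = len(pops)
        N = ns.sum()
        nbar = N / r
        nc = (N - (ns**2).sum() / N) / (r - 1)
        alleles = sorted({a for g in pops for a in g.ravel()})
        for u in alleles:
            # gamete indicator y in {0,1}; individuals hold two gametes
            y = [np.array([[a1 == u, a2 == u] for a1, a2 in g], dtype=float)
                 for g in pops]
            ybar_i = [yi.mean(axis=1) for yi in y]           # per individual
            ybar_p = [yi.mean() for yi in y]                 # per population
            ybar = sum(yi.sum() for yi in y) / (2 * N)
            ssp = sum(2 * n * (yp - ybar) ** 2 for n, yp in zip(ns, ybar_p))
            ssi = sum(2 * ((yi_m - yp) ** 2).sum()
                      for yi_m, yp in zip(ybar_i, ybar_p))
            ssg = sum(((yi - yi_m[:, None]) ** 2).sum()
                      for yi, yi_m in zip(y, ybar_i))
            msp = ssp / (r - 1)
            msi = ssi / (N - r)
            msg = ssg / N
            sum_a += (msp - msi) / (2 * nc)
            sum_b += (msi - msg) / 2
            sum_c += msg
    return sum_a / (sum_a + sum_b + sum_c)


def rho_anova_oracle(ds, pid1, pid2):
    """Rho_ST by brute-force one-way ANOVA on allele sizes."""
    sum_a = sum_tot = 0.0
    for j in range(ds.n_loci):
        groups = []
        for pid in (pid1, pid2):
            g = ds.population(pid).genotypes[:, j, :].ravel()
            groups.append(g[g != MISSING].astype(float))
        ns = np.array([len(g) for g in groups], dtype=float)
        if (ns == 0).any() or ns.sum() <= 2:
            continue
        N = ns.sum()
        grand = np.concatenate(groups).mean()
        ssa = sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups))
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        msa = ssa / (len(groups) - 1)
        msw = ssw / (N - len(groups))
        n0 = (N - (ns**2).sum() / N) / (len(groups) - 1)
        sa = (msa - msw) / n0
        sum_a += sa
        sum_tot += sa + msw
    return sum_a / sum_tot


# ---------------------------------------------------------------------------
# Null-allele EM
# ---------------------------------------------------------------------------

class TestNullAlleleEM:
    def test_hardy_weinberg_counts_give_near_zero_null(self):
        # 25 AA : 50 AB : 25 BB, no missing - textbook HW, no excess
        rows = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
        ds = make_dataset({"A": rows})
        est = estimate_null_freq(ds).get("A", "L1")
        assert est.em_converged
        assert est.null_freq < 1e-3

    def test_all_missing_locus_flagged_degenerate(self):
        ds = make_dataset({"A": [[(1, 2), (0, 0)], [(1, 1), (0, 0)]]})
        est = estimate_null_freq(ds).get("A", "L2")
        assert est.degenerate
        assert est.null_freq == pytest.approx(1.0)

    def test_recovers_planted_null_frequency(self):
        cfg = SimConfig(population_labels=("A",), n_individuals_per_pop=500,
                        n_loci=1, n_alleles_per_locus=4, dirichlet_alpha=1.0,
                        theta_divergence=0.0, null_rate=0.2, seed=5)
        ds, _ = simulate_species(cfg)
        est = estimate_null_freq(ds).get("A", ds.locus_names[0])
        assert est.null_freq == pytest.approx(0.2, abs=0.05)

    def test_frequencies_sum_to_one(self):
        cfg = SimConfig(population_labels=("A", "B"), n_individuals_per_pop=30,
                        n_loci=5, n_alleles_per_locus=4, null_rate=0.1,
                        missing_rate=0.05, seed=6)
        ds, _ = simulate_species(cfg)
        table = estimate_null_freq(ds)
        for est in table.estimates.values():
            if not est.degenerate:
                assert est.total == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestWeirCockerhamFst:
    def test_matches_anova_oracle_on_toy_table(self):
        ds = make_dataset({
            "A": [[(1, 1), (3, 4)], [(1, 2), (3, 3)], [(2, 2), (4, 4)],
                  [(1, 2), (3, 4)]],
            "B": [[(1, 1), (3, 3)], [(1, 1), (3, 4)], [(1, 2), (3, 3)]],
            "C": [[(2, 2), (4, 4)], [(2, 2), (3, 4)], [(1, 2), (4, 4)],
                  [(2, 2), (4, 4)], [(1, 2), (3, 4)]],
        })
        mine = fst_global(ds, corrected=False)
        oracle = wc_theta_anova_oracle(ds)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_matches_oracle_with_missing_data(self):
        cfg = SimConfig(population_labels=("A", "B", "C"),
                        n_individuals_per_pop=12, n_loci=6,
                        n_alleles_per_locus=4, theta_divergence=0.1,
                        missing_rate=0.1, seed=13)
        ds, _ = simulate_species(cfg)
        mine = fst_global(ds, corrected=False)
        oracle = wc_theta_anova_oracle(ds)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_identical_source_frequencies_give_near_zero(self):
        cfg = SimConfig(population_labels=("A", "B"), n_individuals_per_pop=200,
                        n_loci=10, n_alleles_per_locus=4,
                        theta_divergence=0.0, seed=7)
        ds, _ = simulate_species(cfg)
        diff = fst_ena(ds)
        assert abs(diff.fst_global[("A", "B")]) < 0.01

    def test_fixed_disjoint_populations_give_one(self):
        ds = make_dataset({"A": [[(100, 100)]] * 5, "B": [[(200, 200)]] * 5})
        diff = fst_ena(ds)
        assert diff.fst_global_uncorrected[("A", "B")] == pytest.approx(1.0)

    def test_ena_equals_uncorrected_without_nulls(self):
        cfg = SimConfig(population_labels=("A", "B"), n_individuals_per_pop=100,
                        n_loci=8, n_alleles_per_locus=4, theta_divergence=0.08,
                        null_rate=0.0, seed=19)
        ds, _ = simulate_species(cfg)
        freqs = estimate_null_freq(ds)
        nulls = freqs.null_matrix()
        diff = fst_ena(ds, freqs)
        if np.nanmax(nulls) < 1e-6:
            assert diff.fst_global[("A", "B")] == pytest.approx(
                diff.fst_global_uncorrected[("A", "B")], abs=1e-9
            )
        else:  # EM found spurious nulls at this size; still close
            assert diff.fst_global[("A", "B")] == pytest.approx(
                diff.fst_global_uncorrected[("A", "B")], abs=5e-3
            )

    def test_invariant_under_allele_relabelling(self):
        cfg = SimConfig(population_labels=("A", "B"), n_individuals_per_pop=30,
                        n_loci=5, n_alleles_per_locus=4, theta_divergence=0.1,
                        seed=23)
        ds, _ = simulate_species(cfg)
        relabelled = ds.copy()
        for pop in relabelled.populations:
            g = pop.genotypes
            g[g > 0] = 1000 - g[g > 0]
        a = fst_ena(ds).fst_global[("A", "B")]
        b = fst_ena(relabelled).fst_global[("A", "B")]
        assert a == pytest.approx(b, abs=1e-9)

    def test_island_model_calibration(self):
        """Mean estimated theta tracks the generative target within 20%."""
        for theta in (0.01, 0.05, 0.15):
            vals = []
            for seed in range(100):
                cfg = SimConfig(
                    population_labels=("A", "B", "C", "D", "E"),
                    n_individuals_per_pop=20, n_loci=10,
                    n_alleles_per_locus=5, dirichlet_alpha=1.0,
                    theta_divergence=theta, seed=3000 + seed,
                )
                ds, _ = simulate_species(cfg)
                vals.append(fst_global(ds, corrected=False))
            mean = np.mean(vals)
            assert abs(mean - theta) / theta < 0.20, (theta, mean)


# ---------------------------------------------------------------------------
# Rho_ST
# ---------------------------------------------------------------------------

class TestRhoSt:
    def test_matches_anova_oracle(self):
        cfg = SimConfig(population_labels=("A", "B"), n_individuals_per_pop=15,
                        n_loci=4, n_alleles_per_locus=4, theta_divergence=0.1,
                        missing_rate=0.05, seed=31)
        ds, _ = simulate_species(cfg)
        mine = rho_st(ds).rho_global[("A", "B")]
        oracle = rho_anova_oracle(ds, "A", "B")
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_size_dispersion_separates_rho_from_fst(self):
        # same allele identities and frequencies, but B carries the extreme
        # sizes: F_ST ~ 0 while Rho_ST sees the size variance
        ds = make_dataset({
            "A": [[(100, 102)], [(102, 104)], [(100, 104)], [(102, 102)]],
            "B": [[(100, 120)], [(120, 120)], [(100, 100)], [(100, 120)]],
        })
        rho = rho_st(ds).rho_global[("A", "B")]
        fst = fst_ena(ds).fst_global_uncorrected[("A", "B")]
        assert rho > fst

    def test_affine_size_shift_invariance(self):
        cfg = SimConfig(population_labels=("A", "B"), n_individuals_per_pop=20,
                        n_loci=3, n_alleles_per_locus=4, theta_divergence=0.1,
                        seed=37)
        ds, _ = simulate_species(cfg)
        shifted = ds.copy()
        for pop in shifted.populations:
            g = pop.genotypes
            g[g > 0] = g[g > 0] + 50
        a = rho_st(ds).rho_global[("A", "B")]
        b = rho_st(shifted).rho_global[("A", "B")]
        assert a == pytest.approx(b, abs=1e-9)

    def test_size_permutation_changes_rho_not_fst(self):
        cfg = SimConfig(population_labels=("A", "B"), n_individuals_per_pop=25,
                        n_loci=1, n_alleles_per_locus=4, dirichlet_alpha=5.0,
                        theta_divergence=0.15, seed=41)
        ds, _ = simulate_species(cfg)
        sizes = sorted({a for p in ds.populations
                        for a in p.genotypes.ravel() if a > 0})
        assert len(sizes) >= 3
        # swapping the two smallest sizes is a non-affine permutation
        mapping = {s: s for s in sizes}
        mapping[sizes[0]], mapping[sizes[1]] = sizes[1], sizes[0]
        permuted = ds.copy()
        for pop in permuted.populations:
            g = pop.genotypes
            for old, new in [(o, mapping[o] + 10000) for o in sizes]:
                g[g == old] = new
        fst_a = fst_ena(ds).fst_global_uncorrected[("A", "B")]
        fst_b = fst_ena(permuted).fst_global_uncorrected[("A", "B")]
        assert fst_a == pytest.approx(fst_b, abs=1e-9)
        rho_a = rho_st(ds).rho_global[("A", "B")]
        rho_b = rho_st(permuted).rho_global[("A", "B")]
        assert abs(rho_a - rho_b) > 1e-6
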