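"""Per-population diversity and inbreeding statistics.

Implements the Nei-style small-sample estimators for observed
heterozygosity (H_o), within-population gene diversity (H_s), total gene
diversity (H_t), and the multilocus inbreeding coefficient
G_IS = 1 - H_o / H_s, along with mean and effective numbers of alleles
per locus.

Per locus with n typed diploid individuals and visible allele frequencies
p_i::

    H_o = observed heterozygote fraction
    H_s = (n / (n - 1)) * (1 - sum p_i^2 - H_o / (2 n))

G_IS is aggregated across loci from summed H_o and H_s components (Nei's
multilocus convention), never from rounded per-locus means; the ratio of
rounded means can differ in the third decimal.  When several populations
are pooled, the sample size entering the corrections is the harmonic mean
of the per-population typed counts and H_t applies the analogous
correction to the mean allele frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_model import MISSING, GenotypeDataset, PopulationSample

logger = logging.getLogger(__name__)


def locus_allele_freqs(pop: PopulationSample, locus: int) -> dict[int, float]:
    """Visible allele relative frequencies at one locus (missing excluded)."""
    alleles = pop.genotypes[:, locus, :].ravel()
    alleles = alleles[alleles != MISSING]
    if alleles.size == 0:
        return {}
    vals, counts = np.unique(alleles, return_counts=True)
    total = counts.sum()
    return {int(v): c / total for v, c in zip(vals, counts)}


def _locus_components(pop: PopulationSample, locus: int):
    """(n_typed, H_o, sum p^2, H_s) for one population x locus; None if untyped."""
    g = pop.genotypes[:, locus, :]
    typed = g[:, 0] != MISSING
    n = int(typed.sum())
    if n == 0:
        return None
    het = (g[typed, 0] != g[typed, 1]).mean()
    freqs = np.array(list(locus_allele_freqs(pop, locus).values()))
    sum_p2 = float((freqs**2).sum())
    if n < 2:
        return n, float(het), sum_p2, np.nan
    hs = (n / (n - 1.0)) * (1.0 - sum_p2 - het / (2.0 * n))
    return n, float(het), sum_p2, float(hs)


def allele_counts(ds: GenotypeDataset) -> pd.DataFrame:
    """Mean observed (Num) and effective (Eff_num) alleles per locus, per pop.

    Loci with no typed individuals in a population are excluded from that
    population's means and logged.
    """
    rows = []
    for pop in ds.populations:
        nums, effs = [], []
        for j in range(ds.n_loci):
            freqs = locus_allele_freqs(pop, j)
            if not freqs:
                logger.warning(
                    "population %s: locus %s all-missing, excluded",
                    pop.id, ds.locus_names[j],
                )
                continue
            p = np.array(list(freqs.values()))
            nums.append(len(freqs))
            effs.append(1.0 / float((p**2).sum()))
        rows.append(
            {
                "population": pop.id,
                "N": pop.n_individuals,
                "Num": float(np.mean(nums)) if nums else np.nan,
                "Eff_num": float(np.mean(effs)) if effs else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("population")


@dataclass
class DiversitySummary:
    """Per-population diversity table plus pooled totals for one species."""

    species_label: str
    per_population: pd.DataFrame  # index population; N Num Eff_num Ho Hs Ht GIS
    pooled_Ht: float              # total gene diversity over all populations
    pooled_Hs: float              # mean within-population gene diversity

    @property
    def gis(self) -> pd.Series:
        return self.per_population["GIS"]

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        return self.per_population.round(decimals)


def heterozygosity_stats(ds: GenotypeDataset) -> DiversitySummary:
    """Table of N, Num, Eff_num, H_o, H_s, H_t and G_IS per population.

    Per-population rows compute H_t over that single population, so the row
    prints H_s = H_t; pooled H_t across populations is reported separately
    on the summary.  G_IS is undefined (NaN) when every locus has H_s = 0.
    """
    counts = allele_counts(ds)
    rows = []
    # per-locus bookkeeping for the pooled statistics
    pooled_ht_num, pooled_hs_num, n_loci_pooled = 0.0, 0.0, 0
    s = len(ds.populations)
    for pop in ds.populations:
        if pop.n_individuals < 2:
            raise ValueError(
                f"population {pop.id!r} has < 2 individuals; "
                "heterozygosity estimators need at least 2"
            )
        ho_sum = hs_sum = 0.0
        ho_vals, hs_vals = [], []
        for j in range(ds.n_loci):
            comp = _locus_components(pop, j)
            if comp is None:
                continue
            _, ho, _, hs = comp
            ho_vals.append(ho)
            hs_vals.append(hs)
            ho_sum += ho
            hs_sum += hs
        mean_ho = float(np.mean(ho_vals)) if ho_vals else np.nan
        mean_hs = float(np.mean(hs_vals)) if hs_vals else np.nan
        gis = 1.0 - ho_sum / hs_sum if hs_sum > 0 else np.nan
        rows.append(
            {
                "population": pop.id,
                "N": pop.n_individuals,
                "Num": counts.loc[pop.id, "Num"],
                "Eff_num": counts.loc[pop.id, "Eff_num"],
                "Ho": mean_ho,
                "Hs": mean_hs,
                "Ht": mean_hs,  # single-population total equals H_s
                "GIS": gis,
            }
        )

    for j in range(ds.n_loci):
        comps = [c for c in (_locus_components(p, j) for p in ds.populations)
                 if c is not None]
        if len(comps) < s:          # pooled stats use fully typed loci only
            continue
        ns = np.array([c[0] for c in comps], dtype=float)
        n_harm = len(comps) / (1.0 / ns).sum()
        ho_bar = float(np.mean([c[1] for c in comps]))
        sum_p2_bar = float(np.mean([c[2] for c in comps]))
        hs_l = (n_harm / (n_harm - 1.0)) * (1.0 - sum_p2_bar - ho_bar / (2.0 * n_harm))
        # mean allele frequencies across populations
        allele_set: set[int] = set()
        per_pop_freqs = []
        for p in ds.populations:
            f = locus_allele_freqs(p, j)
            per_pop_freqs.append(f)
            allele_set.update(f)
        xbar2 = sum(
            (np.mean([f.get(a, 0.0) for f in per_pop_freqs])) ** 2
            for a in allele_set
        )
        ht_l = 1.0 - xbar2 + hs_l / (n_harm * s) - ho_bar / (2.0 * n_harm * s)
        pooled_ht_num += ht_l
        pooled_hs_num += hs_l
        n_loci_pooled += 1

    pooled_ht = pooled_ht_num / n_loci_pooled if n_loci_pooled else np.nan
    pooled_hs = pooled_hs_num / n_loci_pooled if n_loci_pooled else np.nan
    table = pd.DataFrame(rows).set_index("population")
    return DiversitySummary(ds.species_label, table, pooled_ht, pooled_hs)
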