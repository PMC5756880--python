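"""Null-allele frequency estimation (EM) and null-corrected differentiation.

Microsatellite null alleles fail to amplify: a null/visible heterozygote is
scored as a visible homozygote and a null homozygote as a missing genotype.
Ignoring them inflates homozygosity and biases F_ST.  This module
implements:

* an EM estimator of the per population x locus null-allele frequency,
  under Hardy-Weinberg with one unobservable allele and a genotyping
  failure rate (so genuinely missing data are not all attributed to null
  homozygotes);
* the Weir-Cockerham multiallelic F_ST variance-component estimator, both
  uncorrected and with the ENA ("excluding null alleles") correction that
  substitutes the EM-adjusted visible allele frequencies and drops the
  null class from the allele sums;
* Rho_ST, the allele-size analogue, from a one-way ANOVA of allele sizes
  (population / allele copies within population variance components).

Global multilocus values are ratios of summed variance components across
loci (and alleles), never means of per-locus ratios.  Per-locus estimates
may legitimately be negative and are not truncated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_model import MISSING, GenotypeDataset, PopulationSample


# ---------------------------------------------------------------------------
# EM estimation of null-allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class LocusNullEstimate:
    """EM result for one population x locus."""

    visible_freqs: dict[int, float]   # sum to 1 - null_freq
    null_freq: float
    failure_rate: float               # genuine genotyping-failure probability
    em_iterations: int
    em_converged: bool
    degenerate: bool = False          # e.g. all calls missing

    @property
    def total(self) -> float:
        return sum(self.visible_freqs.values()) + self.null_freq


@dataclass
class AlleleFrequencyTable:
    """Per population x locus visible-allele + null frequency estimates."""

    population_ids: list[str]
    locus_names: list[str]
    estimates: dict[tuple[str, str], LocusNullEstimate] = field(default_factory=dict)

    def get(self, pop_id: str, locus: str) -> LocusNullEstimate:
        return self.estimates[(pop_id, locus)]

    def null_matrix(self) -> np.ndarray:
        """(pops x loci) matrix of estimated null frequencies."""
        out = np.full((len(self.population_ids), len(self.locus_names)), np.nan)
        for i, p in enumerate(self.population_ids):
            for j, l in enumerate(self.locus_names):
                est = self.estimates.get((p, l))
                if est is not None:
                    out[i, j] = est.null_freq
        return out


def _em_locus(genotypes: np.ndarray, tol: float = 1e-6,
              max_iter: int = 10_000) -> LocusNullEstimate:
    """EM for one population x locus slice of shape (n, 2)."""
    n = genotypes.shape[0]
    typed = genotypes[genotypes[:, 0] != MISSING]
    n_miss = n - typed.shape[0]
    if typed.shape[0] == 0:
        return LocusNullEstimate({}, 1.0, 0.0, 0, True, degenerate=True)

    alleles = sorted(set(typed.ravel().tolist()))
    idx = {a: k for k, a in enumerate(alleles)}
    k = len(alleles)
    hom_counts = np.zeros(k)
    het_counts = np.zeros(k)  # allele copies carried in observed heterozygotes
    for a1, a2 in typed:
        if a1 == a2:
            hom_counts[idx[a1]] += 1
        else:
            het_counts[idx[a1]] += 1
            het_counts[idx[a2]] += 1

    # initialise from raw counts, small starting null frequency
    p = np.maximum(2 * hom_counts + het_counts, 1e-12)
    p = p / p.sum() * 0.98
    p0 = 0.02
    beta = 0.5 * n_miss / n if n_miss else 0.0
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        # E-step
        denom_hom = p**2 + 2 * p * p0
        e_true_hom = np.where(denom_hom > 0, hom_counts * p**2 / denom_hom, 0.0)
        e_null_het = hom_counts - e_true_hom
        if n_miss:
            pm = beta + (1 - beta) * p0**2
            e_nullnull = n_miss * ((1 - beta) * p0**2 / pm) if pm > 0 else 0.0
        else:
            e_nullnull = 0.0
        e_fail = n_miss - e_nullnull
        # M-step
        copies = 2 * e_true_hom + het_counts + e_null_het
        null_copies = e_null_het.sum() + 2 * e_nullnull
        total = copies.sum() + null_copies
        new_p = copies / total
        new_p0 = null_copies / total
        new_beta = e_fail / n if n_miss else 0.0
        delta = max(np.abs(new_p - p).max(initial=0.0), abs(new_p0 - p0),
                    abs(new_beta - beta))
        p, p0, beta = new_p, new_p0, new_beta
        if delta < tol:
            converged = True
            break
    visible = {a: float(p[idx[a]]) for a in alleles}
    return LocusNullEstimate(visible, float(p0), float(beta), it, converged,
                             degenerate=bool(p0 > 1 - 1e-6))


def estimate_null_freq(ds: GenotypeDataset, tol: float = 1e-6,
                       max_iter: int = 10_000) -> AlleleFrequencyTable:
    """EM null-allele frequency estimates for every population x locus."""
    table = AlleleFrequencyTable(ds.population_ids, list(ds.locus_names))
    for pop in ds.populations:
        if pop.n_individuals < 2:
            raise ValueError(f"population {pop.id!r} has < 2 individuals")
        for j, locus in enumerate(ds.locus_names):
            table.estimates[(pop.id, locus)] = _em_locus(
                pop.genotypes[:, j, :], tol, max_iter
            )
    return table


# ---------------------------------------------------------------------------
# Weir-Cockerham variance components
# ---------------------------------------------------------------------------

def _pop_locus_observed(pop: PopulationSample, locus: int):
    """(n_typed, {allele: freq}, {allele: het-carrier freq}) at one locus."""
    g = pop.genotypes[:, locus, :]
    typed = g[g[:, 0] != MISSING]
    n = typed.shape[0]
    if n == 0:
        return 0, {}, {}
    freqs: dict[int, float] = {}
    hets: dict[int, float] = {}
    for a1, a2 in typed:
        freqs[a1] = freqs.get(a1, 0.0) + 1
        freqs[a2] = freqs.get(a2, 0.0) + 1
        if a1 != a2:
            hets[a1] = hets.get(a1, 0.0) + 1
            hets[a2] = hets.get(a2, 0.0) + 1
    freqs = {a: c / (2 * n) for a, c in freqs.items()}
    hets = {a: c / n for a, c in hets.items()}
    return n, freqs, hets


def _wc_locus_components(ns, freq_dicts, het_dicts, alleles):
    """Weir-Cockerham (a, b, c) summed over the given allele classes.

    ``ns``: per-population typed sample sizes; ``freq_dicts``/``het_dicts``:
    per-population allele frequency and heterozygote-carrier frequency maps.
    Returns (sum_a, sum_b, sum_c); NaN triple if the locus is uninformative.
    """
    r = len(ns)
    ns = np.asarray(ns, dtype=float)
    if r < 2 or (ns > 0).sum() < 2:
        return np.nan, np.nan, np.nan
    nbar = ns.mean()
    if nbar <= 1:
        return np.nan, np.nan, np.nan
    nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return np.nan, np.nan, np.nan
    A = B = C = 0.0
    for u in alleles:
        p = np.array([f.get(u, 0.0) for f in freq_dicts])
        h = np.array([h_.get(u, 0.0) for h_ in het_dicts])
        pbar = (ns * p).sum() / (r * nbar)
        s2 = (ns * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, B, C


def _locus_inputs(ds: GenotypeDataset, pop_ids, locus_j: int,
                  freqs: AlleleFrequencyTable | None):
    """Per-population (n, freq, het) inputs for one locus, optionally ENA."""
    ns, fds, hds = [], [], []
    locus = ds.locus_names[locus_j]
    for pid in pop_ids:
        pop = ds.population(pid)
        n, f, h = _pop_locus_observed(pop, locus_j)
        if freqs is not None:
            est = freqs.get(pid, locus)
            if not est.degenerate:
                f = est.visible_freqs  # null-adjusted; null class excluded
        ns.append(n)
        fds.append(f)
        hds.append(h)
    return ns, fds, hds


@dataclass
class PairwiseDifferentiation:
    """Pairwise global and per-locus F_ST / Rho_ST for one dataset."""

    population_ids: list[str]
    locus_names: list[str]
    # per unordered pair (pid1, pid2):
    fst_global: dict[tuple[str, str], float] = field(default_factory=dict)
    fst_global_uncorrected: dict[tuple[str, str], float] = field(default_factory=dict)
    fst_per_locus: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    fst_per_locus_uncorrected: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    rho_global: dict[tuple[str, str], float] = field(default_factory=dict)
    rho_per_locus: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    ena_corrected: bool = True
    rho_null_corrected: bool = False  # Rho_ST is reported uncorrected

    def pair(self, pid1: str, pid2: str) -> tuple[str, str]:
        key = (pid1, pid2)
        if key in self.fst_global or key in self.rho_global:
            return key
        return (pid2, pid1)

    def matrix(self, which: str = "fst_global") -> np.ndarray:
        vals = getattr(self, which)
        k = len(self.population_ids)
        out = np.full((k, k), np.nan)
        for (p1, p2), v in vals.items():
            i, j = self.population_ids.index(p1), self.population_ids.index(p2)
            out[i, j] = out[j, i] = v
        return out


def _resolve_pairs(ds: GenotypeDataset, pairs):
    if pairs is None or pairs == "all":
        return list(itertools.combinations(ds.population_ids, 2))
    return [tuple(p) for p in pairs]


def fst_components(ds: GenotypeDataset, pop_ids,
                   freqs: AlleleFrequencyTable | None = None) -> np.ndarray:
    """(n_loci, 3) Weir-Cockerham components for the given populations.

    With ``freqs`` supplied, allele frequencies are the EM null-adjusted
    visible frequencies (the ENA correction); the null class never enters
    the allele sums.  Sample sizes always count typed individuals only.
    """
    comps = np.full((ds.n_loci, 3), np.nan)
    for j in range(ds.n_loci):
        ns, fds, hds = _locus_inputs(ds, pop_ids, j, freqs)
        alleles = sorted({a for f in fds for a in f})
        if not alleles:
            continue
        # a locus monomorphic in both populations yields (0, 0, 0) and
        # drops out of the ratio-of-sums; under ENA a visible frequency
        # below 1 (null complement) still contributes variance.
        comps[j] = _wc_locus_components(ns, fds, hds, alleles)
    return comps


def fst_from_components(comps: np.ndarray) -> float:
    """Ratio-of-sums multilocus theta from (n_loci, 3) components."""
    ok = ~np.isnan(comps).any(axis=1)
    denom = comps[ok].sum(axis=0)
    total = denom.sum()
    if not ok.any() or total == 0:
        return float("nan")
    return float(denom[0] / total)


def fst_ena(ds: GenotypeDataset, freqs: AlleleFrequencyTable | None = None,
            pairs="all") -> PairwiseDifferentiation:
    """Pairwise ENA-corrected and uncorrected Weir-Cockerham F_ST.

    Each pairwise estimate uses variance components of the two focal
    populations only.  ``freqs`` defaults to a fresh EM run on ``ds``.
    """
    if freqs is None:
        freqs = estimate_null_freq(ds)
    result = PairwiseDifferentiation(ds.population_ids, list(ds.locus_names))
    for pid1, pid2 in _resolve_pairs(ds, pairs):
        comp_ena = fst_components(ds, [pid1, pid2], freqs)
        comp_raw = fst_components(ds, [pid1, pid2], None)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_locus_ena = comp_ena[:, 0] / comp_ena.sum(axis=1)
            per_locus_raw = comp_raw[:, 0] / comp_raw.sum(axis=1)
        key = (pid1, pid2)
        result.fst_global[key] = fst_from_components(comp_ena)
        result.fst_global_uncorrected[key] = fst_from_components(comp_raw)
        result.fst_per_locus[key] = per_locus_ena
        result.fst_per_locus_uncorrected[key] = per_locus_raw
    return result


def fst_global(ds: GenotypeDataset, freqs: AlleleFrequencyTable | None = None,
               corrected: bool = True) -> float:
    """Multilocus theta over all populations of the dataset."""
    if corrected and freqs is None:
        freqs = estimate_null_freq(ds)
    comps = fst_components(ds, ds.population_ids, freqs if corrected else None)
    return fst_from_components(comps)


# ---------------------------------------------------------------------------
# Rho_ST: allele-size variance components
# ---------------------------------------------------------------------------

def _rho_locus_components(groups: list[np.ndarray]):
    """(sigma2_among, MS_within) from a one-way ANOVA on allele sizes."""
    groups = [g.astype(float) for g in groups if g.size > 0]
    r = len(groups)
    if r < 2:
        return np.nan, np.nan
    ns = np.array([g.size for g in groups], dtype=float)
    N = ns.sum()
    if N <= r:
        return np.nan, np.nan
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssa = (ns * (means - grand) ** 2).sum()
    ssw = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    msa = ssa / (r - 1)
    msw = ssw / (N - r)
    n0 = (N - (ns**2).sum() / N) / (r - 1)
    sigma_a = (msa - msw) / n0
    return sigma_a, msw


def rho_st(ds: GenotypeDataset, pairs="all") -> PairwiseDifferentiation:
    """Pairwise Rho_ST from allele-size ANOVA; per-locus and ratio-of-sums.

    Allele codes are interpreted as sizes on the fragment-length ladder.
    No null-allele correction is applied (flagged on the result metadata).
    """
    result = PairwiseDifferentiation(
        ds.population_ids, list(ds.locus_names), ena_corrected=False
    )
    for pid1, pid2 in _resolve_pairs(ds, pairs):
        per_locus = np.full(ds.n_loci, np.nan)
        sum_a = sum_tot = 0.0
        any_ok = False
        for j in range(ds.n_loci):
            groups = []
            for pid in (pid1, pid2):
                g = ds.population(pid).genotypes[:, j, :].ravel()
                groups.append(g[g != MISSING])
            sa, msw = _rho_locus_components(groups)
            if math.isnan(sa):
                continue
            tot = sa + msw
            per_locus[j] = sa / tot if tot != 0 else np.nan
            sum_a += sa
            sum_tot += tot
            any_ok = True
        key = (pid1, pid2)
        result.rho_per_locus[key] = per_locus
        result.rho_global[key] = sum_a / sum_tot if any_ok and sum_tot else float("nan")
    return result
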