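"""Exact tests for HWE, genotypic linkage disequilibrium, and genic
population differentiation, with Fisher's combined probability and
Bonferroni multiplicity arithmetic.

The HWE test is the conditional probability test: given the observed
allele counts at a locus, the probability of a diploid genotype table under
Hardy-Weinberg (Levene's conditional distribution) is

    P(table) = n! * 2^H * prod_a n_a! / ((2n)! * prod_{a<=b} n_ab!)

with H the number of heterozygotes.  The p-value is the total probability
of tables no more probable than the observed one.  Small tables are fully
enumerated; larger ones are sampled with a Guo-Thompson-style Markov chain
(allele switches between two individuals, Metropolis-accepted), run as
dememorization followed by batches whose means give a Monte-Carlo SE.

LD and genic differentiation use permutation null distributions of the
log-likelihood-ratio G statistic: genotypes permuted among individuals
within a population (LD), or allele copies permuted between the two
populations (genic test).  Per-stratum p-values are combined with Fisher's
method, X^2 = -2 sum ln p_i on 2k df; an estimated p of zero propagates as
X^2 = infinity and the combined p is reported as bounded by the chain
resolution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotype_model import MISSING, GenotypeDataset, PopulationSample


# ---------------------------------------------------------------------------
# Chain / permutation parameters and shared arithmetic
# ---------------------------------------------------------------------------

@dataclass
class ChainParams:
    """Markov-chain settings (GenePop-style defaults) and permutation count."""

    dememorization: int = 10_000
    batches: int = 20
    iterations_per_batch: int = 5_000
    n_permutations: int = 2_000  # for the permutation-based tests
    enumeration_limit: int = 200_000  # max tables to enumerate exactly

    @property
    def chain_length(self) -> int:
        return self.batches * self.iterations_per_batch


@dataclass
class ExactTestResult:
    """Combined exact-test outcome for one unit (population, locus pair...)."""

    unit: str
    p_value: float
    statistic: float          # Fisher's combined X^2 (may be inf)
    df: int
    se: float = float("nan")  # Monte-Carlo SE where applicable
    p_floor: float = 0.0      # resolution: reported "p < p_floor" when p == 0
    components: dict[str, float] = field(default_factory=dict)

    @property
    def significant_at(self) -> float:
        return self.p_value

    def __repr__(self):  # pragma: no cover - cosmetic
        p = f"< {self.p_floor:g}" if self.p_value == 0.0 else f"= {self.p_value:.4g}"
        chi = "inf" if math.isinf(self.statistic) else f"{self.statistic:.2f}"
        return f"<ExactTestResult {self.unit}: X2={chi}, df={self.df}, p {p}>"


def n_locus_pairs(n_loci: int) -> int:
    """Number of unordered locus pairs tested for LD."""
    return n_loci * (n_loci - 1) // 2


def n_population_pairs(n_pops: int) -> int:
    return n_pops * (n_pops - 1) // 2


def bonferroni_alpha(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test significance threshold under Bonferroni control."""
    if n_tests < 1:
        raise ValueError("need at least one test")
    return alpha / n_tests


def fisher_combine(p_values, p_floor: float = 0.0) -> tuple[float, int, float]:
    """Fisher's method: returns (X^2, df, combined p).

    Any component p of exactly zero yields X^2 = inf and combined p = 0
    (to be reported as "< p_floor").
    """
    ps = [p for p in p_values if not math.isnan(p)]
    df = 2 * len(ps)
    if not ps:
        return float("nan"), 0, float("nan")
    if any(p == 0.0 for p in ps):
        return float("inf"), df, 0.0
    x2 = -2.0 * sum(math.log(p) for p in ps)
    return x2, df, float(stats.chi2.sf(x2, df))


# ---------------------------------------------------------------------------
# HWE exact probability test
# ---------------------------------------------------------------------------

def genotype_table(pop: PopulationSample, locus: int) -> dict[tuple[int, int], int]:
    """Observed genotype counts {(a<=b): count} at one locus, missing dropped."""
    g = pop.genotypes[:, locus, :]
    typed = g[g[:, 0] != MISSING]
    table: dict[tuple[int, int], int] = {}
    for a1, a2 in typed:
        key = (int(min(a1, a2)), int(max(a1, a2)))
        table[key] = table.get(key, 0) + 1
    return table


def _allele_counts_from_table(table: dict[tuple[int, int], int]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for (a, b), n in table.items():
        counts[a] = counts.get(a, 0) + n
        counts[b] = counts.get(b, 0) + n
    return counts


def log_table_prob(table: dict[tuple[int, int], int]) -> float:
    """Log conditional probability of a genotype table given allele counts."""
    n = sum(table.values())
    allele = _allele_counts_from_table(table)
    h = sum(c for (a, b), c in table.items() if a != b)
    lp = math.lgamma(n + 1) + h * math.log(2.0)
    lp += sum(math.lgamma(c + 1) for c in allele.values())
    lp -= math.lgamma(2 * n + 1)
    lp -= sum(math.lgamma(c + 1) for c in table.values())
    return lp


def enumerate_tables(allele_counts: dict[int, int], limit: int | None = None):
    """Yield every genotype table consistent with the given allele counts."""
    alleles = sorted(allele_counts)
    cells = [(a, b) for i, a in enumerate(alleles) for b in alleles[i:]]
    counts = dict(allele_counts)
    seen = 0

    def rec(idx: int, table: dict[tuple[int, int], int]):
        nonlocal seen
        if idx == len(cells):
            if all(v == 0 for v in counts.values()):
                seen += 1
                if limit is not None and seen > limit:
                    raise OverflowError("enumeration limit exceeded")
                yield dict(table)
            return
        a, b = cells[idx]
        if a == b:
            max_n = counts[a] // 2
        else:
            max_n = min(counts[a], counts[b])
        for k in range(max_n, -1, -1):
            if a == b:
                counts[a] -= 2 * k
            else:
                counts[a] -= k
                counts[b] -= k
            if k:
                table[(a, b)] = k
            yield from rec(idx + 1, table)
            if k:
                del table[(a, b)]
            if a == b:
                counts[a] += 2 * k
            else:
                counts[a] += k
                counts[b] += k

    yield from rec(0, {})


def hwe_exact_locus(pop: PopulationSample, locus: int,
                    chain: ChainParams | None = None,
                    rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Exact HWE probability-test p-value at one locus: (p, MC standard error).

    SE is 0 when the table space was fully enumerated.
    """
    chain = chain or ChainParams()
    table = genotype_table(pop, locus)
    allele = _allele_counts_from_table(table)
    if len(allele) < 2:
        return float("nan"), 0.0
    lp_obs = log_table_prob(table)
    eps = 1e-9
    try:
        total = obs_mass = 0.0
        for t in enumerate_tables(allele, limit=chain.enumeration_limit):
            lp = log_table_prob(t)
            p = math.exp(lp)
            total += p
            if lp <= lp_obs + eps:
                obs_mass += p
        return min(obs_mass / total, 1.0), 0.0
    except OverflowError:
        pass

    # Markov chain over ordered allele-copy assignments to individuals.
    # The uniform distribution on these arrangements induces exactly the
    # Levene conditional distribution on genotype tables (the table's state
    # count is n! 2^H / prod n_ab! up to constants), so a random switch of
    # two allele copies is always accepted; only the running table log
    # probability needs updating.
    rng = rng if rng is not None else np.random.default_rng()
    genos = []
    for (a, b), c in table.items():
        genos.extend([[a, b]] * c)
    genos = np.array(genos, dtype=np.int64)
    n = len(genos)
    counts = dict(table)
    lp_cur = lp_obs

    def delta_pair(a, b, c, d):
        """Table log-prob change when (a,b),(c,d) become (c,b),(a,d)."""
        old = [(min(a, b), max(a, b)), (min(c, d), max(c, d))]
        new = [(min(c, b), max(c, b)), (min(a, d), max(a, d))]
        delta = 0.0
        for key in old:
            delta += math.lgamma(counts[key] + 1)
            counts[key] -= 1
            delta -= math.lgamma(counts[key] + 1)
            if key[0] != key[1]:
                delta -= math.log(2.0)  # one heterozygote fewer
            if counts[key] == 0:
                del counts[key]
        for key in new:
            prev = counts.get(key, 0)
            delta += math.lgamma(prev + 1)
            counts[key] = prev + 1
            delta -= math.lgamma(prev + 2)
            if key[0] != key[1]:
                delta += math.log(2.0)  # one heterozygote more
        return delta

    def step():
        nonlocal lp_cur
        i, j = rng.integers(0, n, 2)
        if i == j:
            return
        si, sj = rng.integers(0, 2, 2)
        a, b = genos[i, si], genos[i, 1 - si]
        c, d = genos[j, sj], genos[j, 1 - sj]
        if a == c:  # identical copies: table unchanged
            return
        lp_cur += delta_pair(a, b, c, d)
        genos[i, si], genos[j, sj] = c, a

    for _ in range(chain.dememorization):
        step()
    batch_means = []
    for _ in range(chain.batches):
        hits = 0
        for _ in range(chain.iterations_per_batch):
            step()
            if lp_cur <= lp_obs + eps:
                hits += 1
        batch_means.append(hits / chain.iterations_per_batch)
    p_hat = float(np.mean(batch_means))
    se = float(np.std(batch_means, ddof=1) / math.sqrt(chain.batches))
    return p_hat, se


def hwe_exact(ds: GenotypeDataset, chain: ChainParams | None = None,
              seed: int | None = None) -> dict[str, ExactTestResult]:
    """Per-population HWE test, locus p-values combined by Fisher's method.

    Monomorphic (or untyped) loci are skipped and do not contribute df.
    """
    chain = chain or ChainParams()
    rng = np.random.default_rng(seed)
    out: dict[str, ExactTestResult] = {}
    floor = 1.0 / chain.chain_length
    for pop in ds.populations:
        comps: dict[str, float] = {}
        ses = []
        for j, name in enumerate(ds.locus_names):
            p, se = hwe_exact_locus(pop, j, chain, rng)
            if math.isnan(p):
                continue
            comps[name] = p
            ses.append(se)
        x2, df, p_comb = fisher_combine(comps.values(), floor)
        out[pop.id] = ExactTestResult(
            unit=pop.id, p_value=p_comb, statistic=x2, df=df,
            se=float(np.mean(ses)) if ses else 0.0, p_floor=floor,
            components=comps,
        )
    return out


# ---------------------------------------------------------------------------
# Permutation G tests
# ---------------------------------------------------------------------------

def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio G of an r x c contingency table (zeros ignored)."""
    table = table.astype(float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    mask = table > 0
    return float(2.0 * (table[mask] * np.log(table[mask] / expected[mask])).sum())


def _genotype_codes(pop: PopulationSample, locus: int) -> np.ndarray:
    """Integer code per individual for its (unordered) genotype; -1 missing."""
    g = np.sort(pop.genotypes[:, locus, :], axis=1)
    codes = np.full(pop.n_individuals, -1, dtype=np.int64)
    typed = g[:, 0] != MISSING
    if typed.any():
        pairs, inv = np.unique(g[typed], axis=0, return_inverse=True)
        codes[typed] = inv
    return codes


def _perm_pvalue(obs: float, null: np.ndarray) -> float:
    return float((1 + (null >= obs - 1e-12).sum()) / (1 + len(null)))


def ld_exact(ds: GenotypeDataset, chain: ChainParams | None = None,
             seed: int | None = None) -> dict[tuple[str, str], ExactTestResult]:
    """Genotypic LD for every locus pair, combined over populations.

    Within each population the two-locus genotype contingency table's G
    statistic is referred to its permutation distribution (one locus's
    genotypes shuffled among individuals).  Populations in which either
    locus is monomorphic among co-typed individuals contribute no test and
    no df.  The Bonferroni threshold for the full set of pairs is
    ``bonferroni_alpha(n_locus_pairs(L))``.
    """
    chain = chain or ChainParams()
    rng = np.random.default_rng(seed)
    n_perm = chain.n_permutations
    floor = 1.0 / (1 + n_perm)
    results: dict[tuple[str, str], ExactTestResult] = {}
    codes = {  # per population, per locus genotype codes
        pop.id: [_genotype_codes(pop, j) for j in range(ds.n_loci)]
        for pop in ds.populations
    }
    for j1, j2 in itertools.combinations(range(ds.n_loci), 2):
        comps: dict[str, float] = {}
        for pop in ds.populations:
            c1, c2 = codes[pop.id][j1], codes[pop.id][j2]
            both = (c1 >= 0) & (c2 >= 0)
            a, b = c1[both], c2[both]
            if len(a) < 2 or len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                continue
            k1, k2 = a.max() + 1, b.max() + 1
            obs = _g_statistic(
                np.bincount(a * k2 + b, minlength=k1 * k2).reshape(k1, k2)
            )
            null = np.empty(n_perm)
            for t in range(n_perm):
                bp = rng.permutation(b)
                null[t] = _g_statistic(
                    np.bincount(a * k2 + bp, minlength=k1 * k2).reshape(k1, k2)
                )
            comps[pop.id] = _perm_pvalue(obs, null)
        x2, df, p_comb = fisher_combine(comps.values(), floor)
        key = (ds.locus_names[j1], ds.locus_names[j2])
        results[key] = ExactTestResult(
            unit=f"{key[0]}*{key[1]}", p_value=p_comb, statistic=x2,
            df=df, p_floor=floor, components=comps,
        )
    return results


def genic_differentiation_exact(
    ds: GenotypeDataset, chain: ChainParams | None = None,
    seed: int | None = None, pairs: list[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], ExactTestResult]:
    """Exact G test of allele-frequency homogeneity for population pairs.

    Per locus, allele copies are pooled across the two populations and
    permuted between them; G on the 2 x alleles count table is referred to
    that null.  Locus p-values are combined with Fisher's method.  The
    Bonferroni threshold across all pairs of the dataset's populations is
    ``bonferroni_alpha(n_population_pairs(P))``.
    """
    chain = chain or ChainParams()
    rng = np.random.default_rng(seed)
    n_perm = chain.n_permutations
    floor = 1.0 / (1 + n_perm)
    if pairs is None:
        pairs = list(itertools.combinations(ds.population_ids, 2))
    results: dict[tuple[str, str], ExactTestResult] = {}
    for pid1, pid2 in pairs:
        pop1, pop2 = ds.population(pid1), ds.population(pid2)
        comps: dict[str, float] = {}
        for j, name in enumerate(ds.locus_names):
            al1 = pop1.genotypes[:, j, :].ravel()
            al2 = pop2.genotypes[:, j, :].ravel()
            al1, al2 = al1[al1 != MISSING], al2[al2 != MISSING]
            pooled = np.concatenate([al1, al2])
            if len(al1) == 0 or len(al2) == 0 or len(np.unique(pooled)) < 2:
                continue
            vals, coded = np.unique(pooled, return_inverse=True)
            k = len(vals)
            n1 = len(al1)
            labels = np.zeros(len(pooled), dtype=np.int64)
            labels[n1:] = 1

            def tab(lbl):
                return np.bincount(lbl * k + coded, minlength=2 * k).reshape(2, k)

            obs = _g_statistic(tab(labels))
            null = np.empty(n_perm)
            for t in range(n_perm):
                null[t] = _g_statistic(tab(rng.permutation(labels)))
            comps[name] = _perm_pvalue(obs, null)
        x2, df, p_comb = fisher_combine(comps.values(), floor)
        results[(pid1, pid2)] = ExactTestResult(
            unit=f"{pid1}&{pid2}", p_value=p_comb, statistic=x2, df=df,
            p_floor=floor, components=comps,
        )
    return results
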