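"""Bayesian estimation of recent migration fractions among populations.

The model follows the BayesAss family: each individual in population ``l``
is a non-migrant, a first-generation migrant from ``q``, or a
second-generation migrant (one parent from ``q``).  The migration matrix
``m`` is row-stochastic with non-migrant fraction ``m[l][l] >= 2/3`` (the
off-diagonal row sum may not exceed 1/3), because an estimated migrant
fraction larger than that is unidentifiable from a single generation of
genotypes.  Given its ancestry, an individual's multilocus genotype
likelihood uses the source population's allele frequencies with that
population's inbreeding coefficient,

    P(hom a | p, F) = F p_a + (1 - F) p_a^2
    P(het ab | p, F) = (1 - F) 2 p_a p_b,

while a second-generation migrant draws one gamete from each population
(no inbreeding term).  Priors are uniform on the constrained supports.

Ancestry prior given ``m`` for an individual resident in ``l``::

    P(non-migrant)                  = 1 - sum_{q != l} m[l][q]
    P(gen-1 from q) = P(gen-2 from q) = m[l][q] / 2

so ``m[l][q]`` is the fraction of ``l`` with recent ancestry in ``q``.

Sampling is Metropolis-within-Gibbs: (i) Gibbs resampling of one
individual's ancestry class, (ii) random-walk moves on one off-diagonal
``m`` entry within the simplex constraint, (iii) mass-transfer moves
between two allele frequencies of one population x locus, (iv) reflected
random walk on one population's F.  The mixing parameter scales each
proposal window as ``window = mixing * support_width / 2`` (support widths:
1/3 for an ``m`` entry, 1 for a frequency coordinate and for F).

Significance of a posterior migration fraction follows the
mean +/- 1.96 * SD rule: an off-diagonal entry is flagged when that
interval excludes zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_model import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

FREQ_FLOOR = 1e-6  # keeps alleles unseen in a population at positive frequency
_MOVE_NAMES = ("ancestry", "migration", "frequency", "inbreeding")
_MOVE_WEIGHTS = (0.70, 0.10, 0.15, 0.05)


@dataclass
class MigrationPosterior:
    """Posterior summary of the recent-migration model."""

    population_ids: list[str]
    mean: np.ndarray                    # (P, P) posterior mean of m
    sd: np.ndarray                      # (P, P) posterior SD of m
    f_mean: np.ndarray                  # (P,) posterior mean inbreeding
    f_sd: np.ndarray
    traces: list[pd.DataFrame]          # one thinned trace per chain
    acceptance: dict[str, float]
    n_generations: int
    burn_in: int
    thin: int

    @property
    def significant(self) -> np.ndarray:
        """Off-diagonal entries whose mean +/- 1.96 SD excludes zero."""
        flags = (self.mean - 1.96 * self.sd) > 0.0
        np.fill_diagonal(flags, False)
        return flags

    def summary_table(self) -> pd.DataFrame:
        """Row -> column oriented matrix of posterior means."""
        return pd.DataFrame(self.mean, index=self.population_ids,
                            columns=self.population_ids)


class _SamplerState:
    """Mutable chain state with cached per-individual log-likelihoods.

    Class encoding: ``c = 2 s + t`` with source population ``s`` and
    ``t = 0`` pure ancestry in ``s`` (non-migrant when ``s`` is home,
    first-generation migrant otherwise) or ``t = 1`` one gamete from ``s``
    and one from home (second-generation migrant; prior zero when ``s``
    is home).
    """

    def __init__(self, ds: GenotypeDataset, rng: np.random.Generator,
                 mixing: float, use_likelihood: bool = True):
        self.rng = rng
        self.use_likelihood = use_likelihood
        self.P = len(ds.populations)
        self.L = ds.n_loci
        self.pop_ids = ds.population_ids

        home, g1, g2 = [], [], []
        self.allele_maps: list[dict[int, int]] = []
        for j in range(ds.n_loci):
            alleles = sorted(
                {int(a) for pop in ds.populations
                 for a in pop.genotypes[:, j, :].ravel() if a != MISSING}
            )
            self.allele_maps.append({a: k for k, a in enumerate(alleles)})
        for pi, pop in enumerate(ds.populations):
            for i in range(pop.n_individuals):
                home.append(pi)
                row1, row2 = [], []
                for j in range(ds.n_loci):
                    a1, a2 = pop.genotypes[i, j]
                    if a1 == MISSING:
                        row1.append(-1)
                        row2.append(-1)
                    else:
                        row1.append(self.allele_maps[j][int(a1)])
                        row2.append(self.allele_maps[j][int(a2)])
                g1.append(row1)
                g2.append(row2)
        self.home = np.array(home)
        self.g1 = np.array(g1)  # (N, L) allele index or -1
        self.g2 = np.array(g2)
        self.N = len(home)
        self.Amax = max((len(m) for m in self.allele_maps), default=1)

        # Proposal windows from the mixing parameter: an m entry moves
        # within +/- mixing * (1/3)/2 (half its support); a frequency
        # mass-transfer and an F step use a quarter of their unit support,
        # since full-width windows leave single-coordinate random walks
        # with poor acceptance on these strongly informed parameters.
        self.win_m = mixing * (1.0 / 3.0) / 2.0
        self.win_p = mixing * 0.25
        self.win_f = mixing * 0.25

        # initial values
        self.p = np.zeros((self.P, self.L, self.Amax))
        for pi, pop in enumerate(ds.populations):
            for j in range(self.L):
                counts = np.full(len(self.allele_maps[j]), 0.5)
                for a1, a2 in pop.genotypes[:, j]:
                    if a1 != MISSING:
                        counts[self.allele_maps[j][int(a1)]] += 1
                        counts[self.allele_maps[j][int(a2)]] += 1
                freqs = np.maximum(counts / counts.sum(), FREQ_FLOOR)
                self.p[pi, j, : len(freqs)] = freqs / freqs.sum()
        self.F = np.full(self.P, 0.1)
        off0 = min(0.01, (1.0 / 3.0) / max(self.P - 1, 1) / 2)
        self.m = np.full((self.P, self.P), off0)
        np.fill_diagonal(self.m, 0.0)
        np.fill_diagonal(self.m, 1.0 - self.m.sum(axis=1))
        self.cls = 2 * self.home  # everyone starts as a non-migrant
        # n_src[l, q]: individuals resident in l with source q (either gen)
        self.n_src = np.zeros((self.P, self.P), dtype=np.int64)
        for h in self.home:
            self.n_src[h, h] += 1

        self.ll3 = np.zeros((self.N, 2 * self.P, self.L))
        if self.use_likelihood:
            for j in range(self.L):
                self.ll3[:, :, j] = self._loglik_locus(j, self.p, self.F)
        self.lls = self.ll3.sum(axis=2)  # (N, 2P)
        self.proposed = dict.fromkeys(_MOVE_NAMES, 0)
        self.accepted = dict.fromkeys(_MOVE_NAMES, 0)

    # -- likelihood kernels -------------------------------------------------

    def _loglik_locus(self, j: int, p: np.ndarray, F: np.ndarray) -> np.ndarray:
        """(N, 2P) log-likelihood of locus j under every ancestry class."""
        a1, a2 = self.g1[:, j], self.g2[:, j]
        typed = a1 >= 0
        hom = typed & (a1 == a2)
        het = typed & ~hom
        out = np.zeros((self.N, 2 * self.P))
        ph_a = p[self.home, j, np.where(typed, a1, 0)]
        ph_b = p[self.home, j, np.where(typed, a2, 0)]
        for s in range(self.P):
            ps_a = p[s, j, np.where(typed, a1, 0)]
            ps_b = p[s, j, np.where(typed, a2, 0)]
            pure = np.zeros(self.N)
            pure[hom] = F[s] * ps_a[hom] + (1 - F[s]) * ps_a[hom] ** 2
            pure[het] = (1 - F[s]) * 2 * ps_a[het] * ps_b[het]
            mixed = np.zeros(self.N)
            mixed[hom] = ps_a[hom] * ph_a[hom]
            mixed[het] = ps_a[het] * ph_b[het] + ps_b[het] * ph_a[het]
            with np.errstate(divide="ignore"):
                out[:, 2 * s] = np.where(typed, np.log(np.maximum(pure, 1e-300)), 0.0)
                out[:, 2 * s + 1] = np.where(
                    typed, np.log(np.maximum(mixed, 1e-300)), 0.0
                )
        return out

    def _log_prior_classes(self, h: int) -> np.ndarray:
        """(2P,) log ancestry-class prior for a resident of population h."""
        lp = np.full(2 * self.P, -np.inf)
        stay = 1.0 - (self.m[h].sum() - self.m[h, h])
        with np.errstate(divide="ignore"):
            lp[2 * h] = np.log(stay) if stay > 0 else -np.inf
            for q in range(self.P):
                if q == h:
                    continue
                val = self.m[h, q] / 2.0
                lp[2 * q] = lp[2 * q + 1] = np.log(val) if val > 0 else -np.inf
        return lp

    def total_loglik(self) -> float:
        return float(self.lls[np.arange(self.N), self.cls].sum())

    # -- moves --------------------------------------------------------------

    def move_ancestry(self):
        self.proposed["ancestry"] += 1
        i = int(self.rng.integers(self.N))
        h = self.home[i]
        logw = self._log_prior_classes(h) + self.lls[i]
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        new = int(self.rng.choice(2 * self.P, p=w))
        old = self.cls[i]
        if new != old:
            self.accepted["ancestry"] += 1
            self.n_src[h, old // 2] -= 1
            self.n_src[h, new // 2] += 1
            self.cls[i] = new

    def move_migration(self):
        self.proposed["migration"] += 1
        if self.P < 2:
            return
        l = int(self.rng.integers(self.P))
        q = int(self.rng.integers(self.P - 1))
        if q >= l:
            q += 1
        cur = self.m[l, q]
        prop = cur + self.rng.uniform(-self.win_m, self.win_m)
        off_others = self.m[l].sum() - self.m[l, l] - cur
        if prop < 0 or off_others + prop > 1.0 / 3.0:
            return
        stay_old = 1.0 - off_others - cur
        stay_new = 1.0 - off_others - prop
        n_stay = self.n_src[l, l]
        n_q = self.n_src[l, q]
        logr = 0.0
        if n_stay:
            if stay_new <= 0:
                return
            logr += n_stay * (math.log(stay_new) - math.log(stay_old))
        if n_q:
            if prop <= 0:
                return
            logr += n_q * (math.log(prop) - math.log(cur))
        if logr >= 0 or math.log(self.rng.random()) < logr:
            self.accepted["migration"] += 1
            self.m[l, q] = prop
            self.m[l, l] = stay_new

    def move_frequency(self):
        self.proposed["frequency"] += 1
        s = int(self.rng.integers(self.P))
        j = int(self.rng.integers(self.L))
        k = len(self.allele_maps[j])
        if k < 2:
            return
        a, b = self.rng.choice(k, size=2, replace=False)
        d = self.rng.uniform(0, self.win_p)
        pa, pb = self.p[s, j, a], self.p[s, j, b]
        if pa - d < FREQ_FLOOR or pb + d > 1.0 - FREQ_FLOOR:
            return
        old_col = self.ll3[:, :, j].copy() if self.use_likelihood else None
        self.p[s, j, a] = pa - d
        self.p[s, j, b] = pb + d
        if self.use_likelihood:
            new_col = self._loglik_locus(j, self.p, self.F)
            idx = np.arange(self.N)
            delta = float((new_col[idx, self.cls] - old_col[idx, self.cls]).sum())
        else:
            new_col, delta = None, 0.0
        if delta >= 0 or math.log(self.rng.random()) < delta:
            self.accepted["frequency"] += 1
            if self.use_likelihood:
                self.lls += new_col - old_col
                self.ll3[:, :, j] = new_col
        else:
            self.p[s, j, a] = pa
            self.p[s, j, b] = pb

    def move_inbreeding(self):
        self.proposed["inbreeding"] += 1
        s = int(self.rng.integers(self.P))
        cur = self.F[s]
        prop = cur + self.rng.uniform(-self.win_f, self.win_f)
        # reflect into [0, 1)
        if prop < 0:
            prop = -prop
        if prop >= 1:
            prop = 2 - prop - 1e-12
        if prop < 0 or prop >= 1:
            return
        if not self.use_likelihood:
            self.accepted["inbreeding"] += 1
            self.F[s] = cur = prop
            return
        col = 2 * s  # only the pure-ancestry class of source s depends on F_s
        old = self.ll3[:, col, :].copy()
        F_new = self.F.copy()
        F_new[s] = prop
        new = np.empty_like(old)
        for j in range(self.L):
            new[:, j] = self._loglik_locus_pure(j, s, F_new[s])
        affected = self.cls == col
        delta = float((new[affected].sum()) - old[affected].sum())
        if delta >= 0 or math.log(self.rng.random()) < delta:
            self.accepted["inbreeding"] += 1
            self.F[s] = prop
            self.ll3[:, col, :] = new
            self.lls[:, col] += (new - old).sum(axis=1)

    def _loglik_locus_pure(self, j: int, s: int, f_s: float) -> np.ndarray:
        a1, a2 = self.g1[:, j], self.g2[:, j]
        typed = a1 >= 0
        hom = typed & (a1 == a2)
        het = typed & ~hom
        ps_a = self.p[s, j, np.where(typed, a1, 0)]
        ps_b = self.p[s, j, np.where(typed, a2, 0)]
        pure = np.zeros(self.N)
        pure[hom] = f_s * ps_a[hom] + (1 - f_s) * ps_a[hom] ** 2
        pure[het] = (1 - f_s) * 2 * ps_a[het] * ps_b[het]
        with np.errstate(divide="ignore"):
            return np.where(typed, np.log(np.maximum(pure, 1e-300)), 0.0)

    def step(self):
        u = self.rng.random()
        if u < _MOVE_WEIGHTS[0]:
            self.move_ancestry()
        elif u < _MOVE_WEIGHTS[0] + _MOVE_WEIGHTS[1]:
            self.move_migration()
        elif u < 1.0 - _MOVE_WEIGHTS[3]:
            self.move_frequency()
        else:
            self.move_inbreeding()


def _run_chain(ds: GenotypeDataset, n_gen: int, burn_in: int, thin: int,
               mixing: float, seed, use_likelihood: bool) -> tuple[pd.DataFrame, dict]:
    rng = np.random.default_rng(seed)
    st = _SamplerState(ds, rng, mixing, use_likelihood)
    P = st.P
    records = []
    for gen in range(1, n_gen + 1):
        st.step()
        if gen % thin == 0:
            row = {"state": gen, "loglik": st.total_loglik()}
            for l in range(P):
                for q in range(P):
                    row[f"m[{st.pop_ids[l]}][{st.pop_ids[q]}]"] = st.m[l, q]
            for l in range(P):
                row[f"F[{st.pop_ids[l]}]"] = st.F[l]
            records.append(row)
    trace = pd.DataFrame.from_records(records)
    rates = {
        k: (st.accepted[k] / st.proposed[k] if st.proposed[k] else float("nan"))
        for k in _MOVE_NAMES
    }
    for k, r in rates.items():
        if not math.isnan(r) and (r < 0.01 or r > 0.99):
            logger.warning("move %r acceptance rate %.3f outside (1%%, 99%%)", k, r)
    return trace, rates


def run_migration_mcmc(
    ds: GenotypeDataset,
    n_gen: int = 200_000,
    burn_in: int = 20_000,
    mixing: float = 0.8,
    seed: int | None = None,
    n_chains: int = 4,
    thin: int = 50,
    use_likelihood: bool = True,
) -> MigrationPosterior:
    """Posterior mean/SD matrix of recent migration fractions.

    Runs ``n_chains`` independent chains and pools their post-burn-in
    thinned samples.  ``use_likelihood=False`` runs prior-only chains (a
    validation mode: the sampler must then reproduce the uniform prior on
    the constrained support).

    The field-scale preset of 10 million generations with 1 million
    burn-in is available as ``n_gen=10_000_000, burn_in=1_000_000``; the
    default is a desk-scale run.
    """
    if burn_in >= n_gen:
        raise ValueError("burn_in must be smaller than n_gen")
    pop_ids = ds.population_ids
    P = len(pop_ids)
    if P == 1:
        one = np.ones((1, 1))
        trace = pd.DataFrame({"state": [n_gen], "loglik": [0.0],
                              f"m[{pop_ids[0]}][{pop_ids[0]}]": [1.0]})
        return MigrationPosterior(pop_ids, one, np.zeros((1, 1)),
                                  np.full(1, np.nan), np.full(1, np.nan),
                                  [trace], {}, n_gen, burn_in, thin)
    root = np.random.SeedSequence(seed)
    traces = []
    rates_all: dict[str, list[float]] = {k: [] for k in _MOVE_NAMES}
    for child in root.spawn(n_chains):
        trace, rates = _run_chain(ds, n_gen, burn_in, thin, mixing, child,
                                  use_likelihood)
        traces.append(trace)
        for k, r in rates.items():
            rates_all[k].append(r)
    post = pd.concat([t[t["state"] > burn_in] for t in traces], ignore_index=True)
    mean = np.zeros((P, P))
    sd = np.zeros((P, P))
    for l in range(P):
        for q in range(P):
            col = post[f"m[{pop_ids[l]}][{pop_ids[q]}]"]
            mean[l, q] = col.mean()
            sd[l, q] = col.std(ddof=1)
    f_mean = np.array([post[f"F[{p}]"].mean() for p in pop_ids])
    f_sd = np.array([post[f"F[{p}]"].std(ddof=1) for p in pop_ids])
    acceptance = {k: float(np.nanmean(v)) for k, v in rates_all.items()}
    return MigrationPosterior(pop_ids, mean, sd, f_mean, f_sd, traces,
                              acceptance, n_gen, burn_in, thin)


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1:] / (np.arange(n, 0, -1) * x.var())
    s = 0.0
    for k in range(1, n):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


def convergence_report(post: MigrationPosterior) -> pd.DataFrame:
    """Across-chain diagnostics per parameter.

    Columns: mean, sd, min ESS across chains, and the pooled/within
    variance ratio (a potential-scale-reduction analogue); parameters with
    ratio above 1.1 are flagged.
    """
    if len(post.traces) < 2:
        raise ValueError("convergence diagnostics need >= 2 chains")
    params = [c for c in post.traces[0].columns if c not in ("state", "loglik")]
    rows = []
    for name in params:
        chains = [t.loc[t["state"] > post.burn_in, name].to_numpy()
                  for t in post.traces]
        n = min(len(c) for c in chains)
        chains = [c[:n] for c in chains]
        means = np.array([c.mean() for c in chains])
        variances = np.array([c.var(ddof=1) for c in chains])
        w = variances.mean()
        b = n * means.var(ddof=1) if len(chains) > 1 else 0.0
        var_hat = (n - 1) / n * w + b / n
        # floored at 1: identical chains report exactly unit ratio
        ratio = math.sqrt(max(var_hat / w, 1.0)) if w > 0 else 1.0
        ess = min(effective_sample_size(c) for c in chains)
        rows.append({
            "parameter": name,
            "mean": float(np.concatenate(chains).mean()),
            "sd": float(np.concatenate(chains).std(ddof=1)),
            "min_ess": ess,
            "psrf": ratio,
            "flagged": ratio > 1.1,
        })
    return pd.DataFrame(rows).set_index("parameter")


def write_traces(post: MigrationPosterior, directory) -> list[str]:
    """Dump each chain as a tab-separated trace file readable by viewers."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, trace in enumerate(post.traces, start=1):
        path = directory / f"migration_chain{k}.tsv"
        trace.to_csv(path, sep="\t", index=False)
        paths.append(str(path))
    return paths
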