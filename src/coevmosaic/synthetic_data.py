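"""Paired two-species microsatellite dataset simulator.

Generates host and parasitoid genotype datasets with the structure the
downstream analyses assume: island-model divergence around shared ancestral
allele frequencies, within-population inbreeding, null alleles, genotyping
failure, aphid-style clonal duplication, planted recent migrants, and
optional "hotspot" loci with inflated divergence at designated locations.
Every latent quantity is recorded in a :class:`TruthRecord` so parameter
recovery can be tested.

Model sketch, per species:

* each locus gets an allele-size ladder (base length + 2 bp steps) and
  ancestral frequencies drawn from a symmetric Dirichlet;
* population frequencies follow a drift kernel
  ``p_pop ~ Dirichlet(p_anc * (1 - c) / c)``, whose expected Weir F_ST is
  exactly ``c`` (the Dirichlet/beta identity E[F] = 1 / (1 + alpha_total)
  with alpha_total = (1 - c) / c), so ``theta_divergence`` is calibrated by
  construction;
* genotypes are drawn with inbreeding coefficient F:
  P(hom a) = F p_a + (1 - F) p_a^2, P(het ab) = (1 - F) 2 p_a p_b;
* a null allele of frequency ``null_rate`` joins the ladder invisibly:
  null/visible heterozygotes are recorded as visible homozygotes and
  null/null as missing; independent genotyping failure adds genuine
  missingness;
* recent migrants are planted per a truth matrix: a first-generation
  migrant's genotype is redrawn from the source population, a
  second-generation migrant receives one gamete from each population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_model import MISSING, GenotypeDataset, PopulationSample


class SimConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Generative settings for one species' dataset.

    ``theta_divergence`` is the target expected Weir F_ST among
    populations; ``selfing_F`` the within-population inbreeding
    coefficient; ``null_rate`` the per-locus null-allele frequency;
    ``clone_rate`` the probability that an individual duplicates an
    earlier genotype (aphid cyclical parthenogenesis; 0 for the
    parasitoid).  ``hotspot_loci`` are redrawn at ``hotspot_populations``
    with divergence ``hotspot_theta``.  Only diploid females are emitted.
    """

    species_label: str = "species"
    population_labels: Sequence[str] = ("pop1", "pop2", "pop3", "pop4", "pop5")
    n_individuals_per_pop: int | Sequence[int] = 10
    n_loci: int = 12
    n_alleles_per_locus: int = 4
    dirichlet_alpha: float = 0.3       # ancestral frequency skew
    theta_divergence: float = 0.05
    selfing_F: float | Sequence[float] = 0.0
    null_rate: float | Sequence[float] = 0.0
    missing_rate: float = 0.0          # genuine genotyping failure per call
    clone_rate: float = 0.0
    hotspot_loci: frozenset[int] = frozenset()
    hotspot_populations: frozenset[str] = frozenset()
    hotspot_theta: float = 0.8
    migration_truth: np.ndarray | None = None  # row-stochastic, diag >= 2/3
    migrant_exact_counts: bool = False  # plant exactly round(n*m) migrants
    migrant_gen2_fraction: float = 0.0
    locus_prefix: str = "MSAT"
    seed: int | None = None

    @property
    def n_populations(self) -> int:
        return len(self.population_labels)

    def pop_sizes(self) -> list[int]:
        if isinstance(self.n_individuals_per_pop, int):
            return [self.n_individuals_per_pop] * self.n_populations
        sizes = list(self.n_individuals_per_pop)
        if len(sizes) != self.n_populations:
            raise SimConfigError("per-pop sizes do not match population labels")
        return sizes

    def selfing(self) -> np.ndarray:
        f = self.selfing_F
        arr = np.full(self.n_populations, f) if np.isscalar(f) else np.asarray(f, float)
        if len(arr) != self.n_populations or ((arr < 0) | (arr >= 1)).any():
            raise SimConfigError("selfing_F must be per-pop values in [0, 1)")
        return arr

    def nulls(self) -> np.ndarray:
        r = self.null_rate
        arr = np.full(self.n_loci, r) if np.isscalar(r) else np.asarray(r, float)
        if len(arr) != self.n_loci or ((arr < 0) | (arr > 0.5)).any():
            raise SimConfigError("null_rate must be per-locus values in [0, 0.5]")
        return arr

    def validate(self) -> None:
        if self.n_populations < 1 or self.n_loci < 1:
            raise SimConfigError("need at least one population and one locus")
        if len(set(self.population_labels)) != self.n_populations:
            raise SimConfigError("population labels must be unique")
        if not 0 <= self.theta_divergence < 1:
            raise SimConfigError("theta_divergence must be in [0, 1)")
        if not 0 < self.hotspot_theta < 1:
            raise SimConfigError("hotspot_theta must be in (0, 1)")
        if not 0 <= self.clone_rate < 1:
            raise SimConfigError("clone_rate must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise SimConfigError("missing_rate must be in [0, 1)")
        if self.n_alleles_per_locus < 2 and self.nulls().max(initial=0) > 0:
            raise SimConfigError("null alleles need >= 2 visible alleles")
        self.selfing()
        unknown = self.hotspot_populations - set(self.population_labels)
        if unknown:
            raise SimConfigError(f"unknown hotspot populations {sorted(unknown)}")
        if any(j < 0 or j >= self.n_loci for j in self.hotspot_loci):
            raise SimConfigError("hotspot locus index out of range")
        m = self.migration_truth
        if m is not None:
            m = np.asarray(m, float)
            k = self.n_populations
            if m.shape != (k, k):
                raise SimConfigError("migration_truth shape mismatch")
            if not np.allclose(m.sum(axis=1), 1.0):
                raise SimConfigError("migration_truth rows must sum to 1")
            off = m.sum(axis=1) - np.diag(m)
            if (off > 1 / 3 + 1e-9).any():
                raise SimConfigError(
                    "off-diagonal migration row sums must not exceed 1/3"
                )


@dataclass
class SpeciesTruth:
    """Latent state of one simulated species."""

    config: SimConfig
    allele_sizes: list[np.ndarray]          # per locus, visible ladder
    ancestral_freqs: list[np.ndarray]       # per locus
    population_freqs: dict[tuple[str, int], np.ndarray]  # (pop, locus) visible
    migrants: list[tuple[str, str, str, int]] = field(default_factory=list)
    """(population, individual, source population, generation 1|2)."""
    clones: list[tuple[str, str, str]] = field(default_factory=list)
    """(population, clone individual, template individual)."""


@dataclass
class TruthRecord:
    """Latent quantities of a simulated species pair."""

    host: SpeciesTruth
    parasitoid: SpeciesTruth

    def planted_hot_locations(self) -> set[str]:
        """Locations where both species carry hotspot loci."""
        return set(self.host.config.hotspot_populations) & set(
            self.parasitoid.config.hotspot_populations
        )


def _drift_freqs(p_anc: np.ndarray, theta: float,
                 rng: np.random.Generator) -> np.ndarray:
    if theta <= 0:
        return p_anc.copy()
    alpha = np.clip(p_anc, 1e-6, None)
    alpha = alpha / alpha.sum() * (1.0 - theta) / theta
    return rng.dirichlet(alpha)


def _draw_genotype(freqs: np.ndarray, f_inbreed: float,
                   rng: np.random.Generator) -> tuple[int, int]:
    """Allele-index pair under inbreeding F (indices into the full ladder)."""
    if f_inbreed > 0 and rng.random() < f_inbreed:
        a = rng.choice(len(freqs), p=freqs)
        return int(a), int(a)
    a, b = rng.choice(len(freqs), size=2, p=freqs)
    return int(a), int(b)


def simulate_species(cfg: SimConfig,
                     rng: np.random.Generator | None = None) -> tuple[GenotypeDataset, SpeciesTruth]:
    """Simulate one species' dataset; see the module docstring for the model."""
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    k_vis = cfg.n_alleles_per_locus
    nulls = cfg.nulls()
    selfing = cfg.selfing()
    sizes = cfg.pop_sizes()
    labels = list(cfg.population_labels)

    allele_sizes, anc_freqs = [], []
    for j in range(cfg.n_loci):
        base = int(rng.integers(100, 900 - 2 * k_vis))
        allele_sizes.append(base + 2 * np.arange(k_vis, dtype=np.int64))
        anc_freqs.append(rng.dirichlet(np.full(k_vis, cfg.dirichlet_alpha)))

    # full ladders append the null allele as a final, unobservable class
    pop_freqs_full: dict[tuple[str, int], np.ndarray] = {}
    truth_freqs: dict[tuple[str, int], np.ndarray] = {}
    for pid in labels:
        for j in range(cfg.n_loci):
            vis = _drift_freqs(anc_freqs[j], cfg.theta_divergence, rng)
            if j in cfg.hotspot_loci and pid in cfg.hotspot_populations:
                # local selection modelled as a partial sweep of the
                # ancestrally rarest allele, with intensity hotspot_theta;
                # unlike a high-variance drift redraw this guarantees the
                # designated population actually diverges at the locus
                sweep = np.zeros_like(vis)
                sweep[int(np.argmin(anc_freqs[j]))] = 1.0
                vis = (1 - cfg.hotspot_theta) * vis + cfg.hotspot_theta * sweep
            truth_freqs[(pid, j)] = vis
            pop_freqs_full[(pid, j)] = np.append(vis * (1 - nulls[j]), nulls[j])

    truth = SpeciesTruth(cfg, allele_sizes, anc_freqs, truth_freqs)

    m = cfg.migration_truth
    m = np.asarray(m, float) if m is not None else np.eye(cfg.n_populations)

    pops = []
    for pi, pid in enumerate(labels):
        n = sizes[pi]
        ids = [f"{pid}-{i + 1}" for i in range(n)]
        # ancestry assignment: stochastic per individual, or exact counts
        # (round(n * m) migrants per source) when migrant_exact_counts is set
        sources = np.full(n, pi)
        if cfg.migrant_exact_counts:
            order = rng.permutation(n)
            pos = 0
            for qi in range(cfg.n_populations):
                if qi == pi:
                    continue
                k = int(round(n * m[pi, qi]))
                sources[order[pos:pos + k]] = qi
                pos += k
        else:
            u = rng.random(n)
            acc = 0.0
            for qi in range(cfg.n_populations):
                if qi == pi:
                    continue
                sources[(u >= acc) & (u < acc + m[pi, qi])] = qi
                acc += m[pi, qi]
        # true genotypes as ladder indices (k_vis is the null index)
        geno_idx = np.empty((n, cfg.n_loci, 2), dtype=np.int64)
        for i in range(n):
            if i > 0 and cfg.clone_rate > 0 and rng.random() < cfg.clone_rate:
                # clonal duplication takes precedence over migrant planting
                template = int(rng.integers(0, i))
                geno_idx[i] = geno_idx[template]
                truth.clones.append((pid, ids[i], ids[template]))
                continue
            source, gen = int(sources[i]), 0
            if source != pi:
                gen = 2 if rng.random() < cfg.migrant_gen2_fraction else 1
                truth.migrants.append((pid, ids[i], labels[source], gen))
            for j in range(cfg.n_loci):
                if gen == 2:  # one gamete from each population, no inbreeding
                    fs = pop_freqs_full[(labels[source], j)]
                    fh = pop_freqs_full[(pid, j)]
                    a = int(rng.choice(len(fs), p=fs))
                    b = int(rng.choice(len(fh), p=fh))
                    geno_idx[i, j] = (a, b)
                else:
                    src = labels[source]
                    geno_idx[i, j] = _draw_genotype(
                        pop_freqs_full[(src, j)], selfing[source], rng
                    )

        # score genotypes: nulls mask, genotyping failure erases
        scored = np.zeros_like(geno_idx)
        for j in range(cfg.n_loci):
            ladder = allele_sizes[j]
            for i in range(n):
                a, b = geno_idx[i, j]
                null_a, null_b = a == k_vis, b == k_vis
                if (null_a and null_b) or (
                    cfg.missing_rate > 0 and rng.random() < cfg.missing_rate
                ):
                    scored[i, j] = (MISSING, MISSING)
                elif null_a:
                    scored[i, j] = (ladder[b], ladder[b])
                elif null_b:
                    scored[i, j] = (ladder[a], ladder[a])
                else:
                    scored[i, j] = (ladder[a], ladder[b])
        pops.append(PopulationSample(pid, ids, scored))

    locus_names = [f"{cfg.locus_prefix}{j + 1}" for j in range(cfg.n_loci)]
    ds = GenotypeDataset(cfg.species_label, locus_names, pops)
    return ds, truth


def simulate_pair(cfg_host: SimConfig, cfg_parasitoid: SimConfig,
                  seed: int | None = None) -> tuple[GenotypeDataset, GenotypeDataset, TruthRecord]:
    """Simulate co-sampled host and parasitoid datasets.

    The two configs must share their co-sampled location labels (each may
    add species-specific reference locations).  A shared seed argument
    overrides the per-config seeds and splits the stream between species.
    """
    shared = set(cfg_host.population_labels) & set(cfg_parasitoid.population_labels)
    if not shared:
        raise SimConfigError("configs share no co-sampled population labels")
    if seed is not None:
        root = np.random.SeedSequence(seed)
        s_host, s_para = root.spawn(2)
        rng_h = np.random.default_rng(s_host)
        rng_p = np.random.default_rng(s_para)
    else:
        rng_h = np.random.default_rng(cfg_host.seed)
        rng_p = np.random.default_rng(cfg_parasitoid.seed)
    ds_h, truth_h = simulate_species(cfg_host, rng_h)
    ds_p, truth_p = simulate_species(cfg_parasitoid, rng_p)
    return ds_h, ds_p, TruthRecord(truth_h, truth_p)


def truth_report(t: TruthRecord) -> pd.DataFrame:
    """Long-format table of every latent parameter of a simulated pair."""
    rows = []
    for role, sp in (("host", t.host), ("parasitoid", t.parasitoid)):
        cfg = sp.config
        rows.append((role, "config", "theta_divergence", "", "", cfg.theta_divergence))
        for pi, pid in enumerate(cfg.population_labels):
            rows.append((role, "selfing_F", pid, "", "", cfg.selfing()[pi]))
        for j, nr in enumerate(cfg.nulls()):
            rows.append((role, "null_rate", "", f"locus{j + 1}", "", nr))
        for j in sorted(cfg.hotspot_loci):
            for pid in sorted(cfg.hotspot_populations):
                rows.append((role, "hotspot", pid, f"locus{j + 1}", "",
                             cfg.hotspot_theta))
        for (pid, j), freqs in sp.population_freqs.items():
            for a, f in zip(sp.allele_sizes[j], freqs):
                rows.append((role, "pop_freq", pid, f"locus{j + 1}", str(a), f))
        for pid, ind, src, gen in sp.migrants:
            rows.append((role, "migrant", pid, ind, src, gen))
        for pid, ind, template in sp.clones:
            rows.append((role, "clone", pid, ind, template, 1.0))
    return pd.DataFrame(
        rows, columns=["species_role", "kind", "population", "locus", "detail", "value"]
    )


# ---------------------------------------------------------------------------
# Study-shaped presets: a five-location host-parasitoid survey with one
# species-specific reference location each, parasitoid more heterozygous
# (H_o around 0.28) than the clonal, more structured aphid host (H_o
# around 0.15).
# ---------------------------------------------------------------------------

CO_SAMPLED = ("Arbuckle", "UpperLake", "Escalon", "Newark")


def parasitoid_config(**overrides) -> SimConfig:
    cfg = SimConfig(
        species_label="parasitoid",
        population_labels=("YubaCity",) + CO_SAMPLED,
        n_individuals_per_pop=(7, 14, 13, 12, 10),
        n_loci=15,
        n_alleles_per_locus=4,
        dirichlet_alpha=0.25,
        theta_divergence=0.03,
        selfing_F=0.24,
        null_rate=0.05,
        missing_rate=0.02,
        clone_rate=0.0,
        locus_prefix="Tp_MSAT",
        seed=0,
    )
    return replace(cfg, **overrides)


def aphid_config(**overrides) -> SimConfig:
    cfg = SimConfig(
        species_label="aphid",
        population_labels=("Linden",) + CO_SAMPLED,
        n_individuals_per_pop=(7, 12, 9, 9, 12),
        n_loci=12,
        n_alleles_per_locus=3,
        dirichlet_alpha=0.15,
        theta_divergence=0.12,
        selfing_F=0.13,
        null_rate=0.05,
        missing_rate=0.02,
        clone_rate=0.1,
        locus_prefix="Cj_MSAT",
        seed=1,
    )
    return replace(cfg, **overrides)
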