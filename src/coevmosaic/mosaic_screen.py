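"""Geographic-mosaic screen: locus-specific divergence against reference
cold spots, Tukey-fence outlier loci, and reciprocal hot/cold-spot calls.

The screen follows the comparative logic for two interacting species
surveyed at shared locations: each species has one reference location
where its counterpart is absent (a known coevolutionary cold spot).  For
every other location, per-locus null-corrected F_ST (and Rho_ST) against
the reference is computed, and loci falling outside the Tukey boxplot
whiskers (quartile hinges +/- 1.5 IQR) are flagged as outliers.  A
co-sampled location where BOTH species show at least one outlier locus is
a candidate coevolutionary hot spot; otherwise it is a candidate cold
spot.  Reference locations are never classified as candidates.

An optional permutation test attaches a per-locus significance level to
each outlier by shuffling individuals between the two populations of a
comparison; it is a permutation-based substitute for a Bayesian
locus-selection scan and its p-values are labelled as such.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import DiversitySummary
from .genotype_model import GenotypeDataset, PopulationSample
from .null_fst import (AlleleFrequencyTable, estimate_null_freq, fst_components,
                       fst_from_components, fst_ena, rho_st)

logger = logging.getLogger(__name__)

HOT = "candidate_hot_spot"
COLD = "candidate_cold_spot"
REFERENCE = "reference_cold_spot"


# ---------------------------------------------------------------------------
# Tukey fences
# ---------------------------------------------------------------------------

def tukey_hinges(values: np.ndarray) -> tuple[float, float, float]:
    """(lower hinge, median, upper hinge), the five-number-summary way."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("no values")
    d = (math.floor((n + 3) / 2)) / 2  # 1-based hinge position
    lo = 0.5 * (x[math.floor(d) - 1] + x[math.ceil(d) - 1])
    hi = 0.5 * (x[n - math.floor(d)] + x[n - math.ceil(d)])
    return lo, float(np.median(x)), hi


@dataclass
class FenceResult:
    lower_fence: float
    upper_fence: float
    low_outliers: list[str]
    high_outliers: list[str]

    @property
    def outliers(self) -> set[str]:
        return set(self.low_outliers) | set(self.high_outliers)


def tukey_fence_outliers(values: pd.Series, k: float = 1.5,
                         hinge_method: str = "tukey") -> FenceResult:
    """Outliers beyond quartiles +/- k * IQR, both tails labelled.

    ``values`` is indexed by locus name; NaNs are dropped first.  The
    default quartile convention is Tukey hinges (boxplot whiskers); set
    ``hinge_method='linear'`` for interpolated quantiles.  Fewer than 4
    usable values yields no fences and an empty outlier set (warned).
    """
    clean = values.dropna()
    if len(clean) < 4:
        logger.warning("only %d values; no fences computed", len(clean))
        return FenceResult(float("nan"), float("nan"), [], [])
    if hinge_method == "tukey":
        q1, _, q3 = tukey_hinges(clean.to_numpy())
    elif hinge_method == "linear":
        q1, q3 = np.quantile(clean.to_numpy(), [0.25, 0.75])
    else:
        raise ValueError(f"unknown hinge_method {hinge_method!r}")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    low = sorted(clean.index[clean < lo])
    high = sorted(clean.index[clean > hi])
    return FenceResult(float(lo), float(hi), list(low), list(high))


# ---------------------------------------------------------------------------
# Locus-specific divergence against the reference cold spot
# ---------------------------------------------------------------------------

@dataclass
class SpeciesScreenReport:
    """One species' per-location locus divergence and outlier calls."""

    species_label: str
    reference_pop: str
    fst: pd.DataFrame            # loci x locations, ENA-corrected F_ST
    rho: pd.DataFrame            # loci x locations, Rho_ST (uncorrected)
    fences: dict[str, FenceResult] = field(default_factory=dict)
    metric: str = "fst"          # which table drives the outlier calls

    @property
    def locations(self) -> list[str]:
        return list(self.fst.columns)

    def outliers(self, location: str) -> set[str]:
        return self.fences[location].outliers


def locus_specific_divergence(
    ds: GenotypeDataset, reference_pop: str,
    freqs: AlleleFrequencyTable | None = None,
    hinge_method: str = "tukey",
) -> SpeciesScreenReport:
    """Per-locus F_ST/Rho_ST of every location vs the reference cold spot.

    Loci untyped in either member of a comparison are missing for that
    location and excluded from its fences.  Outlier loci (both tails) are
    flagged per location from the F_ST table.
    """
    if reference_pop not in ds.population_ids:
        raise ValueError(f"reference population {reference_pop!r} not in dataset")
    if freqs is None:
        freqs = estimate_null_freq(ds)
    others = [p for p in ds.population_ids if p != reference_pop]
    pairs = [(reference_pop, o) for o in others]
    diff = fst_ena(ds, freqs, pairs=pairs)
    rho = rho_st(ds, pairs=pairs)
    fst_table = pd.DataFrame(
        {o: diff.fst_per_locus[(reference_pop, o)] for o in others},
        index=ds.locus_names,
    )
    rho_table = pd.DataFrame(
        {o: rho.rho_per_locus[(reference_pop, o)] for o in others},
        index=ds.locus_names,
    )
    report = SpeciesScreenReport(ds.species_label, reference_pop,
                                 fst_table, rho_table)
    for o in others:
        report.fences[o] = tukey_fence_outliers(
            fst_table[o], hinge_method=hinge_method
        )
    return report


# ---------------------------------------------------------------------------
# Reciprocal classification
# ---------------------------------------------------------------------------

@dataclass
class MosaicReport:
    """Hot/cold-spot classification with the per-species evidence."""

    host: SpeciesScreenReport
    parasitoid: SpeciesScreenReport
    classification: pd.DataFrame  # index location; columns classification etc.

    @property
    def hot_spots(self) -> list[str]:
        c = self.classification
        return sorted(c.index[c["classification"] == HOT])

    @property
    def cold_spots(self) -> list[str]:
        c = self.classification
        return sorted(c.index[c["classification"].isin([COLD, REFERENCE])])


def classify_locations(host_report: SpeciesScreenReport,
                       parasitoid_report: SpeciesScreenReport,
                       co_sampled: list[str] | None = None) -> MosaicReport:
    """Reciprocal outlier classification of co-sampled locations.

    Symmetric in which species is passed first.  Locations typed for only
    one species (and not a reference) are excluded with a warning.
    """
    if co_sampled is None:
        co_sampled = sorted(
            set(host_report.locations) & set(parasitoid_report.locations)
        )
    rows = []
    for loc in co_sampled:
        if loc not in host_report.fences or loc not in parasitoid_report.fences:
            logger.warning("location %r missing from one species' screen; "
                           "excluded", loc)
            continue
        h_out = host_report.outliers(loc)
        p_out = parasitoid_report.outliers(loc)
        rows.append({
            "location": loc,
            "classification": HOT if (h_out and p_out) else COLD,
            "host_outliers": ",".join(sorted(h_out)),
            "parasitoid_outliers": ",".join(sorted(p_out)),
        })
    for report, who in ((host_report, "host"), (parasitoid_report, "parasitoid")):
        rows.append({
            "location": report.reference_pop,
            "classification": REFERENCE,
            "host_outliers": "",
            "parasitoid_outliers": "",
        })
    seen = set()
    uniq = []
    for r in rows:
        if r["location"] not in seen:
            seen.add(r["location"])
            uniq.append(r)
    table = pd.DataFrame(uniq).set_index("location")
    return MosaicReport(host_report, parasitoid_report, table)


# ---------------------------------------------------------------------------
# Permutation significance of an outlier locus
# ---------------------------------------------------------------------------

def _locus_fst_two_pops(ds: GenotypeDataset, locus_j: int) -> float:
    comps = fst_components(ds, ds.population_ids, None)
    a, b, c = comps[locus_j]
    tot = a + b + c
    return float(a / tot) if tot else float("nan")


def outlier_permutation_test(ds: GenotypeDataset, reference_pop: str,
                             candidate_pop: str, locus: str,
                             n_perm: int = 1_000,
                             seed: int | None = None) -> float:
    """Permutation p-value for one locus' divergence between two locations.

    Individuals are shuffled between the two populations (sizes kept) and
    the uncorrected Weir-Cockerham locus F_ST recomputed each time;
    p = (1 + #{perm >= observed}) / (1 + n_perm).  This is a permutation
    substitute for a model-based selection scan, not an equivalent of one.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    sub = ds.subset([reference_pop, candidate_pop])
    j = sub.locus_index(locus)
    obs = _locus_fst_two_pops(sub, j)
    if math.isnan(obs):
        raise ValueError(f"locus {locus!r} uninformative in this pair")
    rng = np.random.default_rng(seed)
    g_all = np.concatenate([p.genotypes for p in sub.populations], axis=0)
    n1 = sub.populations[0].n_individuals
    n = g_all.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        shuffled = _two_pop_dataset(sub, g_all[perm], n1)
        if _locus_fst_two_pops(shuffled, j) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def enumerate_label_assignments(ds: GenotypeDataset, reference_pop: str,
                                candidate_pop: str, locus: str) -> float:
    """Exact permutation p-value by exhausting all population labelings.

    Feasible only for very small samples; provided as the exact
    counterpart of :func:`outlier_permutation_test`.
    """
    sub = ds.subset([reference_pop, candidate_pop])
    j = sub.locus_index(locus)
    obs = _locus_fst_two_pops(sub, j)
    g_all = np.concatenate([p.genotypes for p in sub.populations], axis=0)
    n1 = sub.populations[0].n_individuals
    n = g_all.shape[0]
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        order = list(combo) + [i for i in range(n) if i not in combo]
        shuffled = _two_pop_dataset(sub, g_all[order], n1)
        total += 1
        if _locus_fst_two_pops(shuffled, j) >= obs - 1e-12:
            hits += 1
    return hits / total


def _two_pop_dataset(template: GenotypeDataset, genotypes: np.ndarray,
                     n1: int) -> GenotypeDataset:
    p1, p2 = template.populations
    pops = [
        PopulationSample(p1.id, [f"x{i}" for i in range(n1)], genotypes[:n1]),
        PopulationSample(p2.id, [f"y{i}" for i in range(len(genotypes) - n1)],
                         genotypes[n1:]),
    ]
    return GenotypeDataset(template.species_label, list(template.locus_names), pops)


# ---------------------------------------------------------------------------
# Species comparison of inbreeding coefficients
# ---------------------------------------------------------------------------

@dataclass
class WelchReport:
    host_mean: float
    host_sd: float
    parasitoid_mean: float
    parasitoid_sd: float
    t: float
    df: float
    p_value: float


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch unequal-variance t, Welch-Satterthwaite df, two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        return float("nan"), float("nan"), float("nan")
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def compare_species_gis(host_summary: DiversitySummary,
                        parasitoid_summary: DiversitySummary) -> WelchReport:
    """Welch t comparison of per-population G_IS between the two species.

    The statistic is host mean minus parasitoid mean over the per-location
    inbreeding coefficients.
    """
    a = host_summary.gis.dropna().to_numpy()
    b = parasitoid_summary.gis.dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 populations per species")
    t, df, p = welch_t(a, b)
    return WelchReport(
        host_mean=float(a.mean()), host_sd=float(a.std(ddof=1)),
        parasitoid_mean=float(b.mean()), parasitoid_sd=float(b.std(ddof=1)),
        t=t, df=df, p_value=p,
    )


# ---------------------------------------------------------------------------
# Figure export
# ---------------------------------------------------------------------------

def plot_divergence_boxplots(report: SpeciesScreenReport, path) -> None:
    """One boxplot panel per location of per-locus F_ST vs the reference."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    locs = report.locations
    fig, axes = plt.subplots(1, len(locs), figsize=(2.2 * len(locs), 4),
                             sharey=True)
    if len(locs) == 1:
        axes = [axes]
    for ax, loc in zip(axes, locs):
        vals = report.fst[loc].dropna()
        ax.boxplot(vals.to_numpy(), whis=1.5)
        out = report.fences[loc].outliers
        for locus in out:
            ax.annotate(locus, (1.05, report.fst.loc[locus, loc]), fontsize=7)
        ax.set_title(loc, fontsize=9)
        ax.set_xticks([])
    axes[0].set_ylabel(f"locus $F_{{ST}}$ vs {report.reference_pop}")
    fig.suptitle(report.species_label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
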