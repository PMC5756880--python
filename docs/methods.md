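# Methods

This note records the statistical models, estimators and numerical choices
behind `coevmosaic`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model

Genotypes are diploid, co-dominant allele-size calls on a microsatellite
ladder; allele codes are positive integers (fragment lengths or repeat
counts — only identity matters for F_ST, numeric size for Rho_ST).  A
genotype is missing only when both alleles carry the reserved code 0;
half-missing calls are rejected at parse time because co-dominant scoring
yields both alleles or neither.  Clone deduplication (identical complete
multilocus genotypes within a population, missing treated as a distinct
state) is available but off by default: the sampling designs this pipeline
targets limit clonality in the field, and silent filtering would change
sample sizes without a trace, so every removal is logged.

## Diversity statistics

Per locus with n typed individuals, observed heterozygosity H_o is the
heterozygote fraction and the within-population gene diversity uses the
small-sample correction

    H_s = (n / (n - 1)) (1 - sum_i p_i^2 - H_o / (2n)).

The multilocus inbreeding coefficient is G_IS = 1 - (sum_l H_o,l) /
(sum_l H_s,l) — components summed across loci before the ratio.  The
ratio-of-rounded-means alternative differs in the third decimal on real
data (a negative G_IS near zero can shift by 0.003), which is why the
summed convention is the only one offered.

For pooled (multi-population) statistics the correction sample size is the
harmonic mean of per-population typed counts ñ, and total diversity per
locus over s populations is

    H_t = 1 - sum_i (mean_p p_ip)^2 + H_s / (ñ s) - H_o / (2 ñ s).

When a table reports one population per row, H_t is computed over that
single population and equals H_s by construction; the pooled H_t is
reported separately.  Report tables round to 3 decimals; machine-readable
outputs keep full precision.

## Exact tests

**HWE.** The conditional (Levene) distribution of a genotype table given
its allele counts is P(table) = n! 2^H prod_a n_a! / ((2n)! prod n_ab!).
The probability test sums P over all tables no more probable than the
observed one.  Tables are fully enumerated when the recursion stays under
`enumeration_limit` (default 200,000 tables); otherwise a Markov chain is
run over ordered allele-copy assignments to individuals.  Because the
uniform distribution on those arrangements induces exactly the Levene
distribution on tables, the chain is a plain random transposition of two
allele copies, always accepted — no Metropolis ratio.  The chain runs
`dememorization` steps (default 10,000) then `batches` × 
`iterations_per_batch` (20 × 5,000); the batch means give the Monte-Carlo
SE.  The test flavour is the probability test, not the heterozygote
excess/deficit U-test.

**LD and genic differentiation.** Both are permutation G tests: for LD the
two-locus genotype contingency table within a population, with one locus's
genotypes permuted among individuals; for the genic test the 2 × alleles
count table of a population pair, with allele copies permuted between the
populations.  p = (1 + #{G_perm ≥ G_obs}) / (1 + n_perm), a valid
(conservative) p-value.  Default n_perm = 2,000.

**Combination.** Fisher's method across loci or populations:
X² = −2 Σ ln p on 2k df, k counting only strata that actually yielded a
test.  A Monte-Carlo p of exactly zero propagates as X² = ∞ with the
combined p reported as below the chain resolution 1/N.

**Multiplicity.** Bonferroni: α/number of tests (105 locus pairs for 15
loci, 66 for 12; 10 population pairs for 5 locations → 0.005).

## Null alleles and differentiation

**EM.** Per population × locus, the model has visible allele frequencies
p_a, a null-allele frequency p_0, and a genotyping-failure rate β.  Under
HW, an observed homozygote a is a true homozygote (p_a²) or a masked
null heterozygote (2 p_a p_0); an observed blank is a null homozygote
((1−β)p_0²) or a genuine failure (β).  The E-step apportions the observed
counts accordingly; the M-step re-estimates (p, p_0, β) from expected
allele copies.  Iteration stops when the L∞ change is below 1e−6 (cap
10,000 iterations; non-convergence is flagged and the last iterate
returned).  An all-missing locus drives p_0 to the boundary and is flagged
degenerate.  Estimating β keeps genuine missingness from inflating p_0;
with no missing data β = 0 and the model reduces to the standard
null-allele EM.

**F_ST.** Weir–Cockerham variance components per allele u:
with r populations, sizes n_i (typed individuals only), frequencies p_iu,
heterozygote-carrier frequencies h_iu, the standard a, b, c components are
summed over alleles and loci, and θ = Σa / Σ(a+b+c) (ratio of sums, never
mean of per-locus ratios; per-locus values may be negative and are not
truncated — truncation would bias the outlier screen upward).  The ENA
correction replaces the observed frequencies with the EM's null-adjusted
visible frequencies (which sum to 1 − p_0; the null class itself never
enters the allele sums) while keeping observed heterozygote terms and
typed-only sample sizes.  With every estimated p_0 below 1e−6 the
corrected and uncorrected estimators agree to numerical precision.
Pairwise estimates use the two focal populations only, which is what the
reference-cold-spot screen needs.

**Rho_ST.** One-way ANOVA of allele sizes (population / allele copies):
σ²_a = (MSA − MSW)/n_0 with the unequal-size n_0, Rho = σ²_a/(σ²_a + MSW),
globally a ratio of summed components.  The within-individual level is not
modelled — with the small per-location samples here the two-level ANOVA is
the stabler choice, and the screen's headline metric is F_ST with Rho_ST a
parallel report.  Rho_ST is not null-corrected (no size can be imputed for
an unobserved allele); output metadata says so.

## Recent migration

The model follows the BayesAss family.  Each individual of population l
is a non-migrant, a first-generation migrant from q, or a
second-generation migrant (one parent from q); given m, the prior is
P(non) = 1 − Σ_q m_lq and P(gen-1 from q) = P(gen-2 from q) = m_lq/2, so
m_lq is the fraction of l with recent ancestry in q.  Off-diagonal row
sums are constrained to ≤ 1/3 (non-migrant fraction ≥ 2/3), the
identifiability limit of single-generation genotype data.  Genotype
likelihoods use the source population's frequencies with its inbreeding
coefficient, P(hom a) = F p_a + (1−F) p_a², P(het ab) = (1−F) 2 p_a p_b;
a second-generation migrant multiplies one gamete probability from each
population with no inbreeding term.  Missing genotypes contribute
likelihood 1.  Priors are uniform on the constrained supports.

Moves: (i) Gibbs resampling of one individual's ancestry class (70% of
iterations), (ii) random-walk on one off-diagonal m entry within the
simplex constraint (10%), (iii) mass transfer between two allele
frequencies of one population × locus (15%), (iv) reflected random walk on
one F (5%).  The mixing parameter (default 0.8) scales proposal windows:
half the 1/3-support for an m entry, a quarter of the unit support for a
frequency transfer and for F — full-width windows on the strongly informed
frequency parameters mix poorly.  Alleles unseen in a population keep a
frequency floor of 1e−6.  Move acceptance rates outside (1%, 99%) are
logged as warnings.

The desk-scale default is 4 chains × 200,000 generations with 20,000
burn-in and thinning 50, which resolves the two-deme recovery problems in
the tests in seconds per chain; the field-scale setting of 10 million
generations with 1 million burn-in is a parameter choice away.  Posterior
summaries pool post-burn-in samples across chains; an off-diagonal entry
is "significant" when mean ± 1.96 SD excludes zero.  Convergence
diagnostics: per-parameter pooled/within variance ratio (floored at 1,
flagged above 1.1) and an initial-positive-sequence autocorrelation ESS.

Prior correctness is tested directly: with the likelihood disabled the
sampler reproduces the uniform-on-support moments (mean 1/6, SD 1/√12/3
for an m entry of a two-deme system).

## Mosaic screen

For each species, every candidate location is compared with the species'
reference cold spot (a location where the interacting partner is absent):
the per-locus ENA-corrected F_ST vector of that pair, with loci untyped in
either member excluded.  Outlier loci fall outside Tukey fences, quartile
hinges ± 1.5 IQR, with hinges computed by the five-number-summary
convention — the same rule as boxplot whiskers, which is where such calls
come from in practice; interpolated quantiles are available behind
`hinge_method="linear"`.  Both tails are flagged and labelled.  Fewer than
4 usable loci yields no fences and a warning.

A co-sampled location is a candidate hot spot iff both species have at
least one outlier locus there (any tail); otherwise a candidate cold spot;
reference locations are never candidates.  The classification is symmetric
in the species order.

An optional permutation test attaches significance to an outlier locus by
shuffling individuals between the two populations and recomputing the
locus F_ST (p = (1 + #{≥ obs}) / (1 + n_perm), minimum n_perm 100).  It is
a permutation substitute for a model-based Bayesian selection scan and is
labelled as such wherever it is reported; its p-values are not equivalents
of that scan's.

The between-species inbreeding comparison is the Welch unequal-variance t
on the per-location G_IS vectors with Welch–Satterthwaite df, host minus
parasitoid.

**What the screen's detection rate means.** Tukey fences on 12–15
per-locus F_ST values are liberal: under a pure null (no selection), 30–65%
of (species, location) comparisons show at least one outlier locus,
depending on sample sizes and frequency spectra, so reciprocal chance hot
calls arise at roughly the product of the two species' single-species
rates (the species being independent under the null).  The tests therefore
check two separable properties: a planted reciprocal hotspot is detected
essentially always, and false reciprocal calls occur at the predicted
product rate.  A unique hot-spot call should not be over-read on real
data — which is precisely why the downstream significance assessment
exists.

## Synthetic data

The generator emulates a two-species co-sampling design: shared location
labels plus one species-specific reference location each.  Per locus, an
allele ladder (random base length, 2 bp steps) and ancestral frequencies
from a symmetric Dirichlet(α); per population, frequencies from the drift
kernel Dirichlet(p_anc (1−c)/c), whose expected Weir F_ST equals c exactly
(E[F] = 1/(1 + α_total)), so `theta_divergence` needs no calibration
table.  Genotypes are drawn with inbreeding F (the mixture construction
reproduces the HW-with-F genotype probabilities exactly); a null allele of
frequency `null_rate` joins the ladder invisibly and is masked at scoring;
independent genotyping failure adds genuine missingness; aphid-mode
clonality duplicates an earlier individual's genotype with probability
`clone_rate` (cyclical parthenogenesis within a season); only diploid
females are emitted for both species, matching what gets genotyped.
Planted migrants follow a truth matrix with the same ancestry classes as
the migration model (gen-1: full redraw from the source; gen-2: one gamete
per population); planting is per-individual Bernoulli by default, or
exactly round(n·m) migrants per source with `migrant_exact_counts` — the
exact mode is what the recovery experiments use, since a binomial draw
makes the realized migrant fraction, not the nominal one, the quantity
the posterior can see.  A hotspot locus at a designated population is a partial
selective sweep: its frequency vector is pulled toward the ancestrally
rarest allele with intensity `hotspot_theta` (default 0.8).  A
high-variance drift redraw was rejected as the hotspot mechanism because
its realized divergence is too dispersed to represent a planted selection
signal.

Preset configurations mirror the study conditions: parasitoid — 5
locations of 7–14 females, 15 loci, 4 visible alleles, α = 0.25, c = 0.03,
F = 0.24, 5% nulls, 2% failures, no clones; aphid — 5 locations of 7–12,
12 loci, 3 alleles, α = 0.15, c = 0.12, F = 0.13, 5% nulls, 10% clonality.
The α and F values were derived once from the target heterozygosity levels
(E[H] = 1 − (α+1)/(Kα+1) for a symmetric Dirichlet), giving mean H_o near
0.28 for the wasp and 0.15 for the aphid.

**What passing tests do not show.** The generator draws loci
independently (no linkage), uses a frequency-level drift kernel rather
than genealogies, has no mutation model beyond the static ladder (so
stepwise-mutation homoplasy is absent and Rho_ST's advantage over F_ST on
real microsatellites is not represented), and plants migrants and sweeps
as clean single-generation events.  Parameter recovery on these data
validates the estimators' arithmetic and calibration, not their robustness
to demographic history, linkage, or marker misbehaviour beyond the
modelled null alleles.

## Problem sizes used by the test suite and acceptance script

Chosen to resolve each question with sampling error well inside the
asserted tolerances: EM recovery at n = 500 (single locus), inbreeding
recovery at n = 200 × 15 loci, migration recovery on two demes of 50 with
10 loci at 200k generations (10–20 seeded runs), screen calibration over
500 null replicates of 4 co-sampled locations, oracle agreements on
10–20-individual toy tables where exhaustive enumeration is possible.

## Known limitations

The ENA correction keeps observed heterozygote terms (the EM cannot
restore unobserved heterozygotes), so under extreme null frequencies the
corrected θ remains an approximation; the migration sampler can attribute
genuine shared ancestry to migration when divergence is weak (posterior
mass away from zero for truly non-exchanging pairs — a property of this
model family, visible in the tests' two-deme runs); exact-test chains
report Monte-Carlo SEs but no exhaustive guarantee beyond the enumeration
threshold; and the hot/cold classification is a screening heuristic whose
false-positive behaviour is quantified, not eliminated.
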