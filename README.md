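# coevmosaic

Comparative microsatellite population genetics for pairs of interacting
species — an invasive aphid host and its introduced parasitoid wasp — with
a geographic-mosaic screen that nominates candidate coevolutionary hot and
cold spots from reciprocal locus-specific divergence outliers.

Importation biological control introduces a natural enemy onto an invasive
pest and then, ideally, leaves them to coevolve.  Whether they actually do
is hard to observe directly.  One line of evidence is comparative
population genetics: genotype both species at neutral microsatellite loci
across shared sampling locations, compare their population structure
(F<sub>ST</sub>), inbreeding (G<sub>IS</sub>) and recent gene flow, and
screen for loci whose divergence at a location is an outlier for *both*
species — the signature expected at a hot spot of reciprocal selection.
`coevmosaic` implements that entire analysis as one tested pipeline, plus
a generator of study-shaped synthetic datasets so every stage can be
validated against known truth.

## What it computes

* **Diversity and inbreeding** (`diversity`): per-location mean and
  effective allele numbers, observed heterozygosity H<sub>o</sub>, Nei
  gene diversities H<sub>s</sub> and H<sub>t</sub> with small-sample
  corrections, and the multilocus inbreeding coefficient
  G<sub>IS</sub> = 1 − H<sub>o</sub>/H<sub>s</sub>.
* **Exact tests** (`exact_tests`): the Hardy–Weinberg conditional
  probability test (full enumeration or a Markov chain over genotype
  tables), permutation G tests of genotypic linkage disequilibrium and of
  genic differentiation between population pairs, combined across strata
  with Fisher's method (X² = −2Σln p on 2k df) and Bonferroni-adjusted
  thresholds.
* **Null-allele-corrected differentiation** (`null_fst`): EM estimation of
  per population × locus null-allele frequencies (null/visible
  heterozygotes score as visible homozygotes, null homozygotes as missing),
  Weir–Cockerham multiallelic F<sub>ST</sub> with the ENA ("excluding null
  alleles") correction, and the allele-size analogue Rho<sub>ST</sub>.
* **Recent migration** (`migration_mcmc`): a Bayesian
  Metropolis-within-Gibbs sampler over migrant fractions m[l][q]
  (row-stochastic, non-migrant fraction ≥ 2/3), per-population allele
  frequencies and inbreeding coefficients, and per-individual migrant
  ancestries (non-migrant / first- / second-generation), with the
  mean ± 1.96 SD significance rule and multi-chain convergence
  diagnostics.
* **Mosaic screen** (`mosaic_screen`): per-locus F<sub>ST</sub> of every
  location against the species' reference cold spot, Tukey-fence
  (boxplot-whisker) outlier loci, reciprocal hot/cold-spot classification,
  an optional permutation significance test per outlier locus, and the
  Welch t comparison of G<sub>IS</sub> between species.
* **Synthetic data** (`synthetic_data`): island-model genotypes with
  inbreeding, null alleles, genotyping failure, aphid-style clonality,
  planted migrants and planted selection hotspots, all recorded in a truth
  object for recovery testing.

## Worked example

```python
import coevmosaic as cm

# a study-shaped pair: 5 locations each (4 co-sampled), 12 vs 15 loci
host, parasitoid, truth = cm.simulate_pair(
    cm.aphid_config(), cm.parasitoid_config(), seed=1)

print(cm.heterozygosity_stats(parasitoid).rounded())
```

```
             N    Num  Eff_num     Ho     Hs     Ht    GIS
population
YubaCity     7  2.333    1.698  0.270  0.375  0.375  0.280
Arbuckle    14  2.267    1.729  0.244  0.401  0.401  0.392
UpperLake   13  2.467    1.741  0.297  0.376  0.376  0.210
Escalon     12  2.333    1.634  0.259  0.370  0.370  0.302
Newark      10  2.133    1.546  0.267  0.335  0.335  0.203
```

Each row is one sampled location: `N` genotyped diploid females, mean and
effective alleles per locus, observed heterozygosity (here ≈ 0.27, the low
level typical of these markers), gene diversity, and the inbreeding
coefficient (positive = heterozygote deficit).  With a single location per
row, H<sub>s</sub> = H<sub>t</sub>.

```python
screen_h = cm.locus_specific_divergence(host, "Linden")
screen_p = cm.locus_specific_divergence(parasitoid, "YubaCity")
report = cm.classify_locations(screen_h, screen_p)
print(report.classification["classification"])
```

A location is `candidate_hot_spot` only when both species carry at least
one Tukey-fence outlier locus there; the species-specific reference
locations (where the counterpart species is absent) are
`reference_cold_spot`.

The same analyses run from the shell:

```
coevmosaic simulate --seed 1 --out simulated/
coevmosaic diversity simulated/parasitoid.gen
coevmosaic all config.yaml          # full pipeline from a YAML config
```

Input formats: GenePop text (2- or 3-digit alleles) and a CSV dialect
(`id,population,locus1,…` with `a1/a2` cells and `.` for missing).

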