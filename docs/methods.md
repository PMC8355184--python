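# Methods

## The discovery statistic

For each gene *g* with inverse-normal expression across *n* individuals, all
genes *h* whose TSSs lie strictly within 1 Mb of the TSS of *g* form its cis
set. Observed Pearson correlations r(g,h) are compared against a per-gene
null built by shuffling the values of *g* across individuals while leaving
the cis genes intact; each of the R shuffles records the maximum |r| over
the cis set. Keeping the per-shuffle *maximum* makes the null automatically
account for how many neighbours a gene has, and leaving the cis genes
unshuffled preserves their correlation structure — the two properties that
distinguish this test from a naive per-pair permutation test.

The adjusted p-value of a pair from gene *g*'s side is the empirical tail
probability

    adj_p = (1 + #{null maxima >= |r_obs|}) / (R + 1),

which is never zero and counts ties toward the null (conservative). Gene-level
significance is the adjusted p of each gene's best pair; Benjamini–Hochberg
across genes at FDR 1% gives a global threshold (the largest gene-level
adjusted p that passes), and a pair is a called co-expressed pair (COP) only
when its adjusted p from *both* member genes is at or below that threshold.
Pairs with |r| >= 0.99 are treated as mapping artifacts and removed before
the BH step. The |r| statistic makes the null two-sided so negative
co-expression is detectable; a signed mode is available.

A consequence of the discrete (1+k)/(R+1) scale worth knowing: BH at level q
can reject only if the fraction of genes sitting at the floor 1/(R+1)
exceeds 1/(q(R+1)). At the default R = 1000 and q = 0.01 this needs ~10% of
genes carrying signal; at R = 200 (used in tests to keep runtimes short)
it needs ~50%. The bundled generator's default study conditions put 60–80%
of genes in co-expression blocks, so both regimes behave like the real-data
one, where roughly half of expressed genes are locally co-expressed.

Per-gene permutation RNGs derive from a SHA-256 hash of (global seed,
stage name, gene id), so discovery output is independent of gene iteration
order and reproducible gene by gene; tests verify the null maxima
permutation-for-permutation against a brute-force reimplementation.

## Preprocessing

Genes are filtered on biotype (protein-coding and lincRNA by default),
excluded regions/chromosomes keyed on the TSS, and a zero-expression
ceiling (>= 50% zeros removes the gene); optional TPM/read-count rules
mirror the common bulk pipeline. Known covariates and the top expression
principal components (the deterministic stand-in for latent-factor models)
are regressed out by OLS with an intercept; collinear columns are dropped
with a warning. The inverse normal transform maps ranks to normal quantiles
with the rank/(n+1) convention and average ranks for ties; it is idempotent
and preserves Spearman correlations exactly. Default order is
residualize → INT, configurable.

## Matched controls

Each COP receives one non-COP control drawn uniformly, without replacement,
from tested pairs with adjusted p > 0.5 on both sides and TSS-distance
discrepancy <= 100 bp; COPs are visited in a seed-shuffled order so none is
systematically favored when candidates are scarce. Trans controls match on
correlation instead (relative difference <= 5%, pool thresholded at the
run's minimum significant cis |r|).

One calibration subtlety: after matching, the *whole-set* rank AUC of COP
vs control distances is 0.5 to four decimals, but the 50× 80/20
logistic-regression harness reports a mean AUC slightly *below* 0.5
(~0.475–0.48 at ~700 matched pairs). This is a property of train/test
evaluation on a finite zero-signal sample: the test fold is the complement
of the train fold, so whatever spurious direction the model fits on the
train side is anti-correlated with the test side. The effect shrinks with
sample size and is far inside the ±0.03 acceptance band; it would appear
identically in any reimplementation of the same evaluation procedure.

## Molecular features

All 13 pair metrics are symmetric and zero-filled when an annotation source
is absent. Conventions: "between the TSSs" is the open interval between the
two TSS coordinates with any-overlap counting; the inverted-CTCF metric is
n₊ × n₋ over oppositely oriented motifs in that interval (all possible
loop-anchor pairings); TF totals are summed per ±50 kb window so an
instance spanning both windows counts twice; Hi-C lookup bins TSSs by
floor(TSS/5 kb); expression-similarity metrics are relative differences of
raw-scale means (or medians) and coefficients of variation; the LD proxy is
the maximum dosage r² between ±5 kb TSS-flanking variant sets, skipping
monomorphic variants. Coordinates are 0-based half-open throughout (BED
native; GTF converted on read).

## Classification harness

Each named model (CTCF, Hi-C, Enhancer, TF, Expression, GO, LD,
eQTL-sharing, Distance, Combined) is an unregularized logistic regression
(scikit-learn, C=∞) on the model's feature columns, standardized on the
training fold. Per repetition the matched pair set is split 80/20
preserving class balance, and ROC AUC is measured on the held-out 20%; the
mean over 50 repetitions is reported. Split RNGs derive from (seed, model,
repetition).

## cis-eQTL mapping and sharing

The association test is per-variant OLS of INT expression on alternate
allele dosage with a two-sided t p-value, over variants with empirical
MAF >= 5% within ±1 Mb of the TSS. The nominal pass retains associations
with p < 0.05 (each gene's lead retained regardless); the permutation pass
shuffles the phenotype R times, records the best p per shuffle (computed as
the p of the maximum |correlation|, which is the same thing), and adjusts
the observed best p either empirically ((1+k)/(R+1)) or through a
method-of-moments Beta fit of the null minima, which resolves below the
empirical floor at small R (tests check the two agree within ±0.02 at
R = 1000). eGenes are called by BH at FDR 5% on adjusted p-values.

Pair-level sharing counts, per pair, how many of the (up to two) eGene lead
variants are nominally associated (p < 0.05) with the partner gene with the
same effect sign; the partner association is always recomputed directly so
the nominal-pass cut never becomes missing data. The companion metric
counts eGenes in the pair (0/1/2).

## Enrichment tests

Pair-level functional relatedness uses one-sided Fisher's exact tests of
COP membership × relatedness over all tested pairs. The eQTL-annotation
enrichment compares the observed count of lead eQTLs overlapping a track
with its permutation expectation: annotation intervals within ±1 Mb of each
TSS are expressed as strand-oriented offsets (mirrored for minus-strand
genes), neighborhoods are randomly reassigned among genes per permutation,
and each gene–eQTL pair is overlap-tested at its own offset (duplicated
lead variants count once per gene). The reported p-value is the two-sided
empirical tail with the (1+k)/(R+1) floor; the odds ratio comes from a 2×2
of observed vs *rounded* expected counts — the expectation is not an
integer, and rounding to the nearest count is the documented, tested
choice. Shared-vs-other comparisons are plain two-sided Fisher tests per
track. Odds ratios are sample cross-products with Woolf 95% intervals and a
flagged 0.5 continuity correction on empty cells. No multiple-testing
adjustment is applied across annotation categories.

## GWAS pleiotropy and inflation

A variant's pleiotropy is the number of traits with association p strictly
below 5×10⁻⁸. Shared and other lead eQTLs are compared on unique variants
("shared" wins across tissues) by Fisher tests of the ≥1-trait and >1-trait
proportions and a two-sided Wilcoxon rank-sum on counts, by default
restricted to variants associated with at least one trait (a flag includes
zeros). The genomic inflation factor is the median of χ²₁ quantiles of the
p-values divided by 0.45494 (the χ²₁ median to 4 significant figures),
computed through the χ²₁ survival function; zero p-values are clipped to
the smallest positive float. QQ backgrounds are seed-controlled subsamples
of 10,000 variants.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
the biology that produces it:

- **Genome** — genes on 1–5 chromosomes with exponential TSS spacing
  (default mean 100 kb, matching gene density in gene-rich regions), random
  strand, 90/10 protein-coding/lincRNA.
- **Expression** — blocks of consecutive genes share a standard-normal
  latent factor with loading *a* (pairwise correlation a²); defaults used
  in the study conditions are blocks of two at loadings 0.85–0.9 covering
  60–80% of genes, n = 300 individuals (a typical LCL eQTL cohort size).
  Optional sample-level confounders with random gene weights; optional
  exponentiation to a TPM-like scale for filter testing.
- **Genotypes/eQTLs** — independent variants, dosage ~ Binomial(2, MAF),
  MAF uniform in (0.05, 0.5]; per truth pair one variant gains effect
  β·dosage on both members (probability = shared_fraction, default 0.5) or
  on one; standalone eGenes optional. Default β = 0.5 on a unit-variance
  phenotype with MAF 0.3 gives ~10% explained variance, a strong-but-
  realistic cis effect.
- **Tracks** — homogeneous-Poisson intervals (CTCF sites 20/Mb, CTCF motifs
  10/Mb, TF motifs 100/Mb) with configurable survival factors thinning
  intervals between true-pair TSSs (CTCF) or within ±50 kb of true-pair
  TSSs (TF), default factor 0.5 in study conditions — the direction real
  co-expressed pairs show. Enhancer links are Poisson per gene (3/gene)
  with optional depletion and sharing for true pairs; Hi-C triplets follow
  a power-law distance decay (exponent −1) with lognormal noise.
- **GWAS** — null p-values uniform via z ~ N(0,1); planted lead-eQTL
  variants get z variance multipliers (shared 1.6 vs other 1.3 in study
  conditions, the direction of the real λ contrast), and a configurable
  fraction (0.3 shared vs 0.15 other) are designated genome-wide hits in
  ~2 traits each.

What the generator does **not** emulate: linkage disequilibrium between
variants, read-level noise, library-size effects, tissue structure,
realistic annotation clustering, or negative co-expression mechanisms.
Passing tests therefore demonstrate the statistical machinery — calibration
under the null, power under planted effects, direction of enrichments —
not performance on real data, where confounding, LD and annotation quality
dominate.

## Problem sizes and numerical choices

Test and acceptance runs use 2,000 genes × 300 individuals with R = 200
permutations for discovery-level checks (the per-gene empirical-p floor
then sits at 1/201, compatible with BH at 1% given the study conditions'
signal fraction) and 10,000-variant p-vectors for λ calibration; these
sizes give sub-10-second single runs and minute-scale multi-seed averages.
Degenerate inputs are handled explicitly: constant genes (INT → zeros with
a warning, permutation p = 1), monomorphic variants (skipped in LD,
excluded by the MAF filter), empty candidate pools (errors), zero Fisher
cells (continuity correction, flagged), p = 0 (clipped). All RNG use flows
through the (seed, stage, unit) hash derivation; identical configurations
are byte-identical across runs and machines.
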