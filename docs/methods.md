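# Methods

This note documents the statistical procedures implemented in `aireflow`,
the choices made where the methods left room, and what the synthetic-data
generators do and do not emulate.

## Tissue-restricted gene calling (dynamic step)

Samples of a multi-tissue panel are reduced to `n_groups` (default 11)
tissue groups by average-linkage hierarchical clustering on correlation
distance (1 − Pearson across genes), to keep over-represented, similar
tissues from dominating the ranking. Group expression is the arithmetic mean
of member samples on linear scale. Per gene, groups are sorted descending
(ties broken by group label, so calls are deterministic); for
j = 1..`j_max` the criterion is

    (j-th highest group mean) > T(E_{j+1})

where E_{j+1} is the next highest group's mean. `j_star` is the smallest j
satisfying it; a gene is tissue-restricted iff `j_star ≥ 1`. Because the
groups are in descending order, requiring the j-th group to clear the
threshold is equivalent to requiring all top j groups to clear it.

The threshold's printed rendering is algebraically ambiguous, so two parses
ship behind `threshold_form`:

- `gap` (default): `T(E) = E + E/250 + 50`. The gene must beat the next
  group by an expression-dependent margin — a genuinely "dynamic" step.
  Under this form, scaling all expression by c > 1 changes calls only
  through the fixed +50 offset.
- `saturating`: `T(E) = E/(250+E) + 50`, nearly constant at 50–51.

Both satisfy T(0) = 50 and are monotone non-decreasing; neither is asserted
to be the historically original form. `gap` is the default because a
near-constant threshold would not produce step-like behaviour.
`j_max` defaults to 5: tissue-restricted genes typically express in 1–3
groups, and 5 leaves headroom without admitting broadly expressed genes.

## Differential expression

Bulk contrasts use a per-gene Welch two-sample t on log2 values
(LFC = mean(KO) − mean(control)) with Benjamini–Hochberg adjustment. This is
a deliberate, simple stand-in for the proprietary array-analysis tooling
such studies often use; the package's validation surface is parameter
recovery on synthetic data, not replication of any specific tool's gene
lists. Genes with zero variance in both groups and equal means get p = 1.

Single-cell contrasts first collapse cells to `(animal, cell type)`
pseudobulk sums (strata under 10 cells are dropped with a warning), then
library-size normalize to `log2(1 + 1e4·count/total)` and run the same Welch
t across animals. Animals, not cells, are the replication unit.

Aire-dependent genes are those with LFC < −1 and FDR < 0.05 (strict
inequalities) in the knockout mTEC contrast. Downregulation is always the
signed convention LFC < −1 on the KO − control orientation; figure
conventions that print the magnitude ("LFC > 1 downregulated") are mapped
onto this.

Holm–Bonferroni (step-down, family-wise) is used for small families of
per-population tests; BH (FDR) for genome-wide gene lists. Both delegate to
statsmodels and are cross-checked against definitional brute-force
evaluation in the tests.

## Enrichment statistics

Over-representation uses the one-sided (greater) hypergeometric tail
P(X ≥ a) on the 2×2 table (in-set × hit) built from the population's own
tested universe; enrichment is always the direction of interest, and the
two-sided variant is available behind a flag. The odds ratio is the sample
cross-product ad/bc; any zero cell triggers the Haldane–Anscombe +0.5
correction with a `haldane` flag; an empty set row is flagged `degenerate`
with p = 1 and still counts toward the Holm family size m.

Pre-ranked GSEA uses the classic weighted running sum (weight p = 1): hits
increment by |s_i|^p normalized over the set, misses decrement by
1/(N − |set|); ES is the signed maximum deviation. The null permutes gene
labels — the standard choice when only a ranked list, not sample-level data,
is available. NES = ES / mean(|null ES| of the matching sign), and
p = (1 + #{same-sign |null| ≥ |ES|}) / (n_same_sign + 1). Before comparing
NES across sets, all sets are downsampled without replacement to the
smallest set's size, removing the set-size dependence of the null.
10,000 permutations by default.

Per-cell module scores bin genes into 24 equal-frequency bins of average
log-normalized expression; each set gene draws 100 control genes from its
bin (with replacement when the bin is smaller), and the score is
mean(set) − mean(controls) per cell.

## IFN score

Tonic-sensitive ISGs are the ISGs downregulated (LFC < −1, FDR < 0.05) in a
baseline, unstimulated interferon-receptor-knockout reference contrast;
ISGs missing from the reference are flagged unclassified and excluded, and a
reference covering less than half the ISG universe is rejected as
unreliable.

The score operates on per-animal, per-cell-type means of log-normalized
expression. Animal-level aggregation was chosen over cell-level because
cells of one animal are not independent replicates; this is documented as a
stand-in, since the underlying method statement does not fix the
aggregation level. Per cell type and tonic gene g,
z_g = (x_KO,g − mean_ctrl,g)/sd_ctrl,g, and a knockout animal's score is
Σ_g z_g. SD uses the n−1 denominator and needs ≥ 2 control animals; genes
with zero control SD are dropped rather than epsilon-padded (an epsilon
would let a constant gene dominate the sum). The score is invariant to any
affine rescaling applied identically to knockout and control values of a
gene; under the null with a well-estimated control it has mean 0 and
variance ≈ n_genes (with few control animals the variance is inflated by
the estimated mean and SD, by the usual (1 + 1/n)(n−1)/(n−3) factor).

## Diversity (Hill number of order 0)

Only q = 0 (richness) is implemented; the API carries q for future orders
but rejects anything else. Per population, UMIs are pooled across cells and
zero-total genes removed. Interpolation is the exact hypergeometric
expectation E[S_m] = Σ_g [1 − C(N−n_g, m)/C(N, m)], computed with
log-gamma so large N stays finite; it is exact at m = N. Extrapolation
anchors on Chao1 (S_obs + f1²/(2f2), or the bias-corrected
f1(f1−1)/2 form when f2 = 0) and follows the standard asymptotic form
S(N+m*) = S_obs + f̂0[1 − (1 − f1/(Nf̂0+f1))^m*]; with no singletons the
curve is flat at S_obs (flagged, not an error).

Standard errors come from a multinomial bootstrap (default 200 draws) over
the estimated complete abundance distribution: observed relative abundances
shrunk by the unseen-mass estimate f1/N, plus f̂0 equally-abundant unseen
genes. CIs are estimate ± 1.96·se. Populations are compared at a common
depth m* (default 2× the smallest population's UMI total, the usual
extrapolation-limit guidance) with a Wald Z whose SEs are recovered from
the CI half-width /1.96; p values are two-sided normal, Holm-adjusted. When
sampling is fully saturated the bootstrap SE can be exactly zero; a genuine
difference then reports Z = ±inf with p = 0 rather than a spurious 0. Note
that interior rarefied values at a fixed m are evenness-sensitive: adding
cells can lower E[S_m] even though observed richness never decreases.

## Cross-species modules

Mouse DE tables are mapped to rat gene space through an ortholog map
filtered to one-to-one pairs (any ambiguous gene is dropped entirely).
The combined LFC matrix keeps genes present in the rat table and at least
one mouse dataset; missing entries are NaN — imputed as 0 (the scaled mean)
only inside K-means, flagged, and never used in enrichment universes.
K-means (k = 4, taken as a fixed input, not selected by criterion) runs on
column-z-scaled LFCs, best of 50 initializations by within-cluster sum of
squares, labels renumbered by descending size. Module enrichment reduces to
the Fisher machinery per module with Holm across modules.

Sample PCA standardizes genes (dropping zero-variance genes), decomposes
the covariance, and fixes each component's sign so its largest-magnitude
loading is positive — coordinates are then invariant to gene and sample
ordering. Population dendrograms use average linkage on 1 − Pearson with
plain bootstrap proportions (genes resampled with replacement) as node
support; multiscale-corrected (AU) support is out of scope and the values
are labelled as plain proportions. Spearman comparisons use average ranks
for ties, the t approximation for n > 9, and exact permutation enumeration
for n ≤ 9.

## Synthetic data

The generators are pure functions of their parameters and seed, and their
defaults define the simulated study conditions:

- `make_tissue_panel` (2,000 genes, 33 samples, 11 tissue groups, 50 TRAs,
  expr_hi/expr_lo = 1000/10, noise sd 1): background genes sit at expr_lo
  with Gaussian noise truncated at zero; each planted TRA expresses at
  expr_hi in 1–3 random groups; samples within a true group share a
  per-(group, gene) offset of the same magnitude as the noise, which makes
  them correlated replicates the clustering can recover.
- `make_mtec_bulk` (2,000 genes, 100 Aire-dependent at LFC −4, 4 vs 4
  animals, log2 noise sd 0.25): Gaussian-on-log2 noise matches
  microarray-style bulk data; null genes share a common mean across
  genotypes.
- `make_sc_counts` (4 cell types, 3 animals per genotype, 200 cells per
  animal per type, 2,000 genes, 100 ISGs of which half tonic at LFC −2,
  log-normal library sizes around 5,000, negative-binomial size 2):
  per-cell means are library_size × gene_proportion × genotype_effect with
  variance μ + μ²/size. A `support_frac` option restricts a cell type's
  expressed-gene support (default: T cells at 0.5), planting the 2:1
  richness contrast the diversity stage tests.
- `make_cross_species` (1,200 genes, 4 mouse datasets, 4 modules of 50
  genes at effect −3): module 1 is downregulated in every dataset
  (conserved), the others in distinct dataset subsets; the conserved module
  carries TRA membership at 50% vs 10% background (expected sample odds
  ratio (0.5/0.5)/(0.1/0.9) = 9) and ISG membership at 30% vs 5%.

Not simulated: doublets, ambient RNA, batch effects, cell-level
overdispersion heterogeneity, and gene–gene correlation beyond the planted
module/group structure. Passing tests therefore demonstrate that the
algorithms recover the planted signal under their stated noise models, not
that they are robust to every artefact of real single-cell data.

## Problem sizes and numerics

The test suite and the acceptance script scale simulations to desk size as
the package's own choice of problem size: oracle checks run on universes up
to 60 genes (Fisher), abundance vectors with N ≤ 12 (rarefaction, exhaustive
enumeration), 6-gene ranked lists (GSEA, all C(6,3) assignments), and
p-vectors up to length 12 (Holm/BH); null error rates use 100 simulation
replicates; the IFN null contract uses 500 replicates with 100 control
animals (so the control moments are well estimated); the end-to-end cohort
uses the generator defaults above. The diversity Wald Z is additionally
reported from a shallow cohort (20 cells per animal, library size ~80)
where rarefaction and the bootstrap SE are genuinely exercised, because the
default cohort saturates gene detection.

Correlation distances are clipped at 0 to absorb floating-point negatives;
rarefaction terms are computed in log space; permutation p values carry the
+1 pseudocount; K-means and all bootstraps draw from generators derived
from (global seed, stage name), so every stage is independently
reproducible.

## Known limitations

- The bulk DE test is an unmoderated Welch t: no empirical-Bayes shrinkage,
  covariates or paired designs.
- GSEA p values are plain permutation fractions (no multi-level or adaptive
  scheme), so the smallest attainable p is 1/(n_perm+1).
- Bootstrap clade support is the plain proportion, systematically more
  conservative than multiscale-corrected support for well-separated clades.
- The ortholog map must be reduced to one-to-one pairs; paralog-aware
  mapping is out of scope.
- Diversity orders q > 0 (Shannon, Simpson) and coverage-based
  standardization are not implemented.
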