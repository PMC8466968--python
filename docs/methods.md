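# Methods

## The model

`rhmscan` estimates, for each short genomic window, the fraction of
phenotypic variance explained jointly by the SNPs inside it, on top of a
genome-wide polygenic background and the experimental design. The plot-level
mixed model per window is

    y = Xβ + Z₁b + Z₂r + Z₃u + e,

where `y` are plot phenotypes (one per family × replication), `X` holds the
intercept, replication dummies and — for the yield traits GY and PE — the
plants-per-plot and kernel-moisture covariates, `b` is a random
block-within-replication effect with covariance `Iσ²_b`, `r` is the regional
genomic effect with covariance `G_reg σ²_r`, `u` is the polygenic effect
with covariance `G σ²_u`, and `e ~ N(0, Iσ²_e)`. `G` is the VanRaden
relationship matrix `WW′ / 2Σpⱼ(1−pⱼ)` with `W` the column-centred dosage
matrix; `G_reg` is the same construction restricted to the focal window's
SNP columns, using allele frequencies from the full panel so both matrices
share one scale. All four components live on the plot level through the
incidence matrices `Z₁` (plots→blocks) and `Z₃ = Z₂` (plots→families).

The regional component is tested by a likelihood-ratio test of the full
model against the null without `r` (fitted once per trait), and

    h²_region = σ²_r / (σ²_r + σ²_u + σ²_e),

i.e. block variance is excluded from the denominator as design rather than
genetic-plus-residual variance. Windows significant at α are merged into QTL
regions when their half-open intervals overlap or abut; a region reports its
span, distinct SNP count, and the peak window's −log₁₀ p and h²_region.

## Estimation: AI-REML with boundary handling

Variance components are estimated by restricted maximum likelihood,
maximising

    ℓ(σ²) = −½ [ log|V| + log|X′V⁻¹X| + y′Py ],
    V = Σ_c σ²_c K_c,   P = V⁻¹ − V⁻¹X(X′V⁻¹X)⁻¹X′V⁻¹,

by average-information (AI) quasi-Newton updates. Each accepted step must
not decrease ℓ (step halving, up to 10 halvings); when no AI step improves,
a monotone EM update is taken instead. Estimates are constrained to
σ²_c ≥ 0 via a small positive floor (10⁻⁸ × var(y)); a component sitting on
the floor whose score is negative is pinned at exactly zero and removed from
the active set, and any component that still converges on the floor is fixed
at zero with the remaining components refit. Convergence is declared when
the relative change in ℓ falls below 10⁻⁸ (at most 100 iterations; a
non-converged window is flagged, not fatal, and the scan continues). The LRT
statistic is clipped at zero, which together with the boundary refit keeps
it non-negative even when the full fit's numerical optimum lands marginally
below the null's.

Two p-value references are available: χ²(1) (default) and the 50:50 mixture
½χ²₀ + ½χ²₁. Because the tested parameter lies on the boundary of its
space, the χ²(1) reference is conservative (its type-I error at nominal
α = 0.05 is near 0.025); the mixture is the asymptotically correct
reference. The default follows the conservative choice; the scan's fixed
genome-wide threshold is α = 0.001 with no further multiple-testing
correction.

The full-model fit warm-starts from the null estimates with the regional
component initialised at 5% of the residual variance. Focal-window SNPs are
*not* removed from the polygenic `G` by default (the matrices are defined
from the full panel); `exclude_window_from_G` provides the alternative,
since keeping them induces a mild downward bias in ĥ²_region — the
polygenic term absorbs part of the regional signal (visible in the recovery
experiment below, median bias ≈ −0.05 at h²_r = 0.5).

An independent check of the optimiser ships with the package:
`direct_reml_maximize` maximises the same REML objective by Nelder–Mead on
log-variances from multiple starts, including explicit boundary sub-models
with each component removed. It shares no code path with the AI iteration
and serves as the oracle in the tests.

## Windows

Windows are half-open `[k·step, k·step + window_size)` for k = 0, 1, … per
chromosome until the last SNP is covered; defaults 100 kb size and 50 kb
step, so consecutive windows overlap by half. Only windows holding at least
`min_snps = 2` SNPs are fitted — a single-SNP window is a marker test, not a
region. Reports print `start-end` of the half-open interval verbatim.

## Phenotype adjustment and LS-means

Before (or independently of) the scan, per-trait adjusted family means come
from the plot model with progeny treated as fixed: intercept, replication
and covariates plus family dummies as fixed effects, block-within-rep random
(REML via the same engine). A family's adjusted mean averages the fitted
fixed surface over replication levels with covariates held at their grand
means — the standard estimated-marginal-means (LS-means) definition.
Aliased fixed-effect columns (e.g. a constant covariate) are detected by
pivoted QR and dropped with a warning; an aliased family column is an error
because that family's mean would be undefined. The descriptive summary
reports per-trait means, SDs, histogram bins, the Shapiro–Wilk statistic
(the default normality test at n ≈ 98) and pairwise Pearson correlations.

## LD decay

Pairwise r² is the squared Pearson correlation of unphased dosage vectors,
computed for all intra-chromosomal pairs (optionally capped by distance);
zero-variance SNPs are skipped with a tally. The decay curve is the
Hill–Weir drift-recombination expectation

    E[r²](C) = (10+C)/((2+C)(11+C)) · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))],

with C = ρ·d. Note the curve decays monotonically to the finite sampling
asymptote 1/n, not to zero. ρ is fitted by unweighted non-linear least
squares on the unbinned pair cloud, multi-started from a log-spaced grid
ρ₀ ∈ [10⁻⁶, 10⁻²] with positivity enforced by optimising log ρ. The
half-decay distance solves E[r²](ρd) = E[r²](ρd_min)/2 by bisection to 1 bp,
where d_min is the smallest observed pair distance; a target at or below
1/n is an error (unreachable). "Half of the decay" is thus defined relative
to the fitted value at the nearest observed distance — not half of r² = 1
and not the midpoint to the asymptote.

## Genotype QC

Thresholds follow the family-panel recipe with strict inequalities:
individuals removed when missingness > 0.10; SNPs kept when MAF > 0.05
(computed on non-missing calls) and missingness < 0.05; all three are
configurable. Residual missing dosages are mean-imputed per SNP before any
relationship matrix is built. When multiple plants per family are genotyped
but phenotypes are family-level, `aggregate_to_families` collapses plants to
mean family dosages; the alternative of using one plant as its family's
representative amounts to passing a pre-filtered matrix. VCF input is read
with cyvcf2 (biallelic records only; multi-allelic records dropped with a
logged count); a plain-text genotype CSV dialect with chromosome/position
header rows round-trips through the package's own writer.

## The synthetic generator

The generator emulates the features of the real panel that the scan's
statistics depend on, at desk scale:

- **Marker structure.** Capture probes yield clusters of SNPs: by default 50
  clusters per chromosome × 10 SNPs within a 40-kb span, on 10 chromosomes
  of 200 Mb. Within a cluster, families share founder haplotypes (4 per
  cluster by default), which produces strong within-window LD and weak
  between-cluster LD — the structure RHM exploits. LD between clusters is
  not modelled (no coalescent history, no recombination map).
- **Families.** Each family's genotype arises from sampling a parent's two
  cluster haplotypes from the founder pool and one generation of selfing,
  giving the S1 expectation F = 0.5 (mean GRM diagonal above 1). One dosage
  row per family is emitted directly. SNPs violating the MAF floor (0.05)
  are resampled at the founder-allele level, keeping haplotype assignments.
- **Phenotypes.** One plot per family × replication (3 reps), incomplete
  blocks as a random equal-size partition of families within each rep (7
  blocks/rep by default; the real block map is unpublished). On a unit
  non-design variance scale: regional QTL terms are built from centred
  window dosages with random SNP effects rescaled so the realised
  across-family variance equals the configured h²_r exactly; the polygenic
  value is drawn with covariance ∝ G and rescaled to h²_u (0.3 default);
  block effects are N(0, 0.05); replication shifts (0, ±0.3) and small
  covariate effects attach to GY/PE only; the residual takes the remaining
  fraction. Trait means (e.g. 2500 kg/ha for GY) are additive offsets only.

Because the generator scales genetic terms to their target variance exactly,
passing recovery tests demonstrates estimator correctness under the model's
own assumptions — clustered biallelic SNPs, additive effects, Gaussian
residuals, no G×E, no dominance/epistasis — and says nothing about, e.g.,
robustness to non-additive architecture or to LD leaking across windows on
real data.

## Validation experiments and problem sizes

The experiments in `rhmscan.validation` (run by both the test suite and
`scripts/acceptance.py`) use sizes chosen to estimate each property with
useful Monte-Carlo resolution while remaining desk-scale:

- optimiser oracle: 20 random 4-component instances at n = 30;
- type-I error: 50 null data sets (98 families × 3 reps, full default
  genome) × 10 windows = 500 boundary LRTs. The genome is kept at its
  default scale here deliberately: with only a handful of probe clusters,
  each window is a large fraction of the whole-genome matrix, the polygenic
  term absorbs the window's signal under the null, and the boundary LRT
  becomes artificially conservative;
- power/localisation: 50 replicates, planted h²_r = 0.3, 2-chromosome
  genome (~50 windows per scan);
- heritability recovery: 100 replicates each at h²_r ∈ {0.1, 0.3, 0.5},
  fitting the planted window;
- Hill–Weir recovery: 1000 noisy on-curve pairs (noise SD 0.05, n = 196).

## Known limitations

- The scan fits each window independently; no multi-window or multi-trait
  joint model, no dominance or epistatic components, no G×E.
- The χ²(1)/mixture references are asymptotic; at 98 families the realised
  type-I error is checked by simulation rather than assumed.
- Mean imputation slightly attenuates r² and GRM entries at high
  missingness; the QC thresholds keep residual missingness below 5%.
- Gene lookup is pure interval overlap (any-overlap by default, containment
  by flag); no functional annotation is retrieved.
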