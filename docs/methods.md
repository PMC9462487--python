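# Methods

This note documents the statistical models behind `varex`, the defaults and
why they were chosen, what the synthetic-study generator does and does not
emulate, and the numerical choices a maintainer would want to know.

## Allele-count association

A variant is tested by counting alleles, not genotypes: each diploid sample
contributes two alleles, missing calls shrink the denominator (no
imputation), and the 2×2 table (alt/ref × case/control) yields the allelic
odds ratio `OR = (alt_case · ref_control)/(ref_case · alt_control)`. When
any cell is zero, 0.5 is added to all four cells (Haldane–Anscombe) so the
OR and its Woolf standard error `sqrt(Σ 1/cell)` stay finite; the
correction never touches the exact test, which must see the raw integral
table. The two-sided Fisher p follows the minimum-likelihood convention —
the sum of hypergeometric probabilities of all tables with the observed
margins no more probable than the observed one, with a `1 + 1e-7` relative
tolerance on the comparison to absorb floating-point ties (the same
tolerance the common implementations use). The hypergeometric pmf is
evaluated through log-gamma functions, so tables with thousands of alleles
are exact and fast. Benjamini–Hochberg runs step-up over the variants with
defined statistics; degenerate variants (a group with no called samples)
are reported with null statistics and excluded from the family size.

The Woolf SE is computed even though an exact test drives the per-variant
inference: the meta-analysis layer needs within-study variances, and
Fisher p-values cannot be inverted into them.

## Random-effects meta-analysis

Study log-ORs are modeled as `y_i ~ N(μ, v_i + τ²)`. τ² is estimated by
REML: the criterion `-½Σ ln(v_i+τ²) − ½ ln Σw_i − ½Σ w_i (y_i−μ̂)²` with
`w_i = 1/(v_i+τ²)` is maximized on `[0, 10·max(v_i) + 2·var(y; ddof=1)]` by
solving the score equation with Brent root-finding in every sign-change
interval of a 257-point scan, comparing candidates (and both endpoints) on
the criterion. This is exact to near machine precision and reproduces the
k = 2 equal-variance closed form `τ̂² = max(0, Δ²/2 − v)`; the bracket's
`2·var(y)` term is required precisely because that closed form can reach
`2·var_pop(y)`. Pooling uses inverse-variance weights at τ̂²; inference is a
Wald normal test (not Knapp–Hartung). A single study returns τ² = 0 with a
warning. When only (OR, p) pairs are available, an explicit opt-in derives
`SE = |log OR|/Φ⁻¹(1−p/2)` — valid only for Wald-derived p-values, hence
the warning it logs.

## Linkage disequilibrium

LD is composite: the Pearson correlation of unphased dosage vectors,
pairwise-complete over samples called at both variants, with entries
supported by fewer than `min_pairs` (default 10) samples set missing. For
random union of gametes this estimates the haplotype-level r, so the
generator's haplotype frequencies give an exact oracle
`r² = D²/(p_A p_a p_B p_b)`. Monomorphic variants get missing rows and
columns including the diagonal — a 0/0 correlation has no value, and
pinning the diagonal at 1 would misrepresent it. Concordance between two
LD matrices restricts both to the shared variants and compares upper
triangles: Pearson r of the r-vectors and the mean absolute difference of
r², plus the largest per-pair discrepancies for inspection. r² (not D′) is
the displayed statistic.

## Expression contrasts

Size factors are plain median-of-ratios: genes with any zero are excluded
from the geometric-mean reference; `s_j = median_i count_ij / geomean_i`.
The equivariance that holds (and is tested) is relative: scaling one
sample's counts by c multiplies its factor by c relative to every other
sample, while the global geometric-mean anchor redistributes a common
`c^(1/m)`. Log-normalization is `log2(count/s + 1)`; the pseudocount 1
preserves zeros.

The two-group test is a per-gene NB log-link regression on the group
indicator with `log s_j` offset, fit by IRLS to 1e-8 (100-iteration cap;
non-convergence yields null statistics and a flag). Dispersion is a pooled
within-group method of moments, `α̂ = max((s² − m)/m², 1e-8)` with
df-weighted pooling — deliberately simpler than empirical-Bayes shrinkage,
because the claims this pipeline supports are directional group contrasts,
not ranking thousands of marginal genes; an optional `alpha` argument
accepts a known dispersion for calibration studies. The Wald statistic is
`β̂₁/SE` with the SE from the weighted information matrix; `log2fc = β̂₁/ln 2`.
Calibration was verified by simulation: at 20 + 20 samples per group the
null type-I error at p < 0.05 is ~0.054, and at 6 + 6 a 4-fold effect is
recovered with mean log2fc ≈ 2.00. DE calls require BH-adjusted p below
the FDR threshold *and* fold change > fc or < 1/fc (defaults 0.05 and 2).

Three-genotype-group association uses the classical one-way ANOVA on
log-normalized values (F = MS_between/MS_within); zero within-group
variance with unequal means returns p = 0 with a degeneracy flag. ANOVA on
log-normalized values and NB Wald on raw counts coexist on purpose — they
answer the same question under different models and both are exposed.

## Coexpression

Pearson correlations carry two-tailed Student-t p-values
(`t = r√(n−2)/√(1−r²)`; |r| = 1 maps to p = 0 by convention). "Winsorize
when necessary" is made deterministic: each expression vector is winsorized
at 5% per tail when its excess kurtosis exceeds 3 in magnitude; the
winsorization itself clamps the `floor(frac·n)` most extreme order
statistics per tail to the adjacent order statistic. Cook's distances on
the underlying simple regression flag points with `D_i > 4/n`; flags are
reported, never removed — the screen exists to *ensure* no single sample
drives a correlation.

Spearman p-values implement algorithm AS 89 as the published routine is
structured: an exact branch and an Edgeworth-series branch. The exact
branch enumerates the full `n!` rank-permutation null (cached per n) and is
used for tie-free data with n ≤ 9; the Edgeworth series takes over at
n ≥ 10. The crossover is not cosmetic: measured against enumeration, the
series' two-sided error in far tails reaches ~0.04 at n = 7–8, which is why
the algorithm carries an exact branch at all. The series implementation was
checked against an independent implementation of the same algorithm
(upper-tail cases agree to ~1e-9; two-sided values within 5e-3, the residual
coming from a different lower-tail continuity convention). Ties fall back
to the t-approximation with a logged note, since the permutation null
assumes distinct ranks.

Gene distances are `d = 1 − r²`, treating strong correlation of either
sign as proximity; d is not a metric (the triangle inequality fails on
simple triples, and a test asserts one). The 2-D map feeds that
precomputed distance matrix to t-SNE with a fixed seed; the Barnes–Hut
gradient is used because the dense "exact" gradient is not reproducible
across identically-seeded runs in current scikit-learn builds. Perplexity
must satisfy `perplexity < (n−1)/3`; the default 30 suits panels of a
hundred genes or more, and small panels (like the examples) lower it.
Networks threshold on `|r| ≥ 0.6` and BH-adjusted p < 0.05 over a
configured candidate panel rather than all-vs-all, which keeps the
multiple-testing family the size of the scientific question.

## Single-cell layers

Droplet filtering keeps barcodes whose UMI total clears
`max(min_umi, ceil(0.1 · P99))` with `min_umi = 100` — a concrete version
of "a threshold calculated from the UMI distribution": a tenth of the
99th percentile sits far below real cells and far above ambient droplets
whenever the two populations are separated at all. Library correction
reuses median-of-ratios over genes detected in ≥ 95% of cells; with fewer
than 50 such genes (typical droplet sparsity) it falls back to library-size
factors `total/median(total)` with a logged note.

Layer assignment replaces cluster-then-annotate with a direct marker
score: each marker gene is z-scored across cells, a cell's layer score is
the mean z of the layer's markers (basal: DST, KRT5; spinous: KRT10;
granular: KLK7), and the arg-max wins unless the top two scores are within
a margin ε = 0.25, in which case the cell stays unassigned. The testable
content of the downstream claims is the layer-wise statistics, not the
clustering algorithm, so the assignment is the simplest deterministic rule
that uses exactly the published markers. Gradients are one-way ANOVAs
across layers with a direction call from the ordered means
(basal → spinous → granular, strict within 1e-9). The high/low contrast
splits cells expressing gene A (A > 0) at the median of the positive
values, ties to low — the dichotomy is among expressors, matching how
"high and low expressors" are parsed — and compares gene B between halves
with Welch's t (group sizes and variances differ by construction).

## The synthetic-study generator

The generator is the test bed for every stage and defines the study
conditions the acceptance checks run under.

**Genotypes.** Haplotype blocks with explicit haplotype frequencies;
individuals draw two haplotypes per block independently, blocks are
mutually unlinked. LD within a block is therefore exactly the
haplotype-implied r². The default block has five SNPs with the causal
allele at frequency 0.30 and one perfect-LD neighbor.

**Phenotypes.** Disease status follows a logistic model with log-odds
`baseline_logit + dosage · ln(allelic OR)`; case/control cohorts are
ascertained retrospectively by resampling the population with replacement
until both quotas fill. The default `baseline_logit = −4` keeps prevalence
low; this matters because the allele-count OR equals the per-allele odds
ratio only in the rare-disease limit — at prevalence ≈ 25% the estimand
drifts to ~2.1 when the model OR is 2, which would be a bias of the
*simulation design*, not of the estimator.

**Bulk counts.** Gene i in sample j is NB with mean
`s_j · base_i · 2^(β_i g_j + λ_i f_j)` and variance `μ + αμ²`: `g_j` the
causal dosage, `f_j ~ N(0,1)` a shared latent factor creating correlated
modules, `s_j` log-normal library scaling (σ = 0.2). The default panel
plants the motivating biology: PCSK9-like expression falls 0.75 log2 per
alternative allele while IL36G rises, the two load oppositely on the
factor with loadings sized (by a delta-method count-noise formula) so
their latent log-scale correlation is −0.7, PGK1 is flat, and thirty
tight housekeeping genes stand in for the genome-wide background that
real studies estimate size factors from — with only a handful of noisy
genes the estimated factors would carry shared noise that genome-scale
data does not have, attenuating planted correlations by ~0.05. The
exported truth (`implied_gene_correlations`) accounts for factor loadings,
genotype-driven covariance and count noise, and large-n simulation
reproduces it to three decimals.

**Cells.** Three layers (150 cells each by default) with marker means 50
in the home layer and 1 elsewhere, PCSK9 gradient means 8/6/2 and IL36G
1/2/8 across basal/spinous/granular, NB dispersion 0.3, per-cell
log-normal library factors (σ = 0.3), ~4,500-UMI real cells, and 25%
empty droplets at ~10 UMIs.

**What passing does and does not show.** The generator emulates the
*statistical structure* the methods consume — LD, ascertainment,
overdispersion, correlated modules, layered expression, ambient droplets.
It does not emulate read-level artifacts (allele-specific mapping bias,
RNA-editing miscalls, low-coverage genotyping error), population
stratification, batch effects, doublets, or inter-block LD. Passing the
recovery suite shows the estimators are correct and calibrated under the
declared model, not that the upstream variant calling is robust on real
tissue.

## Problem sizes

The test and acceptance runs use: an exhaustive Fisher sweep over all 2×2
tables with margins ≤ 30 (~600k tables); 200 case/control replicates at
1000+1000 with 2000 null variant tests; 200 random REML problems against a
refined grid oracle; 500 meta-analysis recovery replicates; 5000 null and
500 powered NB genes; 100 eQTL replicates at 30 samples per genotype
group; 200 coexpression replicates at n = 200 with a full tie-free n ≤ 8
Spearman sweep; and 20 single-cell replicates of 450 cells. These sizes
give Monte-Carlo error comfortably below each pass band while keeping the
whole suite around a minute of compute.

## Known limitations

- No covariate adjustment anywhere: association is marginal, DE is a
  two-group contrast, the ANOVA is one-way.
- The NB dispersion estimate is per-gene method-of-moments; at very small
  n it is noisy and the Wald test correspondingly liberal, which is why
  calibration claims are made at 20 + 20.
- No trend test across 0/1/2 copies is provided; dose-response claims are
  left to the three-group ANOVA.
- The Spearman tie fallback is the t-approximation, not a tie-corrected
  permutation null.
- VCF support is deliberately a subset: biallelic records with GT; no
  phasing, no indexing, no multi-allelic splitting.
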