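# varex

RNA-Seq variant association and expression analysis toolkit.

Modern transcriptome studies increasingly double as genetic studies: genotypes
called from RNA-Seq reads can be tested for disease association, validated
against a reference panel through their linkage-disequilibrium (LD) structure,
and connected to expression phenotypes in the same samples. `varex`
implements that full chain as a reusable Python library for statistical
geneticists and genomics analysts, with a synthetic-study generator so every
stage can be exercised and calibrated against known ground truth. The
motivating use case is skin immunology — a psoriasis-risk SNP in the 3' UTR
of *PCSK9* (rs662145 C > T) whose alternative allele tracks with lower
*PCSK9* and higher *IL36G* expression in keratinocytes — but every component
is generic.

## What it computes

- **Allele-count association** (`varex.assoc`). Per variant, alternative vs
  reference alleles (two per diploid sample, missing calls dropped) are
  counted in cases and controls. The allelic odds ratio is the 2×2
  cross-product ratio, `OR = (a·d)/(b·c)`, with a Haldane–Anscombe 0.5
  correction when a cell is empty and the Woolf standard error
  `SE(log OR) = sqrt(Σ 1/cell)`. Significance is the two-sided Fisher exact
  test (minimum-likelihood convention), with Benjamini–Hochberg adjustment
  across variants.
- **Random-effects meta-analysis** (`varex.meta`). Study log-ORs `y_i` with
  variances `v_i` follow `y_i ~ N(μ, v_i + τ²)`; the between-study variance
  τ² is estimated by restricted maximum likelihood (score equation solved to
  machine precision), the pooled effect by inverse-variance weighting
  `w_i = 1/(v_i + τ²)`, and inference is a Wald-type normal test on μ.
- **LD concordance** (`varex.ld`). Composite LD as the Pearson correlation
  of unphased dosages (pairwise-complete, with a minimum-pair floor);
  concordance of an RNA-derived LD matrix against a panel matrix as the
  Pearson r of the vectorized upper triangles plus the mean absolute r²
  difference.
- **Genotype-stratified expression** (`varex.de`). Median-of-ratios size
  factors; per-gene negative-binomial log-link regression on a two-group
  indicator (IRLS, log size-factor offset, pooled method-of-moments
  dispersion with variance μ + αμ²) giving a Wald `z = β̂/SE`; one-way ANOVA
  across the three genotype groups on log₂-normalized values; DE calls at
  FDR < 0.05 and fold change > 2 or < 0.5.
- **Coexpression mapping** (`varex.coexpr`). Pearson correlations with
  two-tailed Student-t p-values, optional winsorization of heavy-tailed
  vectors and a Cook's-distance influence screen; Spearman p-values by
  algorithm AS 89 (exact rank-permutation enumeration for n ≤ 9, Edgeworth
  series beyond); gene distances `d = 1 − r²`; a seeded 2-D t-SNE embedding
  of the transcriptome; and a signed coexpression network thresholded on
  |r| and adjusted significance.
- **Single-cell layers** (`varex.sc`). UMI droplet filtering, library
  normalization, marker-score assignment of keratinocytes to epidermal
  layers (basal: *DST*/*KRT5*, spinous: *KRT10*, granular: *KLK7*),
  layer-gradient ANOVA with a monotonicity call, and a Welch t contrast of
  one gene between high and low expressors of another.
- **Synthetic studies** (`varex.simulate`). Haplotype-block genotypes with a
  causal SNP at a stated allelic OR under retrospective case/control
  ascertainment; NB bulk counts with genotype-dependent means and a shared
  latent factor planting gene–gene correlations; layered single-cell counts
  with markers, opposing gradients and empty droplets — all deterministic
  under a seed, all with exported ground truth.

## Worked example

`examples/` holds one narrative script per capability. Association and
meta-analysis (`python examples/01_allele_association.py`):

```
cohortA (1000+1000):
 variant  or_hat      p  p_adj
   rs101  1.1368 0.0462 0.0462
   rs102  1.4191 0.0000 0.0000
   rs103  1.5593 0.0000 0.0000
rs662145  1.8780 0.0000 0.0000
   rs105  1.8780 0.0000 0.0000
...
pooled OR = 1.947 [1.723, 2.199], tau2 = 0.0007, Wald p = 9.73e-27
```

Two simulated cohorts carry a causal allele with true OR 2 at rs662145; the
allele-counting scan estimates ORs near 2 at the causal site (and at its
perfect-LD neighbor rs105), weaker signals at partially linked variants, and
the REML-pooled estimate tightens the interval around the truth.

The single-cell pipeline (`python examples/05_single_cell_layers.py`):

```
kept 450 barcodes after the UMI filter (threshold 932)
layer recovery: 99.8%
PCSK9: decreasing across layers (basal=2.96, spinous=2.46, granular=1.34), F = 125.5, p = 5.70e-44
IL36G: increasing across layers (basal=0.86, spinous=1.35, granular=2.92), F = 251.3, p = 8.23e-74
IL36G in PCSK9-high vs PCSK9-low cells: t = -8.28, p = 1.95e-15 (means 1.17 vs 2.07)
```

All 150 empty droplets are removed, 99.8% of cells land in their true layer,
and the opposing *PCSK9*/*IL36G* gradients plus the negative high/low
contrast are recovered with the correct directions.

A thin CLI mirrors the library (`varex simulate | assoc | meta | ld | de |
coexpr | sc`); run `varex --help` for the options of each subcommand.

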