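"""Synthetic case/control studies with genotype, bulk and single-cell layers.

The generator produces the full chain of inputs the pipeline consumes,
with known ground truth at every level:

* **Genotypes** — haplotype blocks: each individual draws two haplotypes
  independently within each block from the block's frequency table, so
  pairwise LD is exactly the haplotype-implied r^2 = D^2/(pA pa pB pb)
  and blocks are mutually unlinked.
* **Phenotypes** — a logistic disease model, log-odds = baseline_logit +
  dosage * ln(allelic OR) at the causal variant, sampled retrospectively
  (with replacement until the case and control quotas fill) as in a
  case/control design.  With a low baseline the allele-count OR estimand
  equals the per-allele odds ratio.
* **Bulk counts** — negative binomial (variance mu + alpha mu^2) around
  gene means 2^(eqtl_beta * dosage + loading * factor) scaled by a
  log-normal library size; a shared latent factor per sample creates
  correlated gene modules, eqtl_beta creates genotype-dependent
  expression (e.g. a negative effect on a cytokine-like gene).
* **Cells** — layered single-cell counts (basal/spinous/granular) with
  layer-specific marker means, monotone gradient genes, per-cell
  log-normal library factors and a configurable admixture of tiny-library
  empty droplets.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError
from .io import CountsMatrix, GenotypeMatrix, PhenotypeTable, VariantRecord

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeBlock:
    """A set of variants inheriting together: haplotypes with frequencies."""

    variant_ids: list[str]
    haplotypes: list[tuple[int, ...]]
    frequencies: list[float]
    chrom: str = "1"
    start_pos: int = 1

    def __post_init__(self) -> None:
        m = len(self.variant_ids)
        if any(len(h) != m for h in self.haplotypes):
            raise ConfigError("haplotype length inconsistent with variant ids")
        if any(a not in (0, 1) for h in self.haplotypes for a in h):
            raise ConfigError("haplotype alleles must be 0/1")
        if abs(sum(self.frequencies) - 1.0) > 1e-9:
            raise ConfigError(f"haplotype frequencies sum to {sum(self.frequencies)}, "
                              "must sum to 1 (+-1e-9)")
        if any(f < 0 for f in self.frequencies):
            raise ConfigError("negative haplotype frequency")

    def allele_frequencies(self) -> np.ndarray:
        """Haplotype-implied ALT allele frequency at each variant."""
        h = np.asarray(self.haplotypes, dtype=float)
        f = np.asarray(self.frequencies)
        return f @ h

    def implied_r2(self, i: int, j: int) -> float:
        """Haplotype-implied LD r^2 = D^2 / (pA pa pB pb) between two variants."""
        h = np.asarray(self.haplotypes, dtype=float)
        f = np.asarray(self.frequencies)
        p_i, p_j = f @ h[:, i], f @ h[:, j]
        p_ij = float(np.sum(f * h[:, i] * h[:, j]))
        denom = p_i * (1 - p_i) * p_j * (1 - p_j)
        if denom == 0:
            return np.nan
        d = p_ij - p_i * p_j
        return float(d * d / denom)


@dataclass
class GeneParams:
    """Generative parameters for one bulk gene.

    ``eqtl_beta`` is the log2 shift in mean expression per alternative
    allele at the causal variant; ``factor_loading`` is the gene's log2
    loading on the shared latent factor driving coexpression.
    """

    name: str
    baseline_mean: float
    dispersion: float
    eqtl_beta: float = 0.0
    factor_loading: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ConfigError(f"{self.name}: baseline_mean must be > 0")
        if self.dispersion <= 0:
            raise ConfigError(f"{self.name}: dispersion must be > 0")


@dataclass
class SimStudyConfig:
    """Complete recipe for one synthetic case/control expression study."""

    n_case: int = 1000
    n_control: int = 1000
    blocks: list[HaplotypeBlock] = field(default_factory=list)
    causal_variant: str = "rs662145"
    allelic_or: float = 2.0
    baseline_logit: float = -4.0
    genes: list[GeneParams] = field(default_factory=list)
    libsize_sigma: float = 0.2
    n_bulk_samples: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.allelic_or <= 0:
            raise ConfigError("allelic_or must be > 0")
        if self.libsize_sigma < 0:
            raise ConfigError("libsize_sigma must be >= 0")


@dataclass
class SimTruth:
    """Ground truth planted by the generators, for parameter-recovery tests."""

    allelic_or: float | None = None
    eqtl_beta: dict[str, float] | None = None
    gene_correlations: pd.DataFrame | None = None
    layer_labels: pd.Series | None = None
    layer_means: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# genotypes and phenotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(blocks: list[HaplotypeBlock], n: int,
                       seed: int | np.random.Generator = 0) -> GenotypeMatrix:
    """Draw n diploid individuals: two haplotypes per block, dosage = sum."""
    rng = np.random.default_rng(seed)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    for block in blocks:
        h = np.asarray(block.haplotypes, dtype=np.int16)
        f = np.asarray(block.frequencies, dtype=float)
        f = f / f.sum()  # exact normalization within the 1e-9 tolerance
        picks = rng.choice(len(h), size=(n, 2), p=f)
        cols.append(h[picks[:, 0]] + h[picks[:, 1]])
        for k, vid in enumerate(block.variant_ids):
            variants.append(VariantRecord(block.chrom, block.start_pos + k,
                                          vid, "C", "T"))
    dosage = (np.concatenate(cols, axis=1) if cols
              else np.empty((n, 0), dtype=np.int16))
    samples = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(samples, variants, dosage)


def assign_phenotypes(genotypes: GenotypeMatrix, causal_variant: str,
                      allelic_or: float, baseline_logit: float,
                      n_case: int, n_control: int,
                      seed: int | np.random.Generator = 0,
                      dataset: str = "study1",
                      ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Retrospective case/control ascertainment from a source population.

    Individuals are sampled with replacement from ``genotypes``; disease
    status is drawn with log-odds baseline_logit + dosage * ln(allelic_or)
    and individuals fill the case/control quotas until both are met.
    Returns the ascertained cohort's genotype matrix together with its
    phenotype table (resampling defines a new cohort).
    """
    from scipy.special import expit

    j = genotypes.variant_index(causal_variant)
    g = genotypes.dosage[:, j].astype(float)
    if np.any(g < 0):
        raise SimulationError("missing dosage at the causal variant")
    p_disease = expit(baseline_logit + g * np.log(allelic_or))
    if n_case > 0 and p_disease.max() <= 0:
        raise SimulationError("case quota unattainable: disease probability is 0")
    if n_control > 0 and p_disease.min() >= 1:
        raise SimulationError("control quota unattainable: disease probability is 1")
    rng = np.random.default_rng(seed)
    case_idx: list[int] = []
    ctrl_idx: list[int] = []
    max_draws = 5000 * (n_case + n_control) + 100_000
    drawn = 0
    n_pop = len(genotypes.samples)
    while len(case_idx) < n_case or len(ctrl_idx) < n_control:
        batch = max(1024, 4 * (n_case - len(case_idx) + n_control - len(ctrl_idx)))
        idx = rng.integers(0, n_pop, size=batch)
        sick = rng.random(batch) < p_disease[idx]
        case_idx.extend(idx[sick][: n_case - len(case_idx)])
        ctrl_idx.extend(idx[~sick][: n_control - len(ctrl_idx)])
        drawn += batch
        if drawn > max_draws:
            raise SimulationError(
                f"quota not filled after {drawn} draws "
                f"({len(case_idx)}/{n_case} cases, {len(ctrl_idx)}/{n_control} controls)")
    order = np.array(case_idx + ctrl_idx, dtype=int)
    status = ["case"] * n_case + ["control"] * n_control
    samples = [f"{'CA' if st == 'case' else 'CO'}{i + 1:05d}"
               for i, st in enumerate(status)]
    cohort = GenotypeMatrix(samples, genotypes.variants, genotypes.dosage[order])
    pheno = PhenotypeTable(pd.DataFrame({
        "sample_id": samples, "status": status, "dataset": dataset}))
    return cohort, pheno


# ---------------------------------------------------------------------------
# bulk counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, dispersion alpha) with variance mu + alpha mu^2; Poisson limit."""
    if alpha < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mean))


def log2_count_noise_variance(mean: float, alpha: float,
                              pseudocount: float = 1.0) -> float:
    """Delta-method variance of log2(X + pseudocount) for X ~ NB(mean, alpha)."""
    var = mean + alpha * mean * mean
    return var / ((mean + pseudocount) ** 2 * LN2 ** 2)


def loading_for_correlation(target_abs_r: float, mean: float, alpha: float) -> float:
    """Factor loading giving |r| = target for a symmetric-loading gene pair.

    For two genes with loadings +-l on a unit-variance factor and count
    noise v on the log2 scale, |r| = l^2 / (l^2 + v); invert for l.
    """
    if not (0.0 < target_abs_r < 1.0):
        raise ConfigError("target |r| must be in (0, 1)")
    v = log2_count_noise_variance(mean, alpha)
    return float(np.sqrt(target_abs_r * v / (1.0 - target_abs_r)))


def implied_gene_correlations(genes: list[GeneParams],
                              dosages: np.ndarray | None = None) -> pd.DataFrame:
    """Latent correlation of log2 expression implied by loadings (and eQTL).

    Covariance on the log2 scale: loading_i * loading_k from the shared
    unit-normal factor, plus beta_i * beta_k * var(dosage) when dosages
    are supplied; per-gene variance adds the delta-method count noise.
    """
    var_g = float(np.var(dosages)) if dosages is not None else 0.0
    k = len(genes)
    cov = np.empty((k, k))
    for i, gi in enumerate(genes):
        for j, gj in enumerate(genes):
            cov[i, j] = (gi.factor_loading * gj.factor_loading
                         + gi.eqtl_beta * gj.eqtl_beta * var_g)
            if i == j:
                cov[i, j] += log2_count_noise_variance(gi.baseline_mean,
                                                       gi.dispersion)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    names = [g.name for g in genes]
    return pd.DataFrame(corr, index=names, columns=names)


def simulate_bulk_counts(genes: list[GeneParams], dosages,
                         libsize_sigma: float = 0.2,
                         seed: int | np.random.Generator = 0,
                         sample_ids: list[str] | None = None,
                         ) -> tuple[CountsMatrix, SimTruth]:
    """NB bulk counts with eQTL and coexpression structure.

    For sample j with causal-variant dosage g_j, latent factor
    f_j ~ N(0,1) and scaling s_j ~ log-normal(0, libsize_sigma), gene i
    has mean s_j * baseline_i * 2^(beta_i g_j + loading_i f_j) and the
    count is NB with dispersion alpha_i.
    """
    rng = np.random.default_rng(seed)
    g = np.asarray(dosages, dtype=float)
    if not genes:
        raise ConfigError("no genes configured")
    n = g.size
    f = rng.standard_normal(n)
    s = np.exp(rng.normal(0.0, libsize_sigma, size=n)) if libsize_sigma > 0 \
        else np.ones(n)
    counts = np.empty((len(genes), n), dtype=np.int64)
    for i, gene in enumerate(genes):
        mu = s * gene.baseline_mean * np.exp(
            LN2 * (gene.eqtl_beta * g + gene.factor_loading * f))
        counts[i] = _nb_draw(rng, mu, gene.dispersion)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    cm = CountsMatrix([gp.name for gp in genes], list(sample_ids), counts)
    truth = SimTruth(eqtl_beta={gp.name: gp.eqtl_beta for gp in genes},
                     gene_correlations=implied_gene_correlations(genes, g))
    return cm, truth


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------

@dataclass
class CellSimConfig:
    """Layered single-cell recipe: marker genes, gradients, empty droplets.

    ``marker_means`` maps layer -> {gene: mean in that layer}; markers sit
    at ``marker_off_mean`` in every other layer.  ``gradient_means`` maps
    gene -> per-layer mean (the monotone expression gradients).
    Background genes are flat across layers and carry most of the library
    so real cells reach ~``target_umis`` total UMIs; empty droplets are
    extra barcodes whose expected library is ``empty_umis``.
    """

    layer_cells: dict[str, int] = field(default_factory=lambda: {
        "basal": 150, "spinous": 150, "granular": 150})
    marker_means: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "basal": {"DST": 50.0, "KRT5": 50.0},
        "spinous": {"KRT10": 50.0},
        "granular": {"KLK7": 50.0},
    })
    marker_off_mean: float = 1.0
    gradient_means: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "PCSK9": {"basal": 8.0, "spinous": 6.0, "granular": 2.0},
        "IL36G": {"basal": 1.0, "spinous": 2.0, "granular": 8.0},
    })
    n_background_genes: int = 40
    background_mean: float = 120.0
    dispersion: float = 0.3
    libsize_sigma: float = 0.3
    empty_fraction: float = 0.25
    empty_umis: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_cells) < 2:
            raise ConfigError("need >= 2 layers")
        if any(n <= 0 for n in self.layer_cells.values()):
            raise ConfigError("every layer needs at least one cell")
        marker_sets = [set(m) for m in self.marker_means.values()]
        for i, a in enumerate(marker_sets):
            for b in marker_sets[i + 1:]:
                if a & b:
                    raise ConfigError(f"marker sets overlap: {sorted(a & b)}")
        if not (0.0 <= self.empty_fraction < 1.0):
            raise ConfigError("empty_fraction must be in [0, 1)")


def simulate_cells(config: CellSimConfig | None = None,
                   seed: int | np.random.Generator | None = None):
    """Generate a layered cell x gene AnnData plus its ground truth.

    Returns ``(adata, truth)``: the AnnData holds counts for real cells
    and empty-droplet barcodes (obs column ``is_cell``), truth carries the
    per-cell layer labels and the per-layer mean table used to draw them.
    """
    import anndata as ad
    import scipy.sparse as sp

    config = config or CellSimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layers = list(config.layer_cells)
    marker_genes = [g for layer in layers
                    for g in config.marker_means.get(layer, {})]
    gradient_genes = list(config.gradient_means)
    background = [f"BG{i + 1:03d}" for i in range(config.n_background_genes)]
    genes = marker_genes + gradient_genes + background

    mean_table = pd.DataFrame(index=layers, columns=genes, dtype=float)
    for g in genes:
        mean_table[g] = config.background_mean if g in background else config.marker_off_mean
    for layer, markers in config.marker_means.items():
        for g, m in markers.items():
            mean_table.loc[layer, g] = m
    for g, per_layer in config.gradient_means.items():
        missing = set(layers) - set(per_layer)
        if missing:
            raise ConfigError(f"gradient gene {g} lacks means for {sorted(missing)}")
        for layer, m in per_layer.items():
            mean_table.loc[layer, g] = m

    n_real = sum(config.layer_cells.values())
    n_empty = int(round(n_real * config.empty_fraction / (1 - config.empty_fraction)))
    labels = np.repeat(layers, [config.layer_cells[s] for s in layers])
    lib = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_real))
    rows = []
    for c in range(n_real):
        mu = mean_table.loc[labels[c]].to_numpy() * lib[c]
        rows.append(_nb_draw(rng, mu, config.dispersion))
    pooled = mean_table.to_numpy().mean(axis=0)
    empty_mu = pooled * (config.empty_umis / pooled.sum())
    for _ in range(n_empty):
        rows.append(rng.poisson(empty_mu))
    counts = np.asarray(rows, dtype=np.int64)
    barcodes = ([f"CELL{i + 1:05d}" for i in range(n_real)]
                + [f"EMPTY{i + 1:05d}" for i in range(n_empty)])
    adata = ad.AnnData(X=sp.csr_matrix(counts))
    adata.obs_names = barcodes
    adata.var_names = genes
    adata.obs["is_cell"] = [True] * n_real + [False] * n_empty
    truth = SimTruth(
        layer_labels=pd.Series(list(labels) + ["empty"] * n_empty,
                               index=barcodes, name="layer"),
        layer_means=mean_table,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------

def default_blocks() -> list[HaplotypeBlock]:
    """One five-SNP haplotype block with a 0.30-frequency causal allele.

    The causal variant (rs662145-like, ALT frequency 0.30) sits on two
    haplotypes; its neighbor at the block end is in complete LD with it,
    the others in partial LD — enough structure to exercise the LD stage.
    """
    return [HaplotypeBlock(
        variant_ids=["rs101", "rs102", "rs103", "rs662145", "rs105"],
        haplotypes=[(0, 0, 0, 0, 0),
                    (1, 0, 0, 0, 0),
                    (1, 1, 1, 0, 0),
                    (0, 0, 1, 1, 1),
                    (1, 1, 1, 1, 1)],
        frequencies=[0.45, 0.15, 0.10, 0.10, 0.20],
        chrom="1", start_pos=55_039_974)]


def default_gene_panel() -> list[GeneParams]:
    """Cytokine-like bulk panel with a negative eQTL and a -0.7 module.

    PCSK9-like expression falls with each alternative allele
    (eqtl_beta = -0.75) while IL36G rises; PCSK9 and IL36G carry opposite
    loadings on the shared factor sized for a latent correlation of -0.7.
    PGK1 is the flat housekeeping control.  The thirty stable
    housekeeping genes stand in for the genome-wide background real
    studies estimate size factors from: with only a handful of noisy
    genes the median-of-ratios factors would carry artificial shared
    noise that genome-scale data does not have.
    """
    l07 = loading_for_correlation(0.7, 2000.0, 0.02)
    panel = [
        GeneParams("PCSK9", 2000.0, 0.02, eqtl_beta=-0.75, factor_loading=+l07),
        GeneParams("IL36G", 2000.0, 0.02, eqtl_beta=+0.50, factor_loading=-l07),
        GeneParams("IL36B", 800.0, 0.05, eqtl_beta=+0.40, factor_loading=-0.15),
        GeneParams("IL27RA", 600.0, 0.05, factor_loading=+0.20),
        GeneParams("IL1RL1", 400.0, 0.05, factor_loading=-0.20),
        GeneParams("ISG20", 500.0, 0.05, factor_loading=-0.18),
        GeneParams("STX3", 700.0, 0.05, factor_loading=-0.15),
        GeneParams("PGK1", 1500.0, 0.02),
    ]
    rng = np.random.default_rng(20220822)
    for i in range(30):
        panel.append(GeneParams(f"HK{i + 1:02d}",
                                float(rng.uniform(500, 5000)), 0.01))
    return panel


def default_study_config(seed: int = 0) -> SimStudyConfig:
    return SimStudyConfig(blocks=default_blocks(), genes=default_gene_panel(),
                          seed=seed)


@dataclass
class SimStudy:
    """Bundle of one simulated study's layers."""

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    bulk_genotypes: GenotypeMatrix
    bulk_counts: CountsMatrix
    cells: object
    truth: SimTruth


def simulate_study(config: SimStudyConfig | None = None,
                   cell_config: CellSimConfig | None = None,
                   seed: int | None = None) -> SimStudy:
    """Run every generator off one config: genotypes, phenotypes, bulk, cells.

    The bulk expression cohort is an independent draw from the same
    haplotype frequencies (expression samples need not be the
    case/control cohort).
    """
    config = config or default_study_config()
    base_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    pop = simulate_genotypes(config.blocks, max(4 * (config.n_case + config.n_control),
                                                2000), rng)
    cohort, pheno = assign_phenotypes(pop, config.causal_variant, config.allelic_or,
                                      config.baseline_logit, config.n_case,
                                      config.n_control, rng)
    bulk_gm = simulate_genotypes(config.blocks, config.n_bulk_samples, rng)
    j = bulk_gm.variant_index(config.causal_variant)
    bulk_counts, truth = simulate_bulk_counts(
        config.genes, bulk_gm.dosage[:, j], config.libsize_sigma, rng,
        sample_ids=bulk_gm.samples)
    cells, cell_truth = simulate_cells(cell_config or CellSimConfig(), rng)
    truth.allelic_or = config.allelic_or
    truth.layer_labels = cell_truth.layer_labels
    truth.layer_means = cell_truth.layer_means
    return SimStudy(genotypes=cohort, phenotypes=pheno, bulk_genotypes=bulk_gm,
                    bulk_counts=bulk_counts, cells=cells, truth=truth)
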