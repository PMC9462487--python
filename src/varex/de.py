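"""Genotype-stratified expression analysis.

Bulk counts are normalized with median-of-ratios size factors.  Two-group
contrasts (genotype groups at a target SNP, or knockdown vs control) are
tested gene-by-gene with a negative-binomial log-link regression on the
group indicator, fit by iteratively reweighted least squares with the log
size factor as offset; the Wald statistic is the group coefficient over
its standard error.  Dispersion is a pooled within-group method-of-moments
estimate with a small floor — a deliberate simplification relative to
empirical-Bayes shrinkage, since the claims exercised here are directional
group contrasts.  Three-genotype-group association uses a classical
one-way ANOVA on log-normalized values.

A gene is called differentially expressed when its BH-adjusted p falls
below the FDR threshold and its fold change exceeds the fold-change
threshold in either direction (default: p_adj < 0.05 and fold change > 2
or < 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import norm

from .assoc import bh_adjust
from .errors import ContrastError, InputError, NormalizationError
from .io import CountsMatrix, GenotypeMatrix

LN2 = float(np.log(2.0))

#: dosage -> genotype group label at the target SNP
GENOTYPE_LABELS = {0: "REF-HOMO", 1: "HET", 2: "ALT-HOMO"}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def size_factors(counts: CountsMatrix) -> np.ndarray:
    """Median-of-ratios size factors.

    Genes with a zero in any sample are excluded from the reference
    geometric means; s_j is the median over retained genes of
    count_ij / geomean_i.
    """
    c = counts.counts.astype(float)
    keep = (c > 0).all(axis=1)
    if not keep.any():
        raise NormalizationError("no gene is nonzero in every sample")
    logc = np.log(c[keep])
    log_geomean = logc.mean(axis=1, keepdims=True)
    s = np.exp(np.median(logc - log_geomean, axis=0))
    return s


def normalize_log(counts: CountsMatrix, sizefactors: np.ndarray,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    """Element-wise log2(count / s_j + pseudocount), genes x samples."""
    s = np.asarray(sizefactors, dtype=float)
    if np.any(s <= 0):
        raise InputError("size factors must be positive")
    if len(s) != len(counts.samples):
        raise InputError("one size factor per sample required")
    mat = np.log2(counts.counts / s[np.newaxis, :] + pseudocount)
    return pd.DataFrame(mat, index=counts.genes, columns=counts.samples)


# ---------------------------------------------------------------------------
# NB Wald two-group test
# ---------------------------------------------------------------------------

def _pooled_mom_dispersion(norm_counts: np.ndarray, group_b: np.ndarray) -> float:
    """Pooled within-group method-of-moments dispersion for one gene.

    alpha = (s^2 - m) / m^2 within each group, pooled with df weights and
    floored at 1e-8 (variance mu + alpha mu^2 parameterization).
    """
    num = den = 0.0
    for mask in (~group_b, group_b):
        x = norm_counts[mask]
        if len(x) < 2:
            continue
        m = x.mean()
        if m <= 0:
            continue
        s2 = x.var(ddof=1)
        num += (len(x) - 1) * (s2 - m) / m ** 2
        den += len(x) - 1
    alpha = num / den if den > 0 else 0.0
    return max(alpha, 1e-8)


def _nb_irls(y: np.ndarray, group_b: np.ndarray, offset: np.ndarray,
             alpha: float, tol: float = 1e-8, max_iter: int = 100):
    """Fit log mu = offset + b0 + b1*group by IRLS; return (b, se_b1, converged)."""
    x = group_b.astype(float)
    eps = 0.5
    m_a = max(np.mean(y[~group_b] / np.exp(offset[~group_b])), eps / len(y))
    m_b = max(np.mean(y[group_b] / np.exp(offset[group_b])), eps / len(y))
    beta = np.array([np.log(m_a), np.log(m_b / m_a)])
    converged = False
    for _ in range(max_iter):
        eta = offset + beta[0] + beta[1] * x
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        sw, swx = w.sum(), (w * x).sum()
        swx2 = (w * x * x).sum()
        det = sw * swx2 - swx ** 2
        if det <= 0 or not np.isfinite(det):
            return beta, np.nan, False
        b0 = (swx2 * (w * z).sum() - swx * (w * x * z).sum()) / det
        b1 = (sw * (w * x * z).sum() - swx * (w * z).sum()) / det
        new = np.array([b0, b1])
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            converged = True
            break
        beta = new
    eta = offset + beta[0] + beta[1] * x
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + alpha * mu)
    sw, swx, swx2 = w.sum(), (w * x).sum(), (w * x * x).sum()
    det = sw * swx2 - swx ** 2
    se_b1 = np.sqrt(sw / det) if det > 0 else np.nan
    return beta, float(se_b1), converged


def nb_wald_test(counts: CountsMatrix, groups: pd.Series,
                 sizefactors: np.ndarray | None = None,
                 alpha: float | np.ndarray | None = None,
                 fdr: float = 0.05, fc: float = 2.0) -> pd.DataFrame:
    """Per-gene NB Wald contrast between two group levels.

    ``groups`` maps sample id to one of exactly two labels; the second
    level in sorted order is the numerator of the fold change.  ``alpha``
    overrides the pooled method-of-moments dispersion (scalar or
    per-gene), which is useful for calibration studies with known
    dispersion.  All-zero and non-converged genes get null statistics and
    are excluded from the BH family.
    """
    groups = groups.dropna()
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise InputError(f"need exactly two group levels, got {levels}")
    for lev in levels:
        if (groups == lev).sum() < 2:
            raise ContrastError(f"group {lev!r} has fewer than 2 samples")
    cm = counts.subset_samples(list(groups.index))
    if sizefactors is None:
        sizefactors = size_factors(cm)
    s = np.asarray(sizefactors, dtype=float)
    group_b = (groups.loc[cm.samples] == levels[1]).to_numpy()
    offset = np.log(s)
    norm_counts = cm.counts / s[np.newaxis, :]
    n_genes = len(cm.genes)
    if alpha is None:
        alphas = np.array([_pooled_mom_dispersion(norm_counts[i], group_b)
                           for i in range(n_genes)])
    else:
        alphas = np.broadcast_to(np.asarray(alpha, dtype=float), (n_genes,))
    rows = []
    for i in range(n_genes):
        y = cm.counts[i].astype(float)
        if y.sum() == 0:
            rows.append((cm.genes[i], np.nan, np.nan, np.nan, np.nan, False))
            continue
        beta, se, converged = _nb_irls(y, group_b, offset, float(alphas[i]))
        if not converged or not np.isfinite(se) or se <= 0:
            rows.append((cm.genes[i], np.nan, np.nan, np.nan, np.nan, False))
            continue
        z = beta[1] / se
        p = 2.0 * norm.sf(abs(z))
        rows.append((cm.genes[i], beta[1] / LN2, se / LN2, z, p, True))
    out = pd.DataFrame(rows, columns=["gene", "log2fc", "se_log2fc",
                                      "wald_z", "p", "converged"])
    out["p_adj"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    out["de_flag"] = de_call(out, fdr=fdr, fc=fc)
    return out


def de_call(results: pd.DataFrame, fdr: float = 0.05, fc: float = 2.0) -> pd.Series:
    """DE flag: p_adj < fdr AND |log2fc| > log2(fc)."""
    if fc <= 1:
        raise InputError("fold-change threshold must exceed 1")
    flag = (results["p_adj"] < fdr) & (results["log2fc"].abs() > np.log2(fc))
    return flag.fillna(False).astype(bool)


# ---------------------------------------------------------------------------
# genotype grouping and stratified contrasts
# ---------------------------------------------------------------------------

def genotype_groups(genotypes: GenotypeMatrix, snp_id: str) -> pd.Series:
    """Per-sample REF-HOMO/HET/ALT-HOMO label at the target SNP.

    Samples with a missing call are excluded.
    """
    d = genotypes.dosage_for(snp_id).dropna()
    return d.map(lambda g: GENOTYPE_LABELS[int(g)])


def genotype_stratified_de(counts: CountsMatrix, genotypes: GenotypeMatrix,
                           snp_id: str, contrast: tuple[str, str] = ("HET", "ALT-HOMO"),
                           alpha: float | np.ndarray | None = None,
                           fdr: float = 0.05, fc: float = 2.0) -> pd.DataFrame:
    """NB Wald contrast between two genotype groups at ``snp_id``.

    The fold change is ``contrast[1]`` relative to ``contrast[0]``.
    """
    valid = set(GENOTYPE_LABELS.values())
    if not set(contrast) <= valid or len(set(contrast)) != 2:
        raise InputError(f"contrast must name two of {sorted(valid)}")
    labels = genotype_groups(genotypes, snp_id)
    labels = labels[labels.isin(contrast)]
    labels = labels[labels.index.isin(counts.samples)]
    for lev in contrast:
        if (labels == lev).sum() < 2:
            raise ContrastError(f"genotype group {lev!r} has fewer than 2 samples "
                                f"at {snp_id}")
    # order levels so contrast[1] is the numerator regardless of sort order
    coded = labels.map({contrast[0]: "0_" + contrast[0], contrast[1]: "1_" + contrast[1]})
    out = nb_wald_test(counts, coded, alpha=alpha, fdr=fdr, fc=fc)
    return out


# ---------------------------------------------------------------------------
# one-way ANOVA across genotype groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way F test of expression across genotype groups."""

    gene: str
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


def anova_genotype(values: pd.Series, groups: pd.Series,
                   gene: str = "") -> AnovaResult:
    """One-way ANOVA of (log-normalized) expression across group labels.

    F = MS_between / MS_within with the classical decomposition.  Zero
    within-group variance with unequal means yields p = 0 and a
    degeneracy flag instead of a division error.
    """
    common = values.index.intersection(groups.dropna().index)
    v = values.loc[common].to_numpy(dtype=float)
    g = groups.loc[common].to_numpy()
    levels = [lev for lev in pd.unique(g) if (g == lev).sum() >= 2]
    if len(levels) < 2:
        raise InputError("need >= 2 groups with >= 2 samples each")
    keep = np.isin(g, levels)
    v, g = v[keep], g[keep]
    grand = v.mean()
    ss_b = sum((g == lev).sum() * (v[g == lev].mean() - grand) ** 2 for lev in levels)
    ss_w = sum(((v[g == lev] - v[g == lev].mean()) ** 2).sum() for lev in levels)
    df_b = len(levels) - 1
    df_w = len(v) - len(levels)
    if ss_w <= 1e-300:
        if ss_b <= 1e-300:
            return AnovaResult(gene, 0.0, df_b, df_w, 1.0, degenerate=True)
        return AnovaResult(gene, np.inf, df_b, df_w, 0.0, degenerate=True)
    F = (ss_b / df_b) / (ss_w / df_w)
    p = float(f_dist.sf(F, df_b, df_w))
    return AnovaResult(gene, float(F), df_b, df_w, p)


def anova_scan(lognorm: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """One-way genotype ANOVA for every gene of a log-normalized matrix."""
    rows = []
    for gene in lognorm.index:
        try:
            r = anova_genotype(lognorm.loc[gene], groups, gene=gene)
            rows.append((gene, r.F, r.df_between, r.df_within, r.p, r.degenerate))
        except InputError:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, True))
    out = pd.DataFrame(rows, columns=["gene", "F", "df_between", "df_within",
                                      "p", "degenerate"])
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
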