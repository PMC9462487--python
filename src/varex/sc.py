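"""Single-cell stage: droplet filtering, normalization, layer calling,
gradient tests and the high/low expressor contrast.

Cells are kept when their UMI total clears a threshold derived from the
library-size distribution (10% of the 99th percentile, floored).  Library
correction reuses the median-of-ratios rule over broadly detected genes,
falling back to plain library-size factors for very sparse matrices.
Epidermal layers (basal / spinous / granular) are assigned by marker-set
z-scores rather than clustering: the layer whose marker genes score
highest wins, with an abstention margin.  Layer gradients are tested with
a one-way ANOVA across layers, and the marker-free contrast splits cells
into high and low expressors of one gene at the median of its positive
values and compares a second gene between the halves with Welch's t.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from .de import anova_genotype
from .errors import ConfigError, ContrastError, InputError

logger = logging.getLogger(__name__)

LAYER_ORDER = ("basal", "spinous", "granular")


def _dense(adata) -> np.ndarray:
    x = adata.X
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


# ---------------------------------------------------------------------------
# droplet filter
# ---------------------------------------------------------------------------

def umi_threshold(totals: np.ndarray, min_umi: int = 100) -> float:
    """Library-size threshold: max(min_umi, ceil(0.1 * 99th percentile))."""
    return float(max(min_umi, np.ceil(0.1 * np.percentile(totals, 99))))


def filter_droplets(adata, min_umi: int = 100):
    """Drop empty-droplet barcodes by the UMI-total threshold.

    Returns the filtered AnnData (a view-free copy) with the per-cell
    totals in ``obs['total_umis']``.
    """
    if adata.n_obs < 10:
        raise InputError("need >= 10 barcodes to estimate the UMI threshold")
    totals = np.asarray(_dense(adata).sum(axis=1), dtype=float).ravel()
    thr = umi_threshold(totals, min_umi=min_umi)
    keep = totals >= thr
    if not keep.any():
        raise InputError(f"UMI threshold {thr} removed every barcode")
    out = adata[keep].copy()
    out.obs["total_umis"] = totals[keep]
    out.uns["umi_threshold"] = thr
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def sc_normalize(adata, detection_fraction: float = 0.95,
                 min_reference_genes: int = 50):
    """Median-of-ratios cell factors with a library-size fallback.

    The reference set is genes detected in >= ``detection_fraction`` of
    cells and nonzero in every cell (geometric means need positive
    counts).  With fewer than ``min_reference_genes`` such genes —
    typical of sparse droplet data — plain library-size factors
    total / median(total) are used instead, with a logged note.
    Returns ``(lognorm, factors)``: a cells x genes log2(count/s + 1)
    DataFrame and the per-cell factors.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise InputError("empty cell matrix")
    counts = _dense(adata).astype(float)
    detected = (counts > 0).mean(axis=0) >= detection_fraction
    allpos = (counts > 0).all(axis=0)
    ref = detected & allpos
    if ref.sum() >= min_reference_genes:
        logc = np.log(counts[:, ref])
        factors = np.exp(np.median(logc - logc.mean(axis=0, keepdims=True), axis=1))
        method = "median-of-ratios"
    else:
        totals = counts.sum(axis=1)
        if np.any(totals <= 0):
            raise InputError("cell with zero total count; filter droplets first")
        factors = totals / np.median(totals)
        method = "library-size"
        logger.info("only %d reference genes detected in >= %.0f%% of cells; "
                    "falling back to library-size factors",
                    int(ref.sum()), 100 * detection_fraction)
    lognorm = pd.DataFrame(np.log2(counts / factors[:, None] + 1.0),
                           index=adata.obs_names, columns=adata.var_names)
    return lognorm, pd.Series(factors, index=adata.obs_names, name=method)


# ---------------------------------------------------------------------------
# layer assignment
# ---------------------------------------------------------------------------

@dataclass
class LayerAssignment:
    """Per-cell layer labels with the marker-set scores behind them."""

    labels: pd.Series            # basal/spinous/granular/unassigned
    scores: pd.DataFrame         # cells x layers mean marker z-scores
    margin: float


def assign_layers(lognorm: pd.DataFrame, marker_sets: dict[str, list[str]],
                  margin: float = 0.25) -> LayerAssignment:
    """Marker-score arg-max layer call with an abstention margin.

    Each marker gene is z-scored across cells; a cell's layer score is
    the mean z of the layer's marker set and the arg-max wins unless the
    top two scores are within ``margin`` (then ``unassigned``).
    """
    for layer, markers in marker_sets.items():
        missing = [m for m in markers if m not in lognorm.columns]
        if missing:
            raise ConfigError(f"marker gene(s) missing from matrix for layer "
                              f"{layer!r}: {missing}")
    z = (lognorm - lognorm.mean(axis=0)) / lognorm.std(axis=0).replace(0, np.nan)
    scores = pd.DataFrame({layer: z[markers].mean(axis=1)
                           for layer, markers in marker_sets.items()})
    ranked = np.sort(scores.to_numpy(), axis=1)
    top, second = ranked[:, -1], ranked[:, -2]
    labels = scores.idxmax(axis=1).where(top - second >= margin, "unassigned")
    return LayerAssignment(labels=labels.rename("layer"), scores=scores,
                           margin=margin)


# ---------------------------------------------------------------------------
# gradients and contrasts
# ---------------------------------------------------------------------------

@dataclass
class GradientResult:
    """One gene's expression profile across the ordered epidermal layers."""

    gene: str
    layer_means: pd.Series
    F: float
    p: float
    direction: str  # increasing / decreasing / non-monotone


def gradient_anova(expression: pd.Series, labels: pd.Series,
                   order: tuple[str, ...] = LAYER_ORDER,
                   gene: str = "", tol: float = 1e-9) -> GradientResult:
    """One-way ANOVA of one gene across layers with a direction call.

    Direction compares the ordered layer means over ``order``
    (basal -> spinous -> granular): strictly increasing or decreasing
    within ``tol``, else non-monotone.
    """
    labels = labels[labels.isin(order)]
    res = anova_genotype(expression, labels, gene=gene)
    means = expression.loc[labels.index].groupby(labels).mean().reindex(list(order))
    diffs = np.diff(means.to_numpy())
    if np.all(diffs > tol):
        direction = "increasing"
    elif np.all(diffs < -tol):
        direction = "decreasing"
    else:
        direction = "non-monotone"
    return GradientResult(gene=gene, layer_means=means, F=res.F, p=res.p,
                          direction=direction)


@dataclass
class HighLowContrast:
    """Welch t contrast of gene B between high and low expressors of gene A."""

    groups: pd.Series   # high / low over A-positive cells
    t: float
    p: float
    mean_high: float
    mean_low: float


def high_low_contrast(expr_a: pd.Series, expr_b: pd.Series) -> HighLowContrast:
    """Split A-positive cells at the median of positive A (ties to low),
    then Welch two-sample t on B between the halves.

    Cells with zero A expression are excluded — the dichotomy is among
    expressors only.
    """
    common = expr_a.index.intersection(expr_b.index)
    a = expr_a.loc[common]
    positive = a[a > 0]
    if len(positive) < 4:
        raise InputError("need >= 4 cells expressing gene A")
    cut = positive.median()
    groups = pd.Series(np.where(positive > cut, "high", "low"),
                       index=positive.index, name="group")
    n_high, n_low = (groups == "high").sum(), (groups == "low").sum()
    if n_high < 2 or n_low < 2:
        raise ContrastError(
            f"high/low split degenerate: {n_high} high vs {n_low} low")
    b_high = expr_b.loc[groups.index[groups == "high"]].to_numpy(dtype=float)
    b_low = expr_b.loc[groups.index[groups == "low"]].to_numpy(dtype=float)
    if np.ptp(b_high) == 0 and np.ptp(b_low) == 0 and b_high.mean() == b_low.mean():
        return HighLowContrast(groups, 0.0, 1.0, float(b_high.mean()),
                               float(b_low.mean()))
    t, p = ttest_ind(b_high, b_low, equal_var=False)
    return HighLowContrast(groups=groups, t=float(t), p=float(p),
                           mean_high=float(b_high.mean()),
                           mean_low=float(b_low.mean()))


def run_sc_pipeline(adata, marker_sets: dict[str, list[str]] | None = None,
                    gene_a: str = "PCSK9", gene_b: str = "IL36G",
                    min_umi: int = 100, margin: float = 0.25):
    """Filter -> normalize -> assign layers -> gradients + high/low contrast.

    Returns a dict with the kept AnnData, log-normalized matrix, layer
    assignment, per-gene GradientResults for ``gene_a``/``gene_b`` and the
    high/low contrast of ``gene_b`` against ``gene_a``.
    """
    marker_sets = marker_sets or {"basal": ["DST", "KRT5"],
                                  "spinous": ["KRT10"],
                                  "granular": ["KLK7"]}
    kept = filter_droplets(adata, min_umi=min_umi)
    lognorm, factors = sc_normalize(kept)
    assignment = assign_layers(lognorm, marker_sets, margin=margin)
    gradients = {g: gradient_anova(lognorm[g], assignment.labels, gene=g)
                 for g in (gene_a, gene_b) if g in lognorm.columns}
    contrast = high_low_contrast(lognorm[gene_a], lognorm[gene_b]) \
        if gene_a in lognorm.columns and gene_b in lognorm.columns else None
    return {"adata": kept, "lognorm": lognorm, "factors": factors,
            "assignment": assignment, "gradients": gradients,
            "contrast": contrast}
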