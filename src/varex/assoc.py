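"""Case/control allele-count association.

Each variant is tested by counting alternative vs reference alleles
(two per diploid sample, missing calls dropped) in cases and controls,
forming a 2x2 table.  The allelic odds ratio is the table's cross-product
ratio with a Haldane-Anscombe 0.5 correction when any cell is zero (the
correction applies to the OR and its Woolf standard error only, never to
the exact test).  Significance comes from the two-sided Fisher exact test
under the minimum-likelihood convention, with Benjamini-Hochberg
adjustment across variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import DegenerateTableError, InputError
from .io import GenotypeMatrix, PhenotypeTable


@dataclass(frozen=True)
class AlleleTable:
    """Per-variant 2x2 allele counts (alt/ref x case/control).

    Raw tables are integral; cells become real-valued only after the
    continuity correction inside :func:`odds_ratio`.
    """

    alt_case: float
    ref_case: float
    alt_control: float
    ref_control: float

    def __post_init__(self) -> None:
        cells = (self.alt_case, self.ref_case, self.alt_control, self.ref_control)
        if any(c < 0 for c in cells):
            raise InputError(f"negative allele count in {cells}")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.alt_case, self.ref_case, self.alt_control, self.ref_control)


def count_alleles(dosages: pd.Series, phenotype: PhenotypeTable) -> AlleleTable:
    """Build the allele-count 2x2 table for one variant.

    ``dosages`` is indexed by sample id with NaN for missing calls; the
    alternative-allele count in a group is the dosage sum and the
    reference count is 2 * n_called - alt.  Missing calls shrink the
    allele denominator (no imputation).
    """
    status = phenotype.status_for(list(dosages.index))
    out = {}
    for label in ("case", "control"):
        d = dosages[status.to_numpy() == label]
        d = d.dropna()
        if len(d) == 0:
            raise DegenerateTableError(f"no called samples in {label} group")
        alt = float(d.sum())
        out[label] = (alt, 2.0 * len(d) - alt)
    return AlleleTable(out["case"][0], out["case"][1], out["control"][0], out["control"][1])


def odds_ratio(table: AlleleTable) -> tuple[float, float, float]:
    """Allelic odds ratio with Woolf standard error of its log.

    Returns ``(or_hat, log_or, se_log_or)``.  If any cell is zero, 0.5 is
    added to all four cells first (Haldane-Anscombe) so the OR stays
    finite; ``se_log_or = sqrt(sum 1/cell)`` on the possibly corrected
    cells.  A table with two empty margins has no defined OR.
    """
    a, b, c, d = table.cells
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0) \
            or (a + b == 0 and a + c == 0) or (c + d == 0 and b + d == 0):
        raise InputError("odds ratio undefined: two empty margins")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_hat = (a * d) / (b * c)
    log_or = float(np.log(or_hat))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return float(or_hat), log_or, se


def _as_int_cells(table: AlleleTable) -> tuple[int, int, int, int]:
    cells = table.cells
    rounded = tuple(round(c) for c in cells)
    if any(abs(c - r) > 1e-9 for c, r in zip(cells, rounded)):
        raise InputError(f"Fisher test requires integral cells, got {cells}")
    return rounded  # type: ignore[return-value]


def fisher_exact_two_sided(table: AlleleTable) -> float:
    """Two-sided Fisher exact p under the minimum-likelihood rule.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability is at most the observed table's (within a
    1 + 1e-7 tolerance factor).  A zero margin leaves a single attainable
    table, hence p = 1.
    """
    a, b, c, d = _as_int_cells(table)
    n1, n2, m1 = a + b, c + d, a + c
    lo, hi = max(0, m1 - n2), min(m1, n1)
    x = np.arange(lo, hi + 1)
    # hypergeometric log-pmf for X = alt_case given margins (n1, n2, m1)
    logpmf = (gammaln(n1 + 1) - gammaln(x + 1) - gammaln(n1 - x + 1)
              + gammaln(n2 + 1) - gammaln(m1 - x + 1) - gammaln(n2 - m1 + x + 1)
              - (gammaln(n1 + n2 + 1) - gammaln(m1 + 1) - gammaln(n1 + n2 - m1 + 1)))
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("p-values must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def run_association(genotypes: GenotypeMatrix, phenotype: PhenotypeTable) -> pd.DataFrame:
    """Allele-count association scan over every variant.

    Applies count_alleles -> odds_ratio -> Fisher -> BH per variant.
    Variants whose table is degenerate (a group with no called samples)
    are reported with null statistics and excluded from the BH family.
    """
    shared = [s for s in genotypes.samples
              if s in set(phenotype.frame["sample_id"])]
    pheno_sub = PhenotypeTable(
        phenotype.frame[phenotype.frame["sample_id"].isin(shared)].copy())
    if len(pheno_sub.case_ids) < 2 or len(pheno_sub.control_ids) < 2:
        raise InputError("need >= 2 overlapping samples per group")
    gm = genotypes.subset_samples(shared)
    dos = gm.dosage_float()
    rows = []
    for j, v in enumerate(gm.variants):
        d = pd.Series(dos[:, j], index=gm.samples)
        try:
            t = count_alleles(d, pheno_sub)
            or_hat, log_or, se = odds_ratio(t)
            p = fisher_exact_two_sided(t)
            rows.append((v.id, *t.cells, or_hat, log_or, se, p))
        except InputError:
            rows.append((v.id, *(np.nan,) * 8))
    out = pd.DataFrame(rows, columns=[
        "variant", "alt_case", "ref_case", "alt_control", "ref_control",
        "or_hat", "log_or", "se_log_or", "p"])
    out["p_adj"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out
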