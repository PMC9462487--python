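"""Composite linkage disequilibrium and cross-panel concordance.

LD is estimated as the Pearson correlation of unphased allele dosages
(composite LD): phase is unavailable both from RNA-Seq genotype calls and
from unphased reference panels, and for random-union-of-gametes
populations the dosage correlation estimates the haplotype-level r.
Missingness is handled pairwise-complete with a minimum-pair floor.

Concordance of an RNA-derived LD matrix against a reference-panel
("gold standard") matrix is scored on the shared variants' upper
triangles: Pearson r between the r vectors and the mean absolute
difference of r^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .io import GenotypeMatrix


@dataclass
class LDMatrix:
    """Symmetric dosage-correlation matrix with per-entry pair counts.

    Monomorphic variants and entries supported by fewer than ``min_pairs``
    samples are missing (NaN), including a monomorphic variant's diagonal
    (0/0 correlation is undefined).
    """

    ids: list[str]
    r: pd.DataFrame
    n_pairs: pd.DataFrame

    @property
    def r2(self) -> pd.DataFrame:
        return self.r ** 2


def ld_matrix(genotypes: GenotypeMatrix, min_pairs: int = 10) -> LDMatrix:
    """Pairwise composite LD over samples non-missing at both variants."""
    if len(genotypes.variants) < 2:
        raise InputError("need >= 2 variants for an LD matrix")
    ids = genotypes.variant_ids
    if len(set(ids)) != len(ids):
        raise InputError("duplicate variant ids")
    df = pd.DataFrame(genotypes.dosage_float(), columns=ids)
    called = df.notna().astype(float)
    n_pairs = pd.DataFrame(called.T.to_numpy() @ called.to_numpy(),
                           index=ids, columns=ids).astype(int)
    r = df.corr(min_periods=max(min_pairs, 2))
    r[n_pairs < min_pairs] = np.nan
    # pandas pins the diagonal at 1 even for zero-variance columns; a
    # monomorphic variant has no defined correlation with anything,
    # itself included.
    mono = df.std(ddof=0) == 0
    r.loc[mono, :] = np.nan
    r.loc[:, mono] = np.nan
    return LDMatrix(ids=ids, r=r, n_pairs=n_pairs)


@dataclass
class ConcordanceReport:
    """Agreement of two LD matrices on their shared variants."""

    shared_ids: list[str]
    pearson_r: float
    mad_r2: float
    top_discrepancies: pd.DataFrame  # id1, id2, r2_a, r2_b, abs_diff


def ld_concordance(a: LDMatrix, b: LDMatrix, n_top: int = 10) -> ConcordanceReport:
    """Score matrix ``a`` (e.g. RNA-derived) against matrix ``b`` (panel)."""
    shared = [i for i in a.ids if i in set(b.ids)]
    if len(shared) < 3:
        raise InputError(f"need >= 3 shared variants, got {len(shared)}")
    ra = a.r.loc[shared, shared].to_numpy()
    rb = b.r.loc[shared, shared].to_numpy()
    iu = np.triu_indices(len(shared), k=1)
    va, vb = ra[iu], rb[iu]
    ok = np.isfinite(va) & np.isfinite(vb)
    if ok.sum() < 3:
        raise InputError("fewer than 3 jointly non-missing LD entries")
    va, vb = va[ok], vb[ok]
    if np.std(va) == 0 or np.std(vb) == 0:
        pearson_r = np.nan
    else:
        pearson_r = float(np.corrcoef(va, vb)[0, 1])
    diff = np.abs(va ** 2 - vb ** 2)
    pairs = pd.DataFrame({
        "id1": np.asarray(shared)[iu[0][ok]],
        "id2": np.asarray(shared)[iu[1][ok]],
        "r2_a": va ** 2,
        "r2_b": vb ** 2,
        "abs_diff": diff,
    }).sort_values("abs_diff", ascending=False, kind="mergesort").head(n_top)
    return ConcordanceReport(shared_ids=shared, pearson_r=pearson_r,
                             mad_r2=float(diff.mean()),
                             top_discrepancies=pairs.reset_index(drop=True))


def ld_long_table(ldm: LDMatrix) -> pd.DataFrame:
    """Long-format (id1, id2, r, r2, n) table of the upper triangle."""
    rows = []
    for i in range(len(ldm.ids)):
        for j in range(i + 1, len(ldm.ids)):
            rij = ldm.r.iat[i, j]
            rows.append((ldm.ids[i], ldm.ids[j], rij,
                         rij ** 2 if np.isfinite(rij) else np.nan,
                         int(ldm.n_pairs.iat[i, j])))
    return pd.DataFrame(rows, columns=["id1", "id2", "r", "r2", "n"])
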