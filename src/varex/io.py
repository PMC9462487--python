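"""Readers, writers and shared tabular containers.

The toolkit consumes genotype calls as a VCF 4.2 subset (biallelic records
with a GT FORMAT field), case/control phenotypes and gene x sample count
matrices as TSV, and cell x gene count matrices as MatrixMarket triplets
with barcode/gene sidecar files.  Dosage counts alternative alleles
(0 = REF-HOMO, 1 = HET, 2 = ALT-HOMO); missing calls stay missing and are
excluded from every downstream count rather than imputed.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, FormatError, InputError

#: Integer code for a missing genotype call inside ``GenotypeMatrix.dosage``.
MISSING = -1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """A biallelic variant: REF is the genome-build base, ALT the variant base.

    Positions are 1-based as in VCF.  Multi-allelic sites are rejected on
    read so that dosage 0/1/2 has a single unambiguous meaning (the count
    of alternative alleles, e.g. rs662145-T on a rs662145 C > T site).
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant {self.id}: position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(f"variant {self.id}: REF and ALT are identical ({self.ref})")


class GenotypeMatrix:
    """Samples x variants allele-dosage calls over {0, 1, 2, missing}."""

    def __init__(self, samples: Sequence[str], variants: Sequence[VariantRecord],
                 dosage: np.ndarray):
        dosage = np.asarray(dosage, dtype=np.int16)
        if dosage.shape != (len(samples), len(variants)):
            raise InputError(
                f"dosage shape {dosage.shape} inconsistent with "
                f"{len(samples)} samples x {len(variants)} variants")
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise InputError(f"dosage contains values outside {{0,1,2,missing}}: "
                             f"{np.unique(dosage[bad])}")
        if len(set(samples)) != len(samples):
            raise InputError("duplicate sample identifiers")
        self.samples = list(samples)
        self.variants = list(variants)
        self.dosage = dosage

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with NaN for missing calls."""
        out = self.dosage.astype(float)
        out[self.dosage == MISSING] = np.nan
        return out

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise InputError(f"variant {variant_id!r} not present") from None

    def dosage_for(self, variant_id: str) -> pd.Series:
        """Per-sample dosage at one variant (NaN = missing)."""
        j = self.variant_index(variant_id)
        return pd.Series(self.dosage_float()[:, j], index=self.samples, name=variant_id)

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return GenotypeMatrix(list(keep), self.variants, self.dosage[idx])

    def __repr__(self) -> str:  # pragma: no cover
        return (f"GenotypeMatrix({len(self.samples)} samples x "
                f"{len(self.variants)} variants)")


@dataclass
class PhenotypeTable:
    """Case/control labels with a study label for meta-analysis grouping."""

    frame: pd.DataFrame  # columns: sample_id, status, dataset

    def __post_init__(self) -> None:
        required = {"sample_id", "status", "dataset"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataError(f"phenotype table missing columns: {sorted(missing)}")
        if self.frame["sample_id"].duplicated().any():
            raise DataError("duplicate sample ids in phenotype table")
        bad = set(self.frame["status"]) - {"case", "control"}
        if bad:
            raise DataError(f"status must be case/control, got {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def case_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["status"] == "case", "sample_id"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.frame.loc[self.frame["status"] == "control", "sample_id"])

    def status_for(self, samples: Sequence[str]) -> pd.Series:
        s = self.frame.set_index("sample_id")["status"]
        missing = [x for x in samples if x not in s.index]
        if missing:
            raise InputError(f"samples without phenotype: {missing[:5]}")
        return s.loc[list(samples)]


@dataclass
class CountsMatrix:
    """Raw gene x sample counts (nonnegative integers, unique gene symbols)."""

    genes: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise DataError("counts shape inconsistent with gene/sample lists")
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene symbols")
        if np.any(self.counts < 0):
            raise DataError("negative counts")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise DataError("counts must be integral")
        self.counts = np.round(self.counts).astype(np.int64)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountsMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def subset_samples(self, keep: Sequence[str]) -> "CountsMatrix":
        return CountsMatrix.from_frame(self.to_frame()[list(keep)])


@dataclass
class AnalysisConfig:
    """Plumbing knobs for the downstream stages (thresholds, markers, seeds)."""

    snp_id: str = "rs662145"
    contrast: tuple[str, str] = ("HET", "ALT-HOMO")
    fdr: float = 0.05
    fc: float = 2.0
    winsor_frac: float = 0.05
    perplexity: float = 30.0
    seed: int = 0
    min_umi: int = 100
    min_pairs: int = 10
    marker_sets: dict = field(default_factory=lambda: {
        "basal": ["DST", "KRT5"],
        "spinous": ["KRT10"],
        "granular": ["KLK7"],
    })

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr < 1.0):
            raise ConfigError(f"fdr must be in (0,1), got {self.fdr}")
        if self.fc <= 1.0:
            raise ConfigError(f"fc must exceed 1, got {self.fc}")
        if not (0.0 <= self.winsor_frac <= 0.25):
            raise ConfigError(f"winsor_frac must be in [0, 0.25], got {self.winsor_frac}")
        if self.perplexity <= 0:
            raise ConfigError("perplexity must be positive")
        self.contrast = tuple(self.contrast)  # type: ignore[assignment]


def load_config(path: str | os.PathLike) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**data)


# ---------------------------------------------------------------------------
# VCF subset
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a VCF 4.2 subset into a :class:`GenotypeMatrix`.

    Requires a GT FORMAT field; all other FORMAT keys are ignored.
    Multi-allelic ALT rows are rejected (the downstream analyses are
    single-SNP biallelic and splitting would create allele-coding
    ambiguity).  ``./.`` becomes a missing dosage; phase separators are
    ignored.
    """
    import pysam

    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        if "GT" not in vf.header.formats:
            raise FormatError("VCF has no GT FORMAT field")
        samples = list(vf.header.samples)
        variants: list[VariantRecord] = []
        rows: list[list[int]] = []
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                raise FormatError(
                    f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos} "
                    f"({rec.id or '.'}): ALT={alts}; only biallelic records are supported")
            vid = rec.id or f"{rec.chrom}:{rec.pos}"
            variants.append(VariantRecord(rec.chrom, rec.pos, vid, rec.ref, alts[0]))
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row.append(MISSING)
                    continue
                if len(gt) != 2:
                    raise FormatError(f"non-diploid GT at {vid} sample {s}: {gt}")
                row.append(sum(1 for a in gt if a == 1))
            rows.append(row)
    dosage = (np.array(rows, dtype=np.int16).T if rows
              else np.empty((len(samples), 0), dtype=np.int16))
    return GenotypeMatrix(samples, variants, dosage)


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in gm.variants):
        header.contigs.add(chrom)
    header.formats.add("GT", 1, "String", "Genotype")
    for s in gm.samples:
        header.add_sample(s)
    gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for j, v in enumerate(gm.variants):
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt), id=v.id)
            for i, s in enumerate(gm.samples):
                rec.samples[s]["GT"] = gt_of[int(gm.dosage[i, j])]
            out.write(rec)


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

def parse_counts_tsv(path: str | os.PathLike) -> CountsMatrix:
    """Parse a gene x sample TSV (first column gene symbols, header sample ids)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty counts file: {path}") from exc
    if frame.empty and frame.shape[1] == 0:
        raise DataError(f"counts file has no samples: {path}")
    vals = frame.apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        bad = frame.where(vals.isna()).stack()
        raise DataError(f"non-numeric count value(s), e.g. {bad.iloc[0]!r}")
    return CountsMatrix(list(frame.index.astype(str)), list(frame.columns.astype(str)),
                        vals.to_numpy())


def write_counts_tsv(counts: CountsMatrix, path: str | os.PathLike) -> None:
    counts.to_frame().to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


def read_phenotype_tsv(path: str | os.PathLike) -> PhenotypeTable:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"empty phenotype file: {path}") from exc
    return PhenotypeTable(frame)


def write_phenotype_tsv(pheno: PhenotypeTable, path: str | os.PathLike) -> None:
    pheno.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _sanitize(value):
    if value is None:
        return None
    if isinstance(value, (np.floating, float)):
        return None if math.isnan(value) else float(value)
    if isinstance(value, np.integer):
        return int(value)
    if isinstance(value, np.bool_):
        return bool(value)
    return value


def write_results(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table deterministically.

    ``.json`` paths get a record-oriented JSON document with NaN p-values
    serialized as ``null``; anything else gets a TSV with ``NA`` for
    missing cells.  Identical input always produces identical bytes.
    """
    path = os.fspath(path)
    if path.endswith(".json"):
        records = [
            {k: _sanitize(v) for k, v in row.items()}
            for row in table.to_dict(orient="records")
        ]
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2, allow_nan=False)
            fh.write("\n")
    else:
        table.to_csv(path, sep="\t", index=False, na_rep="NA",
                     lineterminator="\n", float_format="%.10g")


# ---------------------------------------------------------------------------
# cell matrices (MatrixMarket triplet + sidecars)
# ---------------------------------------------------------------------------

def read_cell_matrix(matrix_path: str | os.PathLike,
                     barcodes_path: str | os.PathLike | None = None,
                     genes_path: str | os.PathLike | None = None):
    """Read a cell x gene count matrix into an AnnData object.

    ``matrix_path`` may be a MatrixMarket ``.mtx`` triplet (cells as rows,
    with ``barcodes.tsv``/``genes.tsv`` sidecars, paths inferred from the
    matrix path when not given) or a dense TSV with barcodes in the first
    column and gene symbols in the header.
    """
    import anndata as ad
    import scipy.io
    import scipy.sparse as sp

    matrix_path = os.fspath(matrix_path)
    if matrix_path.endswith(".mtx"):
        base = os.path.dirname(matrix_path)
        barcodes_path = barcodes_path or os.path.join(base, "barcodes.tsv")
        genes_path = genes_path or os.path.join(base, "genes.tsv")
        mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
        barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
        if mat.shape != (len(barcodes), len(genes)):
            raise DataError(f"matrix shape {mat.shape} inconsistent with "
                            f"{len(barcodes)} barcodes x {len(genes)} genes")
    else:
        frame = pd.read_csv(matrix_path, sep="\t", index_col=0)
        mat = sp.csr_matrix(frame.to_numpy())
        barcodes = frame.index.astype(str)
        genes = frame.columns.astype(str)
    if (mat.data < 0).any():
        raise DataError("negative cell counts")
    adata = ad.AnnData(X=mat)
    adata.obs_names = list(barcodes)
    adata.var_names = list(genes)
    return adata


def write_cell_matrix(adata, out_dir: str | os.PathLike) -> None:
    """Write an AnnData cell matrix as matrix.mtx + barcodes.tsv + genes.tsv."""
    import scipy.io
    import scipy.sparse as sp

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    mat = sp.coo_matrix(adata.X)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), mat, field="integer")
    pd.Series(adata.obs_names).to_csv(os.path.join(out_dir, "barcodes.tsv"),
                                      sep="\t", index=False, header=False)
    pd.Series(adata.var_names).to_csv(os.path.join(out_dir, "genes.tsv"),
                                      sep="\t", index=False, header=False)
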