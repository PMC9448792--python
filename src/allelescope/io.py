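"""Readers and writers for the external formats and the canonical in-memory model.

All genomic intervals are held 0-based half-open internally.  VCF positions
(1-based) are shifted at the boundary; BED-like inputs (fragments, peaks,
genes, region sets) are already 0-based half-open and pass through unchanged.

Tabular data are pandas DataFrames with fixed column schemas (see the
``*_COLUMNS`` constants); the small record dataclasses below exist for
record-level work and documentation of invariants.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "support"]
VARIANT_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele",
    "hap_of_alt", "fs", "qd", "is_het", "is_phased",
]
PEAK_COLUMNS = ["chrom", "start", "end", "peak_id"]
META_COLUMNS = ["barcode", "sample_id", "cell_type", "condition"]
BASEOBS_COLUMNS = ["chrom", "start", "end", "barcode", "pos", "base", "qual"]

CONDITIONS = ("control", "disease")


@dataclasses.dataclass(frozen=True)
class Fragment:
    """One accessible-chromatin fragment with its cell barcode.

    ``support`` is the read-pair count backing the fragment; the fragment, not
    the read, is the observation unit everywhere downstream.
    """

    chrom: str
    start: int
    end: int
    barcode: str
    support: int = 1

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"fragment start must be < end: {self}")
        if self.support < 1:
            raise ValueError(f"fragment support must be >= 1: {self}")


@dataclasses.dataclass(frozen=True)
class PhasedVariant:
    """A biallelic SNV with optional phase. ``pos`` is 0-based.

    ``hap_of_alt`` is the haplotype index (0 or 1) carrying the alternate
    allele, defined only when ``is_phased``; -1 otherwise.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    hap_of_alt: int = -1
    fs: float = float("nan")
    qd: float = float("nan")
    is_het: bool = True
    is_phased: bool = True

    def __post_init__(self):
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-base SNVs are modelled")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt allele must differ")
        if self.is_phased and self.hap_of_alt not in (0, 1):
            raise ValueError("phased variant needs hap_of_alt in {0, 1}")


@dataclasses.dataclass
class ReadStats:
    """Per-reader QC counters."""

    n_read: int = 0
    n_kept: int = 0
    n_rejected_invalid_interval: int = 0
    n_skipped_non_snv: int = 0
    n_skipped_multiallelic: int = 0
    n_skipped_missing_gt: int = 0


class ExpressionMatrix:
    """Cells x genes matrix of nonnegative imputed expression.

    Wraps a CSR sparse matrix with barcode and gene indices; values are
    addressable by ``(barcode, gene)`` labels.
    """

    def __init__(self, matrix, barcodes: Iterable[str], genes: Iterable[str]):
        matrix = scipy.sparse.csr_matrix(matrix)
        self.barcodes = pd.Index(barcodes, name="barcode")
        self.genes = pd.Index(genes, name="gene")
        if matrix.shape != (len(self.barcodes), len(self.genes)):
            raise ValueError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        if matrix.nnz and matrix.min() < 0:
            raise ValueError("expression values must be nonnegative")
        self.matrix = matrix

    @property
    def shape(self):
        return self.matrix.shape

    def value(self, barcode: str, gene: str) -> float:
        i = self.barcodes.get_loc(barcode)
        j = self.genes.get_loc(gene)
        return float(self.matrix[i, j])

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense per-cell vector for one gene, in barcode order."""
        j = self.genes.get_loc(gene)
        return np.asarray(self.matrix[:, j].todense()).ravel()

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.barcodes, columns=self.genes
        )

    def subset_barcodes(self, barcodes: Iterable[str]) -> "ExpressionMatrix":
        idx = self.barcodes.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            missing = pd.Index(barcodes)[idx < 0][:3].tolist()
            raise KeyError(f"barcodes absent from expression matrix: {missing}")
        return ExpressionMatrix(self.matrix[idx], pd.Index(barcodes), self.genes)


# ---------------------------------------------------------------------------
# fragments


def read_fragments(path, *, return_stats: bool = False) -> pd.DataFrame:
    """Read a 10x-style fragments file (TSV, >=5 columns, '#' comments).

    Returns a DataFrame with :data:`FRAGMENT_COLUMNS`, sorted by
    (chrom, start, end, barcode).  Records with start >= end are rejected and
    counted in the returned stats.  Malformed lines raise ``ValueError``
    naming the offending line number.
    """
    stats = ReadStats()
    try:
        raw = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        empty = _empty_fragments()
        return (empty, stats) if return_stats else empty
    if raw.shape[1] < 5:
        raise ValueError(
            f"{path}: fragments file needs >=5 tab-separated columns, "
            f"found {raw.shape[1]}"
        )
    raw = raw.iloc[:, :5]
    raw.columns = FRAGMENT_COLUMNS
    stats.n_read = len(raw)

    for col in ("start", "end", "support"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (raw[col].isna())
        if bad.any():
            # data line numbers are 1-based and ignore comment lines
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(
                f"{path}: malformed {col!r} field at data line {line}"
            )
        raw[col] = vals.astype(np.int64)

    ok = (raw["start"] < raw["end"]) & (raw["support"] >= 1)
    stats.n_rejected_invalid_interval = int((~ok).sum())
    frags = raw[ok].sort_values(
        ["chrom", "start", "end", "barcode"], kind="mergesort"
    ).reset_index(drop=True)
    stats.n_kept = len(frags)
    return (frags, stats) if return_stats else frags


def _empty_fragments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "barcode": pd.Series(dtype=str),
            "support": pd.Series(dtype=np.int64),
        }
    )


def write_fragments(frags: pd.DataFrame, path) -> None:
    frags[FRAGMENT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# VCF


def read_phased_vcf(path, *, sample: int = 0, return_stats: bool = False) -> pd.DataFrame:
    """Read biallelic SNVs from a VCF into a variant table.

    Positions are converted from the VCF's 1-based convention to 0-based.
    ``is_phased`` reflects the '|' separator; ``hap_of_alt`` is the GT slot
    holding the alternate allele ("0|1" -> 1, "1|0" -> 0), or -1 when the
    record is unphased or homozygous.  Indels and multiallelic records are
    skipped and counted; records with a missing genotype are skipped with a
    warning count.
    """
    from cyvcf2 import VCF

    stats = ReadStats()
    rows = []
    vcf = VCF(os.fspath(path), gts012=False)
    for v in vcf:
        stats.n_read += 1
        if len(v.ALT) != 1:
            stats.n_skipped_multiallelic += 1
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            stats.n_skipped_non_snv += 1
            continue
        gt = v.genotypes[sample]
        a0, a1, phased = int(gt[0]), int(gt[1]), bool(gt[2])
        if a0 < 0 or a1 < 0:
            stats.n_skipped_missing_gt += 1
            continue
        is_het = a0 != a1
        hap_of_alt = -1
        if phased and is_het:
            hap_of_alt = 0 if a0 == 1 else 1
        fs = v.INFO.get("FS")
        qd = v.INFO.get("QD")
        rows.append(
            (
                v.CHROM, v.POS - 1, v.REF, v.ALT[0], hap_of_alt,
                np.nan if fs is None else float(fs),
                np.nan if qd is None else float(qd),
                is_het, phased and is_het,
            )
        )
        stats.n_kept += 1
    vcf.close()
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    if df.empty:
        df = _empty_variants()
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return (df, stats) if return_stats else df


def _empty_variants() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "ref_allele": pd.Series(dtype=str),
            "alt_allele": pd.Series(dtype=str),
            "hap_of_alt": pd.Series(dtype=np.int64),
            "fs": pd.Series(dtype=float),
            "qd": pd.Series(dtype=float),
            "is_het": pd.Series(dtype=bool),
            "is_phased": pd.Series(dtype=bool),
        }
    )


def write_phased_vcf(variants: pd.DataFrame, path, *, sample_name: str = "sample") -> None:
    """Write a variant table as a single-sample VCF (0-based pos -> 1-based)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">')
    header.add_line('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in pd.unique(variants["chrom"]):
        sub = variants[variants["chrom"] == chrom]
        header.contigs.add(str(chrom), length=int(sub["pos"].max()) + 1000)
    header.add_sample(sample_name)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for row in variants.itertuples(index=False):
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos),
                alleles=(row.ref_allele, row.alt_allele),
            )
            if np.isfinite(row.fs):
                rec.info["FS"] = float(row.fs)
            if np.isfinite(row.qd):
                rec.info["QD"] = float(row.qd)
            if not row.is_het:
                gt = (1, 1)
            elif row.is_phased:
                gt = (1, 0) if row.hap_of_alt == 0 else (0, 1)
            else:
                gt = (0, 1)
            rec.samples[sample_name]["GT"] = gt
            rec.samples[sample_name].phased = bool(row.is_phased or not row.is_het)
            out.write(rec)


# ---------------------------------------------------------------------------
# BED-like tables


def read_bed(path, *, extra_names: tuple = ("name", "score", "strand")) -> pd.DataFrame:
    """Read a BED3+ file; columns beyond chrom/start/end take ``extra_names``."""
    try:
        raw = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end", *extra_names[:1]])
    ncol = raw.shape[1]
    names = ["chrom", "start", "end", *extra_names[: max(0, ncol - 3)]]
    raw = raw.iloc[:, : len(names)]
    raw.columns = names
    raw["start"] = raw["start"].astype(np.int64)
    raw["end"] = raw["end"].astype(np.int64)
    if (raw["start"] >= raw["end"]).any():
        bad = int((raw["start"] >= raw["end"]).sum())
        raise ValueError(f"{path}: {bad} intervals with start >= end")
    return raw


def read_peaks(path) -> pd.DataFrame:
    """Peaks BED; the 4th column (or a generated one) is ``peak_id``."""
    df = read_bed(path, extra_names=("peak_id",))
    if "peak_id" not in df.columns:
        df["peak_id"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ]
    return df[PEAK_COLUMNS]


def read_genes(path) -> pd.DataFrame:
    """Gene coordinates BED6 (name in col 4, strand in col 6); strand required."""
    df = read_bed(path, extra_names=("gene_id", "score", "strand"))
    if "strand" not in df.columns:
        raise ValueError(f"{path}: gene BED needs a strand column (BED6)")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: strand must be '+' or '-'")
    return df[["chrom", "start", "end", "gene_id", "strand"]]


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# metadata, base observations, expression


def read_cell_meta(path) -> pd.DataFrame:
    """Cell metadata TSV with header: barcode, sample_id, cell_type, condition."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if meta["barcode"].duplicated().any():
        raise ValueError(f"{path}: duplicate barcodes in cell metadata")
    bad = set(meta["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(
            f"{path}: condition must be one of {CONDITIONS}, found {sorted(bad)}"
        )
    return meta[META_COLUMNS]


def read_base_observations(path) -> pd.DataFrame:
    """Per-fragment base observations at variant positions (TSV sidecar).

    Columns: chrom, start, end, barcode (the fragment key), pos (0-based
    variant position), base, qual.  This is the adapter point for
    BAM-derived allele counts.
    """
    obs = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "barcode": str, "base": str},
    )
    missing = set(BASEOBS_COLUMNS) - set(obs.columns)
    if missing:
        raise ValueError(f"{path}: missing observation columns {sorted(missing)}")
    for col in ("start", "end", "pos"):
        obs[col] = obs[col].astype(np.int64)
    obs["qual"] = obs["qual"].astype(float)
    inside = (obs["pos"] >= obs["start"]) & (obs["pos"] < obs["end"])
    if not inside.all():
        raise ValueError(
            f"{path}: {int((~inside).sum())} observations outside their fragment"
        )
    return obs[BASEOBS_COLUMNS]


def read_expression(mtx_path, barcodes_path, features_path) -> ExpressionMatrix:
    """Read a MatrixMarket expression matrix with barcode/feature sidecars.

    The MTX is stored features x barcodes (10x dialect) and returned as
    cells x genes.
    """
    mat = scipy.io.mmread(os.fspath(mtx_path))
    barcodes = pd.read_csv(barcodes_path, header=None, dtype=str)[0].tolist()
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)[0].tolist()
    if mat.shape != (len(features), len(barcodes)):
        raise ValueError(
            f"MTX shape {mat.shape} inconsistent with {len(features)} features "
            f"x {len(barcodes)} barcodes"
        )
    return ExpressionMatrix(mat.T.tocsr(), barcodes, features)


def write_expression(expr: ExpressionMatrix, mtx_path, barcodes_path, features_path) -> None:
    scipy.io.mmwrite(os.fspath(mtx_path), expr.matrix.T.tocoo())
    pd.Series(expr.barcodes).to_csv(barcodes_path, header=False, index=False)
    pd.Series(expr.genes).to_csv(features_path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# results tables

RESULTS_FLOAT_FORMAT = "%.6g"


def write_results_table(records, path) -> None:
    """Write a homogeneous record collection as a TSV with a header row.

    Floats are written at 6 significant digits; :func:`read_results_table`
    round-trips losslessly at that precision.  Accepts a DataFrame or an
    iterable of dataclasses / dicts.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and dataclasses.is_dataclass(records[0]):
            records = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame.from_records(records)
    df.to_csv(path, sep="\t", index=False, float_format=RESULTS_FLOAT_FORMAT)


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
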