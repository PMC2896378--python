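"""Readers, writers and core value types for the cis/trans attribution pipeline.

All tabular data moves through pandas DataFrames with documented schemas.
Genomic coordinates are 0-based, half-open ``[start, end)`` everywhere inside
the package; conversion from the 1-based conventions of the on-disk formats
(SNP tables, GFF-style TSS columns) happens only in the readers and writers
in this module.

Schemas
-------
SNP table
    columns ``chromosome`` (str), ``position`` (int, 0-based) plus one
    single-character allele column per strain (``A/C/G/T`` or ``N`` for
    missing).  Rows sorted by (chromosome, position), no duplicates.
gene table
    columns ``gene_id``, ``chromosome``, ``start``, ``end``, ``strand``
    (``+``/``-``) and ``tss`` (0-based position of the transcription start:
    ``start`` on the plus strand, ``end - 1`` on the minus strand).
block table
    columns ``block_id``, ``chromosome``, ``start``, ``end`` (BED-dialect
    intervals; non-overlapping within a chromosome).
probe table
    columns ``gene_id``, ``chromosome``, ``start``, ``end`` — one row per
    25-mer probe interval.
expression table
    column ``gene_id`` plus one ``rep_<i>`` column per replicate of log2
    expression values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cistrans")

VALID_ALLELES = frozenset("ACGTN")

SNP_FIXED_COLUMNS = ("chromosome", "position")
GENE_COLUMNS = ("gene_id", "chromosome", "start", "end", "strand", "tss")
BLOCK_COLUMNS = ("block_id", "chromosome", "start", "end")
PROBE_COLUMNS = ("gene_id", "chromosome", "start", "end")


class FormatError(ValueError):
    """Raised when an input file violates its documented schema."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if not self.start < self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chromosome: str, position: int) -> bool:
        """True if a single position falls inside the interval."""
        return chromosome == self.chromosome and self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AnalysisConfig:
    """Thresholds and scan parameters shared by all analysis stages.

    Parameters
    ----------
    pplr_strict, pplr_loose
        pplr cut-offs for the stringent and relaxed differential-expression
        calls.  ``pplr = min(PPLR, 1 - PPLR)`` so both live in (0, 0.5].
    lfc_threshold
        Minimum absolute log2 fold change for a differential-expression call
        (strict inequality).
    upstream_window
        Length in bp of the promoter-proximal window upstream of the TSS in
        which SNPs are counted and haplotype is assessed.
    haplotype_distance_threshold
        Jukes-Cantor distance (substitutions/site) below which a strain is
        assigned the same haplotype allele as the reference strain.
    n_percentiles, max_snp_threshold
        Shape of the pplr-percentile x SNP-count association scan; the
        Bonferroni family size is their product.
    min_expected
        Minimum expected cell count for a 2x2 chi-square in the scan to be
        considered testable (Cochran-style validity guard).
    alpha
        Family-wise significance level for the scan.
    """

    pplr_strict: float = 0.005
    pplr_loose: float = 0.05
    lfc_threshold: float = 0.5
    upstream_window: int = 1000
    haplotype_distance_threshold: float = 0.2
    n_percentiles: int = 100
    max_snp_threshold: int = 10
    min_expected: float = 5.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pplr_strict", "pplr_loose", "alpha"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name}={value} must lie in (0, 1)")
        if not self.pplr_strict < self.pplr_loose:
            raise ValueError("pplr_strict must be below pplr_loose")
        if self.upstream_window <= 0:
            raise ValueError("upstream_window must be positive")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be non-negative")
        if self.haplotype_distance_threshold <= 0:
            raise ValueError("haplotype_distance_threshold must be positive")
        if self.n_percentiles < 1 or self.max_snp_threshold < 1:
            raise ValueError("scan dimensions must be at least 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise FormatError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# SNP tables
# ---------------------------------------------------------------------------

def read_snp_table(path: str | Path, strains: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a strain x SNP allele TSV into the internal SNP-table schema.

    The file stores 1-based positions; they are shifted to 0-based on read.
    ``strains`` restricts/validates the allele columns; by default every
    column beyond ``chromosome``/``position`` is taken as a strain.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in SNP_FIXED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    allele_cols = [c for c in df.columns if c not in SNP_FIXED_COLUMNS]
    if strains is not None:
        missing = set(strains) - set(allele_cols)
        if missing:
            raise FormatError(f"{path}: missing strain columns {sorted(missing)}")
        allele_cols = list(strains)
    if not allele_cols:
        raise FormatError(f"{path}: no strain allele columns")

    df = df[list(SNP_FIXED_COLUMNS) + allele_cols].copy()
    try:
        df["position"] = df["position"].astype(np.int64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer position: {exc}") from exc
    if (df["position"] < 1).any():
        row = int(df.index[df["position"] < 1][0])
        raise FormatError(f"{path}: row {row}: positions are 1-based, got < 1")
    df["position"] -= 1  # 1-based file -> 0-based internal

    for col in allele_cols:
        alleles = df[col].fillna("N").str.upper()
        bad = ~alleles.isin(list(VALID_ALLELES))
        if bad.any():
            row = int(df.index[bad][0])
            raise FormatError(
                f"{path}: row {row}: invalid allele {df[col].iloc[row]!r} "
                f"for strain {col!r}"
            )
        df[col] = alleles

    dup = df.duplicated(subset=list(SNP_FIXED_COLUMNS))
    if dup.any():
        row = int(df.index[dup][0])
        raise FormatError(f"{path}: row {row}: duplicate (chromosome, position)")
    df = df.sort_values(list(SNP_FIXED_COLUMNS), kind="mergesort").reset_index(drop=True)
    logger.info("read_snp_table: %d sites, %d strains from %s", len(df), len(allele_cols), path)
    return df


def write_snp_table(snps: pd.DataFrame, path: str | Path) -> None:
    """Write a SNP table, converting positions back to the 1-based file convention."""
    out = snps.copy()
    out["position"] = out["position"].astype(np.int64) + 1
    out.to_csv(path, sep="\t", index=False)


def snp_strains(snps: pd.DataFrame) -> list[str]:
    return [c for c in snps.columns if c not in SNP_FIXED_COLUMNS]


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def _tss_from_bed(start: np.ndarray, end: np.ndarray, strand: np.ndarray) -> np.ndarray:
    # TSS is the 5' end of the gene body: start on '+', end - 1 on '-'
    return np.where(strand == "+", start, end - 1)


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene records from BED6 or from a minimal TSV.

    BED6: ``chrom start end gene_id score strand`` without a header
    (0-based half-open, the BED convention).  Minimal TSV: header columns
    ``gene_id chromosome tss strand`` with a 1-based TSS.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
        required = {"gene_id", "chromosome", "tss", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        df["tss"] = df["tss"].astype(np.int64) - 1  # 1-based file -> 0-based
        df["start"] = df["tss"]
        df["end"] = df["tss"] + 1
    else:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype={0: str, 3: str, 5: str},
        )
        if df.shape[1] != 6:
            raise FormatError(f"{path}: expected 6 BED columns, found {df.shape[1]}")
        df.columns = ["chromosome", "start", "end", "gene_id", "score", "strand"]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["tss"] = _tss_from_bed(
            df["start"].to_numpy(), df["end"].to_numpy(), df["strand"].to_numpy()
        )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        row = int(df.index[bad][0])
        raise FormatError(f"{path}: row {row}: strand must be '+' or '-'")
    if df["gene_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate gene ids")
    df = df[list(GENE_COLUMNS)].sort_values(["chromosome", "tss"]).reset_index(drop=True)
    logger.info("read_gene_annotation: %d genes from %s", len(df), path)
    return df


def write_gene_annotation(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene records as BED6 (0-based half-open, no header)."""
    out = genes[["chromosome", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes["strand"].to_numpy()
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Interval tables (haplotype blocks, probes, congenic intervals)
# ---------------------------------------------------------------------------

def read_block_table(path: str | Path) -> pd.DataFrame:
    """Read haplotype-block intervals from BED-dialect (chrom start end block_id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str, 3: str})
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected >= 4 BED columns, found {df.shape[1]}")
    df = df.iloc[:, :4]
    df.columns = ["chromosome", "start", "end", "block_id"]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] >= df["end"]).any():
        raise FormatError(f"{path}: empty or inverted block interval")
    df = df[list(BLOCK_COLUMNS)].sort_values(["chromosome", "start"]).reset_index(drop=True)
    logger.info("read_block_table: %d blocks from %s", len(df), path)
    return df


def write_block_table(blocks: pd.DataFrame, path: str | Path) -> None:
    blocks[["chromosome", "start", "end", "block_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_probe_table(path: str | Path) -> pd.DataFrame:
    """Read per-gene probe intervals from BED-dialect (chrom start end gene_id)."""
    df = read_block_table(path).rename(columns={"block_id": "gene_id"})
    return df[list(PROBE_COLUMNS)]


def write_probe_table(probes: pd.DataFrame, path: str | Path) -> None:
    probes[["chromosome", "start", "end", "gene_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# Expression matrices and result tables
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a replicate expression matrix (gene_id + rep_* columns of log2 values)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    rep_cols = [c for c in df.columns if c.startswith("rep_")]
    if len(rep_cols) < 2:
        raise FormatError(f"{path}: need >= 2 replicate columns, found {len(rep_cols)}")
    return df[["gene_id"] + rep_cols]


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "condition_pair": str})
    required = {"gene_id", "log2_ratio", "PPLR", "pplr"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_de_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.8g")


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a basic stderr handler so 'n of m' filter counts are visible."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(level)
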