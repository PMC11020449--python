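"""Core record types: heterozygous sites and computed variant allele counts.

A CVAC table (computed variant allele counts) is the central exchange
format: one row per heterozygous X-linked site per sample, carrying the
RNA-seq reference/alternate read counts. Tables round-trip through TSV with
the fixed header ``sample_id chrom pos ref alt ref_count alt_count gene``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

__all__ = [
    "HetSite",
    "CvacRecord",
    "NO_GENE",
    "CVAC_COLUMNS",
    "read_cvac",
    "write_cvac",
    "records_to_frame",
    "frame_to_records",
]

#: Sentinel gene symbol for intergenic positions (excluded from gene models).
NO_GENE = "."

CVAC_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "gene",
]


def _allele_ok(ref: str, alt: str) -> bool:
    """SNVs and 1-bp indels only: equal-length-1, or one allele is the other
    plus a single trailing base."""
    if len(ref) == 1 and len(alt) == 1:
        return True
    d = len(ref) - len(alt)
    return abs(d) == 1 and min(len(ref), len(alt)) == 1


@dataclasses.dataclass(frozen=True)
class HetSite:
    """One exome-confirmed heterozygous site on chromosome X."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotype_quality: int
    dna_depth: int
    filter_status: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not _allele_ok(self.ref_allele, self.alt_allele):
            raise ValueError(
                f"only SNVs and 1-bp indels supported: "
                f"{self.ref_allele}>{self.alt_allele}"
            )


@dataclasses.dataclass(frozen=True)
class CvacRecord:
    """RNA allele counts at one heterozygous site in one sample."""

    sample_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int
    gene_symbol: str = NO_GENE

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele counts must be non-negative")

    @property
    def total_depth(self) -> int:
        return self.ref_count + self.alt_count


def records_to_frame(records: list[CvacRecord]) -> pd.DataFrame:
    rows = [
        (
            r.sample_id,
            r.chrom,
            r.pos,
            r.ref_allele,
            r.alt_allele,
            r.ref_count,
            r.alt_count,
            r.gene_symbol,
        )
        for r in records
    ]
    df = pd.DataFrame(rows, columns=CVAC_COLUMNS)
    df["pos"] = df["pos"].astype("int64")
    df["ref_count"] = df["ref_count"].astype("int64")
    df["alt_count"] = df["alt_count"].astype("int64")
    return df


def frame_to_records(df: pd.DataFrame) -> list[CvacRecord]:
    return [
        CvacRecord(
            sample_id=str(row.sample_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref_allele=str(row.ref),
            alt_allele=str(row.alt),
            ref_count=int(row.ref_count),
            alt_count=int(row.alt_count),
            gene_symbol=str(row.gene),
        )
        for row in df.itertuples(index=False)
    ]


def write_cvac(df: pd.DataFrame, path: str | Path) -> None:
    """Write a CVAC table as TSV with the canonical header."""
    missing = [c for c in CVAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CVAC frame missing columns: {missing}")
    df[CVAC_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cvac(path: str | Path) -> pd.DataFrame:
    """Read a CVAC TSV, validating schema and count non-negativity."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "sample_id": str,
            "chrom": str,
            "ref": str,
            "alt": str,
            "gene": str,
        },
    )
    missing = [c for c in CVAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: CVAC table missing columns {missing}")
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        raise ValueError(f"{path}: negative allele count in CVAC table")
    df["pos"] = df["pos"].astype("int64")
    df["gene"] = df["gene"].fillna(NO_GENE)
    return df[CVAC_COLUMNS]
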