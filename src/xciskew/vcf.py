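"""Heterozygous-site selection from exome VCFs.

Selection mirrors a GATK-style workflow: chromosome-X records only,
VQSR/FILTER pass, DNA depth strictly greater than the floor, genotype
quality at or above the floor, heterozygous genotypes carrying exactly one
reference and one alternate allele. Multi-allelic records are decomposed
into biallelic ref/alt pairings before evaluation, and alleles beyond SNVs
and 1-bp indels are dropped.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pysam

from .intervals import normalize_chrom
from .sites import HetSite, _allele_ok

__all__ = ["filter_het_sites", "read_het_sites"]

logger = logging.getLogger(__name__)


def _passes_filter(filter_keys: list[str], strict_missing: bool) -> bool:
    if not filter_keys:  # '.' — missing FILTER
        return not strict_missing
    return filter_keys == ["PASS"]


def filter_het_sites(
    vcf_records: Iterable[pysam.VariantRecord],
    min_dna_depth: int = 10,
    min_gq: int = 20,
    sample: str | None = None,
    strict_missing_filter: bool = False,
) -> list[HetSite]:
    """Select high-confidence heterozygous X sites from VCF records.

    Parameters
    ----------
    vcf_records : iterable of pysam.VariantRecord
    min_dna_depth : int
        Kept sites require DNA depth strictly greater than this value.
    min_gq : int
        Kept sites require genotype quality >= this value.
    sample : str, optional
        Sample to evaluate in multi-sample VCFs; defaults to the first.
    strict_missing_filter : bool
        When True, FILTER '.' is rejected instead of treated as PASS.

    Records missing GQ or DP are skipped with a warning, never a crash;
    non-X records are skipped silently.
    """
    kept: list[HetSite] = []
    for rec in vcf_records:
        if normalize_chrom(rec.chrom) != "X":
            continue
        if not _passes_filter(list(rec.filter.keys()), strict_missing_filter):
            continue
        if sample is None:
            if not rec.samples:
                logger.warning("record %s:%d has no genotypes; skipped", rec.chrom, rec.pos)
                continue
            call = rec.samples[0]
        else:
            if sample not in rec.samples:
                raise KeyError(f"sample {sample!r} absent from VCF")
            call = rec.samples[sample]

        gt = call.get("GT")
        if gt is None or any(a is None for a in gt):
            continue
        gq = call.get("GQ")
        dp = call.get("DP")
        if dp is None:
            dp = rec.info.get("DP")
        if gq is None or dp is None:
            logger.warning(
                "record %s:%d missing GQ or DP; skipped", rec.chrom, rec.pos
            )
            continue
        if dp <= min_dna_depth or gq < min_gq:
            continue

        # decompose: each alt pairing with exactly one ref + one alt call
        alts = rec.alts or ()
        for alt_index, alt in enumerate(alts, start=1):
            if sorted(gt) != [0, alt_index]:
                continue
            ref, alt_a = rec.ref, alt
            if alt_a is None or not _allele_ok(ref, alt_a):
                continue
            kept.append(
                HetSite(
                    chrom=normalize_chrom(rec.chrom),
                    pos=rec.pos,
                    ref_allele=ref,
                    alt_allele=alt_a,
                    genotype_quality=int(gq),
                    dna_depth=int(dp),
                    filter_status=tuple(rec.filter.keys()),
                )
            )
    return kept


def read_het_sites(
    vcf_path: str | Path,
    min_dna_depth: int = 10,
    min_gq: int = 20,
    sample: str | None = None,
    strict_missing_filter: bool = False,
) -> list[HetSite]:
    """Open a VCF (plain or bgzipped) and apply :func:`filter_het_sites`."""
    with pysam.VariantFile(str(vcf_path)) as vf:
        return filter_het_sites(
            vf,
            min_dna_depth=min_dna_depth,
            min_gq=min_gq,
            sample=sample,
            strict_missing_filter=strict_missing_filter,
        )
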