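"""CVAC extraction: region filters, gene annotation and the site -> count
table pipeline."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .intervals import GenomicIntervalSet, default_par_intervals, normalize_chrom
from .pileup import count_alleles_for_sites
from .sites import NO_GENE, CvacRecord, HetSite, records_to_frame
from .vcf import read_het_sites

__all__ = [
    "exclude_regions",
    "restrict_to_coding",
    "sites_to_bed",
    "annotate_genes",
    "extract_cvac",
]

logger = logging.getLogger(__name__)


def exclude_regions(
    sites: list[HetSite], regions: GenomicIntervalSet
) -> list[HetSite]:
    """Drop sites falling inside any excluded interval (e.g. the PARs)."""
    if len(regions) == 0:
        logger.warning("empty %s region set: no sites excluded", regions.role)
        return list(sites)
    kept = [s for s in sites if not regions.contains(s.chrom, s.pos)]
    removed = len(sites) - len(kept)
    logger.info("excluded %d/%d sites in %s regions", removed, len(sites), regions.role)
    if sites and not kept:
        logger.warning("all %d sites fell inside %s regions", len(sites), regions.role)
    return kept


def restrict_to_coding(
    sites: list[HetSite], coding: GenomicIntervalSet | None
) -> list[HetSite]:
    """Keep only sites overlapping a coding interval; a missing coding set
    is a documented bypass (all sites pass)."""
    if coding is None:
        logger.info("no coding interval set provided; coding restriction skipped")
        return list(sites)
    if not sites:
        logger.warning("restrict_to_coding called on an empty site list")
        return []
    return [s for s in sites if coding.contains(s.chrom, s.pos)]


def sites_to_bed(sites: list[HetSite]) -> list[str]:
    """One 0-based half-open BED line per distinct site position."""
    seen: set[tuple[str, int]] = set()
    lines: list[str] = []
    for s in sites:
        key = (normalize_chrom(s.chrom), s.pos)
        if key in seen:
            continue
        seen.add(key)
        lines.append(f"{key[0]}\t{s.pos - 1}\t{s.pos}")
    return lines


def write_sites_bed(sites: list[HetSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for line in sites_to_bed(sites):
            fh.write(line + "\n")


def annotate_genes(
    cvacs: list[CvacRecord], gene_map: GenomicIntervalSet
) -> list[CvacRecord]:
    """Attach the containing gene's symbol to each record.

    Intergenic positions get the sentinel symbol (they remain usable by the
    position and global model tiers). Overlapping genes resolve to the
    first by (start, end, name) order, logged once.
    """
    out: list[CvacRecord] = []
    overlap_noted = False
    for rec in cvacs:
        names = gene_map.names_at(rec.chrom, rec.pos)
        if len(names) > 1 and not overlap_noted:
            logger.info(
                "position %s:%d inside %d overlapping genes; using first by "
                "coordinate-then-name order",
                rec.chrom,
                rec.pos,
                len(names),
            )
            overlap_noted = True
        symbol = names[0] if names else NO_GENE
        out.append(
            CvacRecord(
                sample_id=rec.sample_id,
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref_allele,
                alt_allele=rec.alt_allele,
                ref_count=rec.ref_count,
                alt_count=rec.alt_count,
                gene_symbol=symbol,
            )
        )
    return out


def extract_cvac(
    vcf_path: str | Path,
    mpileup_lines: Iterable[str] | None = None,
    sample_id: str = "sample",
    vcf_sample: str | None = None,
    coding: GenomicIntervalSet | None = None,
    par: GenomicIntervalSet | None = None,
    gene_map: GenomicIntervalSet | None = None,
    min_dna_depth: int = 10,
    min_gq: int = 20,
    min_baseq: int = 30,
) -> pd.DataFrame:
    """Full extraction pipeline for one sample: VCF het sites -> PAR
    exclusion -> coding restriction -> pileup allele counting -> gene
    annotation. Returns a CVAC table."""
    sites = read_het_sites(
        vcf_path, min_dna_depth=min_dna_depth, min_gq=min_gq, sample=vcf_sample
    )
    sites = exclude_regions(sites, par if par is not None else default_par_intervals())
    sites = restrict_to_coding(sites, coding)
    if mpileup_lines is None:
        raise ValueError("mpileup input required to count RNA alleles")
    records = list(
        count_alleles_for_sites(
            mpileup_lines, sites, min_baseq=min_baseq, sample_id=sample_id
        )
    )
    if gene_map is not None:
        records = annotate_genes(records, gene_map)
    records.sort(key=lambda r: (r.chrom, r.pos, r.alt_allele))
    return records_to_frame(records)
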