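"""Synthetic XCI cohorts with known skew, for model validation end to end.

The generative model mirrors the biology the caller assumes: each female
has an XCI ratio ``rho`` (fraction of cells with the same X active;
0.5 = perfectly random, 1.0 = fully skewed). At every heterozygous site the
expected reference-allele fraction is ``rho`` or ``1 - rho`` with equal
probability — the data are unphased, so which haplotype carries the
reference allele is a fair coin per site. Escape sites express both X
copies and sit at 0.5 regardless of ``rho``. Read counts are then drawn
beta-binomially around that expectation (``site_overdispersion`` is the
extra-binomial noise at a site), with per-site RNA depth from a
negative-binomial law.

All randomness flows from ``spec.seed`` through per-sample child streams,
so any sample can be regenerated independently and byte-identically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import PAR_HG19
from .sites import CvacRecord, records_to_frame

__all__ = [
    "SimulationSpec",
    "SiteMap",
    "simulate_sample",
    "simulate_reference_cohort",
    "draw_cohort_rhos",
    "emit_fixtures",
]

_SITEMAP_STREAM = 10_000_019  # child-stream tag reserved for the site map
_X_LO, _X_HI = 3_000_000, 150_000_000  # outside both hg19 PARs


@dataclasses.dataclass
class SimulationSpec:
    """Study conditions for a synthetic cohort.

    ``rho`` fixes per-sample XCI ratios explicitly; when ``None``,
    :func:`draw_cohort_rhos` supplies a population mixture (90% random
    XCI with rho ~ U(0.5, 0.65), 10% skewed with rho ~ U(0.85, 0.99),
    the make-up of a healthy female cohort).
    """

    n_samples: int = 135
    n_sites: int = 150
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0
    depth_cap: int = 500
    site_overdispersion: float = 0.02
    escape_fraction: float = 0.05
    phase_randomization: bool = True
    rho: Sequence[float] | None = None
    status_rho_cutoff: float = 0.8
    sites_per_gene: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho is not None:
            arr = np.asarray(self.rho, dtype=float)
            if arr.shape != (self.n_samples,):
                raise ValueError("rho must have one entry per sample")
            if np.any(arr < 0.5) or np.any(arr > 1.0):
                raise ValueError("rho values must lie in [0.5, 1.0]")
        if self.site_overdispersion <= 0:
            raise ValueError("site_overdispersion must be > 0")


@dataclasses.dataclass
class SiteMap:
    """Shared cohort site map: positions, alleles, genes, escape flags."""

    chrom: str
    pos: np.ndarray
    ref: list[str]
    alt: list[str]
    gene: list[str]
    is_escape: np.ndarray


def build_site_map(spec: SimulationSpec) -> SiteMap:
    rng = np.random.default_rng([spec.seed, _SITEMAP_STREAM])
    pos = np.sort(
        rng.choice(np.arange(_X_LO, _X_HI, 200, dtype=np.int64), size=spec.n_sites,
                   replace=False)
    )
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=spec.n_sites)
    alt_shift = rng.integers(1, 4, size=spec.n_sites)
    ref = [bases[i] for i in ref_idx]
    alt = [bases[(i + s) % 4] for i, s in zip(ref_idx, alt_shift)]
    gene = [f"GENE{1 + i // spec.sites_per_gene:04d}" for i in range(spec.n_sites)]
    n_escape = int(round(spec.escape_fraction * spec.n_sites))
    is_escape = np.zeros(spec.n_sites, dtype=bool)
    if n_escape:
        is_escape[rng.choice(spec.n_sites, size=n_escape, replace=False)] = True
    return SiteMap(
        chrom="X", pos=pos, ref=ref, alt=alt, gene=gene, is_escape=is_escape
    )


def _draw_counts(
    rng: np.random.Generator, n: np.ndarray, p: np.ndarray, sigma: float
) -> np.ndarray:
    """Beta-binomial draws around expectation p with GAMLSS dispersion sigma."""
    x = np.zeros_like(n)
    inner = (p > 0.0) & (p < 1.0) & (n > 0)
    if inner.any():
        a = p[inner] / sigma
        b = (1.0 - p[inner]) / sigma
        q = rng.beta(a, b)
        x[inner] = rng.binomial(n[inner], q)
    x[(p >= 1.0)] = n[(p >= 1.0)]
    return x


def simulate_sample(
    spec: SimulationSpec,
    sample_index: int,
    rho: float | None = None,
    site_map: SiteMap | None = None,
) -> tuple[list[CvacRecord], pd.DataFrame]:
    """Generate one sample's CVAC records plus its per-site truth rows."""
    if site_map is None:
        site_map = build_site_map(spec)
    if rho is None:
        if spec.rho is None:
            raise ValueError("rho not given and spec.rho unset")
        rho = float(spec.rho[sample_index])
    rng = np.random.default_rng([spec.seed, sample_index])
    sample_id = f"S{sample_index:04d}"

    m = spec.n_sites
    if spec.phase_randomization:
        flip = rng.random(m) < 0.5
    else:
        flip = np.zeros(m, dtype=bool)
    p = np.where(flip, 1.0 - rho, rho)
    p = np.where(site_map.is_escape, 0.5, p)

    pnb = spec.depth_dispersion / (spec.depth_dispersion + spec.depth_mean)
    depth = rng.negative_binomial(spec.depth_dispersion, pnb, size=m)
    depth = np.minimum(depth, spec.depth_cap)
    ref_count = _draw_counts(rng, depth, p, spec.site_overdispersion)

    records = [
        CvacRecord(
            sample_id=sample_id,
            chrom=site_map.chrom,
            pos=int(site_map.pos[i]),
            ref_allele=site_map.ref[i],
            alt_allele=site_map.alt[i],
            ref_count=int(ref_count[i]),
            alt_count=int(depth[i] - ref_count[i]),
            gene_symbol=site_map.gene[i],
        )
        for i in range(m)
    ]
    truth = pd.DataFrame(
        {
            "sample_id": sample_id,
            "chrom": site_map.chrom,
            "pos": site_map.pos,
            "rho": rho,
            "true_status": "skewed" if rho >= spec.status_rho_cutoff else "random",
            "phase_flipped": flip,
            "is_escape": site_map.is_escape,
            "expected_ref_fraction": p,
        }
    )
    return records, truth


def draw_cohort_rhos(
    spec: SimulationSpec,
    skewed_fraction: float = 0.10,
    random_range: tuple[float, float] = (0.5, 0.65),
    skewed_range: tuple[float, float] = (0.85, 0.99),
) -> np.ndarray:
    """Population mixture of XCI ratios for a reference cohort."""
    rng = np.random.default_rng([spec.seed, _SITEMAP_STREAM + 1])
    n_skew = int(round(skewed_fraction * spec.n_samples))
    rhos = rng.uniform(*random_range, size=spec.n_samples)
    if n_skew:
        idx = rng.choice(spec.n_samples, size=n_skew, replace=False)
        rhos[idx] = rng.uniform(*skewed_range, size=n_skew)
    return rhos


def simulate_reference_cohort(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, SiteMap]:
    """Emit the whole cohort's CVAC table (shared site map) plus truth."""
    site_map = build_site_map(spec)
    rhos = (
        np.asarray(spec.rho, dtype=float)
        if spec.rho is not None
        else draw_cohort_rhos(spec)
    )
    frames, truths = [], []
    for j in range(spec.n_samples):
        recs, truth = simulate_sample(spec, j, rho=float(rhos[j]), site_map=site_map)
        frames.append(records_to_frame(recs))
        truths.append(truth)
    return pd.concat(frames, ignore_index=True), pd.concat(truths, ignore_index=True), site_map


# ---------------------------------------------------------------------------
# fixture emission: miniature VCF + mpileup + BEDs for the extraction stage


def _vcf_text(
    site_map: SiteMap, decoys: list[tuple[int, str, str, int, int, str]]
) -> str:
    """Single-sample VCF with PASS het genotypes (plus optional decoys as
    (pos, ref, alt, dp, gq, filter) tuples)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FILTER=<ID=VQSRTrancheSNP99.90,Description="VQSR failed">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "##contig=<ID=X,length=155270560>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    entries = [
        (int(site_map.pos[i]), site_map.ref[i], site_map.alt[i], 50, 99, "PASS")
        for i in range(len(site_map.pos))
    ] + decoys
    for pos, ref, alt, dp, gq, filt in sorted(entries):
        lines.append(
            f"X\t{pos}\t.\t{ref}\t{alt}\t100\t{filt}\t.\tGT:GQ:DP\t0/1:{gq}:{dp}"
        )
    return "\n".join(lines) + "\n"


def _mpileup_text(records: list[CvacRecord], qual_char: str = "I") -> str:
    """mpileup whose hand-countable base strings reproduce the counts."""
    lines = []
    for r in sorted(records, key=lambda r: r.pos):
        bases = []
        for i in range(r.ref_count):
            bases.append("." if i % 2 == 0 else ",")
        for i in range(r.alt_count):
            bases.append(r.alt_allele if i % 2 == 0 else r.alt_allele.lower())
        n = r.ref_count + r.alt_count
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.ref_allele}\t{n}\t{''.join(bases)}\t{qual_char * n}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def emit_fixtures(
    spec: SimulationSpec,
    outdir: str | Path,
    sample_index: int = 0,
    rho: float = 0.9,
    with_decoys: bool = True,
) -> dict[str, Path]:
    """Write a self-consistent VCF + mpileup + BED bundle for one sample.

    Decoy entries (a PAR1 site and a low-GQ site) exercise the extraction
    filters: neither may survive into the extracted CVAC table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    site_map = build_site_map(spec)
    records, truth = simulate_sample(spec, sample_index, rho=rho, site_map=site_map)

    decoys = []
    if with_decoys:
        decoys = [
            (1_000_000, "A", "G", 50, 99, "PASS"),   # inside hg19 PAR1
            (5_000_001, "C", "T", 50, 19, "PASS"),   # GQ below threshold
            (5_000_101, "C", "T", 50, 99, "VQSRTrancheSNP99.90"),
        ]
    paths = {
        "vcf": outdir / "sample.vcf",
        "mpileup": outdir / "sample.mpileup",
        "par": outdir / "par.bed",
        "coding": outdir / "coding.bed",
        "genes": outdir / "genes.bed",
        "escape": outdir / "escape.bed",
        "cvac": outdir / "sample.cvac.tsv",
        "truth": outdir / "sample.truth.tsv",
    }
    paths["vcf"].write_text(_vcf_text(site_map, decoys))
    paths["mpileup"].write_text(_mpileup_text(records))

    with open(paths["par"], "w") as fh:
        for chrom, start1, end1 in PAR_HG19:
            fh.write(f"{chrom}\t{start1 - 1}\t{end1}\n")

    genes: dict[str, list[int]] = {}
    for i, g in enumerate(site_map.gene):
        genes.setdefault(g, []).append(int(site_map.pos[i]))
    with open(paths["genes"], "w") as fh, open(paths["coding"], "w") as cf:
        for g in sorted(genes):
            lo, hi = min(genes[g]) - 50, max(genes[g]) + 50
            fh.write(f"X\t{lo - 1}\t{hi}\t{g}\n")
            cf.write(f"X\t{lo - 1}\t{hi}\n")
        # decoy sites must pass the coding restriction to exercise the
        # PAR/GQ/FILTER stages specifically
        for pos, *_ in decoys:
            cf.write(f"X\t{pos - 1}\t{pos}\n")

    escape_genes = sorted({g for i, g in enumerate(site_map.gene) if site_map.is_escape[i]})
    with open(paths["escape"], "w") as fh:
        for g in escape_genes:
            lo, hi = min(genes[g]) - 50, max(genes[g]) + 50
            fh.write(f"X\t{lo - 1}\t{hi}\t{g}\n")

    records_to_frame(records).to_csv(paths["cvac"], sep="\t", index=False)
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
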