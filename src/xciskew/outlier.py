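"""Per-site outlier testing against the reference hierarchy and per-sample
skew summaries.

Each patient site with RNA depth strictly above the floor is scored with a
two-sided beta-binomial tail p-value under the most specific available
null: the position model if one exists at that coordinate, else the gene
model for the site's gene, else the global model. The patient's counts are
tested raw (unsmoothed). The per-sample summary is the percentage of
tested sites that are significant at ``alpha``; no multiple-testing
correction is applied, matching the method's definition of the statistic.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .betabinom import BetaBinParams, betabinom_pmf_grid
from .intervals import GenomicIntervalSet
from .refmodel import ReferenceModel, position_key
from .sites import NO_GENE, CvacRecord

__all__ = [
    "SiteTestResult",
    "SampleSkewResult",
    "UnreportableSampleError",
    "two_sided_pvalue",
    "select_model",
    "test_sample",
    "exclude_site_lists",
    "model_usage_agreement",
    "site_results_to_frame",
]

logger = logging.getLogger(__name__)

TwoSidedMethod = Literal["doubled_tail", "minlike"]


@dataclasses.dataclass(frozen=True)
class SiteTestResult:
    chrom: str
    pos: int
    gene_symbol: str
    ref_count: int
    alt_count: int
    p_value: float
    model_used: str  # position | gene | global
    significant: bool

    @property
    def total_depth(self) -> int:
        return self.ref_count + self.alt_count


@dataclasses.dataclass(frozen=True)
class SampleSkewResult:
    sample_id: str
    n_sites_tested: int
    n_significant: int
    pct_skewed: float
    alpha: float
    min_test_depth: int
    model_usage: dict[str, float]
    reportable: bool = True
    pct_skewed_no_escape: float | None = None


class UnreportableSampleError(RuntimeError):
    """No site met the testing depth floor; the sample has no skew estimate."""


def two_sided_pvalue(
    x: int,
    n: int,
    params: BetaBinParams,
    method: TwoSidedMethod = "doubled_tail",
) -> float:
    """Two-sided outlier p-value of observing ``x`` reference reads out of
    ``n`` under the beta-binomial null.

    ``doubled_tail`` (default): ``min(1, 2 * min(P(X <= x), P(X >= x)))``
    with both tails including the observed point mass. ``minlike``: the
    total probability of outcomes no more likely than ``x``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if x < 0 or x > n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    pmf = betabinom_pmf_grid(n, params.mu, params.sigma)
    if method == "doubled_tail":
        lower = float(pmf[: x + 1].sum())
        upper = float(pmf[x:].sum())
        p = min(1.0, 2.0 * min(lower, upper))
    elif method == "minlike":
        p = float(pmf[pmf <= pmf[x] * (1.0 + 1e-12)].sum())
        p = min(1.0, p)
    else:
        raise ValueError(f"unknown two-sided method {method!r}")
    return max(p, 5e-324)  # stay inside (0, 1]


def select_model(
    chrom: str, pos: int, gene_symbol: str, model: ReferenceModel
) -> tuple[BetaBinParams, str]:
    """Hierarchy: position model, else gene model, else global."""
    pk = position_key(chrom, pos)
    params = model.position_models.get(pk)
    if params is not None:
        return params, "position"
    if gene_symbol and gene_symbol != NO_GENE:
        params = model.gene_models.get(gene_symbol)
        if params is not None:
            return params, "gene"
    return model.global_model, "global"


def _usage_fractions(tiers: Sequence[str]) -> dict[str, float]:
    n = len(tiers)
    return {
        t: (sum(1 for x in tiers if x == t) / n if n else 0.0)
        for t in ("position", "gene", "global")
    }


def test_sample(
    cvacs: Sequence[CvacRecord],
    model: ReferenceModel,
    min_test_depth: int = 10,
    alpha: float = 0.05,
    method: TwoSidedMethod = "doubled_tail",
) -> tuple[list[SiteTestResult], SampleSkewResult]:
    """Score every eligible site of one sample and summarize its skew.

    Sites need total RNA depth strictly greater than ``min_test_depth``.
    The tested statistic is the reference-allele count (two-sided, so the
    choice of allele is inconsequential). Raises
    :class:`UnreportableSampleError` when no site qualifies.
    """
    sample_ids = {r.sample_id for r in cvacs}
    if len(sample_ids) > 1:
        raise ValueError(f"records from multiple samples: {sorted(sample_ids)}")
    sample_id = next(iter(sample_ids)) if sample_ids else "sample"

    results: list[SiteTestResult] = []
    for rec in cvacs:
        n = rec.total_depth
        if n <= min_test_depth:
            continue
        params, tier = select_model(rec.chrom, rec.pos, rec.gene_symbol, model)
        p = two_sided_pvalue(rec.ref_count, n, params, method=method)
        results.append(
            SiteTestResult(
                chrom=rec.chrom,
                pos=rec.pos,
                gene_symbol=rec.gene_symbol,
                ref_count=rec.ref_count,
                alt_count=rec.alt_count,
                p_value=p,
                model_used=tier,
                significant=p < alpha,
            )
        )
    if not results:
        raise UnreportableSampleError(
            f"sample {sample_id}: no site with depth > {min_test_depth}"
        )
    n_sig = sum(r.significant for r in results)
    summary = SampleSkewResult(
        sample_id=sample_id,
        n_sites_tested=len(results),
        n_significant=n_sig,
        pct_skewed=100.0 * n_sig / len(results),
        alpha=alpha,
        min_test_depth=min_test_depth,
        model_usage=_usage_fractions([r.model_used for r in results]),
    )
    return results, summary


def exclude_site_lists(
    results: Sequence[SiteTestResult],
    summary: SampleSkewResult,
    escape: GenomicIntervalSet | None = None,
    editing_sites: GenomicIntervalSet | None = None,
) -> SampleSkewResult:
    """Recompute the skew percentage after removing sites inside escape
    genes and/or matching known RNA-editing coordinates.

    Both numerator and denominator shrink; the original percentage is kept
    alongside the recomputed one on the returned summary.
    """
    def excluded(r: SiteTestResult) -> bool:
        if escape is not None and escape.contains(r.chrom, r.pos):
            return True
        if editing_sites is not None and editing_sites.contains(r.chrom, r.pos):
            return True
        return False

    kept = [r for r in results if not excluded(r)]
    if (escape is None or len(escape) == 0) and (
        editing_sites is None or len(editing_sites) == 0
    ):
        return dataclasses.replace(summary, pct_skewed_no_escape=summary.pct_skewed)
    if not kept:
        logger.warning(
            "sample %s: every tested site excluded by site lists", summary.sample_id
        )
        return dataclasses.replace(summary, pct_skewed_no_escape=math.nan)
    n_sig = sum(r.significant for r in kept)
    return dataclasses.replace(
        summary, pct_skewed_no_escape=100.0 * n_sig / len(kept)
    )


def model_usage_agreement(
    cvacs: Sequence[CvacRecord],
    model: ReferenceModel,
    min_test_depth: int = 10,
    alpha: float = 0.05,
    method: TwoSidedMethod = "doubled_tail",
) -> dict[tuple[str, str], float]:
    """Pairwise significance agreement between tiers.

    For every eligible site, significance is evaluated under each tier
    whose model exists; for each tier pair the returned value is the
    percentage of co-evaluable sites on which the two calls agree (NaN
    when no site is co-evaluable).
    """
    calls: dict[str, dict[tuple[str, int], bool]] = {
        "position": {},
        "gene": {},
        "global": {},
    }
    for rec in cvacs:
        n = rec.total_depth
        if n <= min_test_depth:
            continue
        key = (rec.chrom, rec.pos)
        pk = position_key(rec.chrom, rec.pos)
        tiers: dict[str, BetaBinParams] = {"global": model.global_model}
        if pk in model.position_models:
            tiers["position"] = model.position_models[pk]
        if rec.gene_symbol in model.gene_models:
            tiers["gene"] = model.gene_models[rec.gene_symbol]
        for tier, params in tiers.items():
            p = two_sided_pvalue(rec.ref_count, n, params, method=method)
            calls[tier][key] = p < alpha

    out: dict[tuple[str, str], float] = {}
    for a, b in (("position", "gene"), ("gene", "global"), ("position", "global")):
        shared = calls[a].keys() & calls[b].keys()
        if not shared:
            logger.warning("no co-evaluable sites for tiers (%s, %s)", a, b)
            out[(a, b)] = math.nan
            continue
        agree = sum(calls[a][k] == calls[b][k] for k in shared)
        out[(a, b)] = 100.0 * agree / len(shared)
    return out


def site_results_to_frame(
    results: Sequence[SiteTestResult],
    ref_alt: dict[tuple[str, int], tuple[str, str]] | None = None,
) -> pd.DataFrame:
    rows = []
    for r in results:
        ref, alt = (ref_alt or {}).get((r.chrom, r.pos), (".", "."))
        rows.append(
            (
                r.chrom, r.pos, ref, alt, r.ref_count, r.alt_count,
                r.gene_symbol, r.p_value, r.model_used, r.significant,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "ref_count", "alt_count",
            "gene", "p_value", "model_used", "significant",
        ],
    )
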