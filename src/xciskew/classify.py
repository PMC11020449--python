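"""Cohort-level skew classification, threshold derivation and concordance
against an orthogonal clinical assay.

A sample is called *skewed* when its percentage of significantly biased
sites exceeds the threshold (strictly). The threshold itself can be fixed
(default 14%, appropriate for a healthy reference cohort) or derived from
the cohort as a local minimum of a Gaussian kernel density over per-sample
percentages, constrained to yield a population skew-call rate in the
expected 10–20% range.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from statsmodels.stats.proportion import proportion_confint

from .outlier import SampleSkewResult

__all__ = [
    "ThresholdConfig",
    "ThresholdResult",
    "ConfusionSummary",
    "classify_sample",
    "derive_threshold",
    "concordance_stats",
    "summarize_cohort",
]

logger = logging.getLogger(__name__)

SKEWED = "skewed"
RANDOM = "random"
UNINFORMATIVE = "uninformative"

# clinical assay labels that collapse onto "skewed"
_SKEW_LABELS = {"skewed", "highly skewed", "moderately skewed", "high", "moderate"}


@dataclasses.dataclass
class ThresholdConfig:
    mode: str = "fixed"  # fixed | density_minimum
    fixed_value: float = 14.0
    search_range: tuple[float, float] = (5.0, 25.0)
    kde_bandwidth: str | float = "silverman"
    expected_population_rate: tuple[float, float] = (0.10, 0.20)
    grid_points: int = 512
    min_samples_for_density: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.fixed_value < 100.0):
            raise ValueError("fixed threshold must be inside (0, 100)")
        if self.search_range[0] >= self.search_range[1]:
            raise ValueError("empty threshold search range")


@dataclasses.dataclass
class ThresholdResult:
    threshold: float
    mode_used: str  # density_minimum | fixed_fallback | fixed
    candidates: list[float]
    grid: np.ndarray | None = None
    density: np.ndarray | None = None


def classify_sample(pct_skewed: float, threshold: float) -> str:
    """Skewed iff the percentage strictly exceeds the threshold."""
    if not (0.0 <= pct_skewed <= 100.0):
        raise ValueError(f"percentage out of [0,100]: {pct_skewed}")
    return SKEWED if pct_skewed > threshold else RANDOM


def derive_threshold(
    cohort_pcts: Sequence[float], config: ThresholdConfig | None = None
) -> ThresholdResult:
    """Pick the skew threshold from the cohort's density of percentages.

    A Gaussian KDE (Silverman bandwidth by default) is evaluated on a
    uniform grid over [0, max+5]; candidate thresholds are interior local
    minima of the density inside ``search_range``. Among candidates whose
    implied call rate (fraction of samples above the candidate) falls in
    ``expected_population_rate`` the deepest minimum wins; if none
    qualifies, the candidate with the call rate closest to that range is
    used. With no candidate at all — or too few samples — the fixed value
    is the documented fallback.
    """
    cfg = config or ThresholdConfig()
    pcts = np.asarray(list(cohort_pcts), dtype=float)
    if cfg.mode == "fixed":
        return ThresholdResult(cfg.fixed_value, "fixed", [])
    if len(pcts) < cfg.min_samples_for_density or np.ptp(pcts) == 0.0:
        logger.warning(
            "density threshold needs >= %d spread-out samples (have %d); "
            "falling back to fixed %.1f%%",
            cfg.min_samples_for_density,
            len(pcts),
            cfg.fixed_value,
        )
        return ThresholdResult(cfg.fixed_value, "fixed_fallback", [])

    kde = gaussian_kde(pcts, bw_method=cfg.kde_bandwidth)
    grid = np.linspace(0.0, float(pcts.max()) + 5.0, cfg.grid_points)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])
    ) + 1
    lo, hi = cfg.search_range
    candidates = [float(grid[i]) for i in interior if lo <= grid[i] <= hi]
    if not candidates:
        logger.warning(
            "no density minimum in [%.1f, %.1f]; falling back to fixed %.1f%%",
            lo, hi, cfg.fixed_value,
        )
        return ThresholdResult(cfg.fixed_value, "fixed_fallback", [], grid, dens)

    rate_lo, rate_hi = cfg.expected_population_rate
    def call_rate(t: float) -> float:
        return float(np.mean(pcts > t))

    inside = [t for t in candidates if rate_lo <= call_rate(t) <= rate_hi]
    if inside:
        chosen = min(inside, key=lambda t: float(kde(t)[0]))
    else:
        def dist(t: float) -> float:
            r = call_rate(t)
            return max(rate_lo - r, r - rate_hi, 0.0)
        chosen = min(candidates, key=dist)
    return ThresholdResult(chosen, "density_minimum", candidates, grid, dens)


@dataclasses.dataclass
class ConfusionSummary:
    """2x3 table: NGS {random, skewed} x assay {random, skewed, uninformative}."""

    table: pd.DataFrame
    n_informative: int
    n_concordant: int
    concordance_pct: float
    ci_lower: float
    ci_upper: float


def _collapse_assay(label: str) -> str:
    s = label.strip().lower()
    if s in _SKEW_LABELS:
        return SKEWED
    if s == RANDOM:
        return RANDOM
    if s in (UNINFORMATIVE, "inconclusive", "na"):
        return UNINFORMATIVE
    raise ValueError(f"unrecognized assay call {label!r}")


def concordance_stats(
    ngs_calls: Sequence[str], assay_calls: Sequence[str]
) -> ConfusionSummary:
    """Confusion table and percent positive agreement with exact 95% CI.

    High/moderate assay skew collapses to one "skewed" class; uninformative
    assay results are excluded from the agreement denominator. The CI is
    the exact Clopper–Pearson interval on concordant/informative.
    """
    if len(ngs_calls) != len(assay_calls):
        raise ValueError("paired call lists must have equal length")
    ngs = [c.strip().lower() for c in ngs_calls]
    if any(c not in (RANDOM, SKEWED) for c in ngs):
        raise ValueError("NGS calls must be 'random' or 'skewed'")
    assay = [_collapse_assay(c) for c in assay_calls]

    table = pd.DataFrame(
        0,
        index=pd.Index([RANDOM, SKEWED], name="NGS"),
        columns=pd.Index([RANDOM, SKEWED, UNINFORMATIVE], name="assay"),
    )
    for n, a in zip(ngs, assay):
        table.loc[n, a] += 1
    informative = [(n, a) for n, a in zip(ngs, assay) if a != UNINFORMATIVE]
    n_inf = len(informative)
    if n_inf == 0:
        raise ValueError("no informative assay results to compare against")
    n_conc = sum(n == a for n, a in informative)
    lo, hi = proportion_confint(n_conc, n_inf, alpha=0.05, method="beta")
    return ConfusionSummary(
        table=table,
        n_informative=n_inf,
        n_concordant=n_conc,
        concordance_pct=100.0 * n_conc / n_inf,
        ci_lower=float(lo),
        ci_upper=float(hi),
    )


def summarize_cohort(
    results: Sequence[SampleSkewResult], threshold: float
) -> pd.DataFrame:
    """Per-sample status table plus the cohort skew-call rate.

    Returns a frame with one row per reportable sample (columns:
    sample_id, n_sites_tested, n_significant, pct_skewed, status) with the
    call rate available as ``frame.attrs["skew_call_rate"]``.
    """
    reportable = [r for r in results if r.reportable and r.n_sites_tested >= 1]
    if not reportable:
        raise ValueError("no reportable samples in cohort")
    rows = [
        (
            r.sample_id,
            r.n_sites_tested,
            r.n_significant,
            round(r.pct_skewed, 2),
            classify_sample(r.pct_skewed, threshold),
        )
        for r in reportable
    ]
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "n_sites_tested", "n_significant", "pct_skewed", "status"],
    )
    df.attrs["skew_call_rate"] = float((df["status"] == SKEWED).mean())
    df.attrs["threshold"] = float(threshold)
    return df


def plot_density(
    pcts: Sequence[float],
    threshold: float | None,
    path: str,
    bw: str | float = "silverman",
) -> None:
    """Density plot of per-sample skew percentages (optional diagnostic)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(list(pcts), dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(arr) >= 2 and np.ptp(arr) > 0:
        kde = gaussian_kde(arr, bw_method=bw)
        grid = np.linspace(0, arr.max() + 5, 512)
        ax.plot(grid, kde(grid), lw=1.5)
    ax.plot(arr, np.zeros_like(arr), "|", ms=12, alpha=0.6)
    if threshold is not None and math.isfinite(threshold):
        ax.axvline(threshold, ls="--", color="crimson", label=f"threshold {threshold:g}%")
        ax.legend()
    ax.set_xlabel("% significantly skewed sites")
    ax.set_ylabel("density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
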