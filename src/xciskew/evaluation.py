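"""Self-contained evaluation studies: calibration, oracle equivalence,
parameter recovery and end-to-end skew-call recovery on synthetic cohorts.

These are the package's own validation experiments. Each function takes an
integer seed, regenerates its inputs from scratch and returns the measured
quantity; nothing is cached or looked up.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import betabinom as scipy_betabinom

from .betabinom import fit_betabinom
from .classify import SKEWED, classify_sample, concordance_stats
from .datasets import clinical_validation_cohort
from .outlier import test_sample, two_sided_pvalue
from .refmodel import (
    build_reference_model,
    eligible_position_keys,
    build_position_models,
)
from .simulate import SimulationSpec, simulate_reference_cohort, simulate_sample

__all__ = [
    "validation_cohort_classification",
    "validation_cohort_concordance",
    "type_one_error_rate",
    "pvalue_oracle_max_diff",
    "mu_recovery_error",
    "end_to_end_recovery",
    "eligibility_match_fraction",
]


def validation_cohort_classification(threshold: float = 14.0) -> dict:
    """Classify the published validation cohort's percentages."""
    cohort = clinical_validation_cohort()
    calls = [classify_sample(p, threshold) for p in cohort["pct_skewed"]]
    return {
        "n_samples": len(cohort),
        "n_skewed": sum(c == SKEWED for c in calls),
        "n_random": sum(c != SKEWED for c in calls),
        "calls": calls,
    }


def validation_cohort_concordance(threshold: float = 14.0):
    """NGS-vs-assay confusion summary on the published validation cohort."""
    cohort = clinical_validation_cohort()
    ngs = [classify_sample(p, threshold) for p in cohort["pct_skewed"]]
    return concordance_stats(ngs, cohort["assay_call"].tolist())


def _truncated_depths(
    rng: np.random.Generator, n: int, mean: float, disp: float, floor: int
) -> np.ndarray:
    p = disp / (disp + mean)
    out = np.empty(0, dtype=int)
    while len(out) < n:
        d = rng.negative_binomial(disp, p, size=2 * n)
        out = np.concatenate([out, d[d > floor]])
    return out[:n]


def type_one_error_rate(
    seed: int, n_sites: int = 10_000, alpha: float = 0.05
) -> float:
    """Fraction of significant sites when counts come from the fitted null.

    A default-conditions reference cohort is simulated, the global
    beta-binomial null is fitted to it, and ``n_sites`` fresh (depth,
    count) pairs are drawn from that fitted null (depths from the
    simulator's own negative-binomial law, truncated to the testable
    range). Each pair is then scored with the same fitted null.
    """
    spec = SimulationSpec(seed=seed)
    cohort, _, _ = simulate_reference_cohort(spec)
    model = build_reference_model(cohort, seed=7)
    g = model.global_model

    rng = np.random.default_rng([seed, 1])
    n = _truncated_depths(rng, n_sites, spec.depth_mean, spec.depth_dispersion, 10)
    q = rng.beta(g.mu / g.sigma, (1 - g.mu) / g.sigma, size=n_sites)
    x = rng.binomial(n, q)
    pv = np.array(
        [two_sided_pvalue(int(xi), int(ni), g) for xi, ni in zip(x, n)]
    )
    return float((pv < alpha).mean())


def pvalue_oracle_max_diff(
    ns: tuple[int, ...] = (5, 20, 50, 200),
    mus: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
    sigmas: tuple[float, ...] = (0.01, 0.1, 0.5, 1.0),
) -> float:
    """Max |p - oracle| over all x, with the oracle a full-pmf enumeration
    through an independent implementation of the distribution."""
    from .betabinom import BetaBinParams

    worst = 0.0
    for n in ns:
        k = np.arange(n + 1)
        for mu in mus:
            for sigma in sigmas:
                a, b = mu / sigma, (1 - mu) / sigma
                pmf = scipy_betabinom.pmf(k, n, a, b)
                lower = np.cumsum(pmf)
                upper = pmf[::-1].cumsum()[::-1]
                oracle = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
                params = BetaBinParams(
                    mu=mu, sigma=sigma, n_observations=1, tier="global", key="g"
                )
                mine = np.array(
                    [two_sided_pvalue(int(x), n, params) for x in k]
                )
                worst = max(worst, float(np.max(np.abs(mine - oracle))))
    return worst


def mu_recovery_error(
    seed: int,
    mus: tuple[float, ...] = (0.5, 0.7, 0.9),
    sigmas: tuple[float, ...] = (0.02, 0.2),
    n_pairs: int = 200,
    depth: int = 50,
    n_replicates: int = 20,
) -> dict[tuple[float, float], float]:
    """Median |mu_hat - mu| per (mu, sigma) over replicate simulations."""
    rng = np.random.default_rng([seed, 2])
    out: dict[tuple[float, float], float] = {}
    for mu in mus:
        for sigma in sigmas:
            errs = []
            for _ in range(n_replicates):
                q = rng.beta(mu / sigma, (1 - mu) / sigma, size=n_pairs)
                x = rng.binomial(depth, q)
                pairs = [(int(xi), depth - int(xi)) for xi in x]
                fit = fit_betabinom(pairs, k_smooth=1.0, min_pairs=10)
                errs.append(abs(fit.mu - mu))
            out[(mu, sigma)] = float(np.median(errs))
    return out


def end_to_end_recovery(
    seed: int,
    n_seeds: int = 20,
    n_skewed: int = 10,
    n_random: int = 10,
    threshold: float = 14.0,
) -> dict:
    """Sensitivity/specificity of the whole pipeline on synthetic patients.

    Per replicate: a 135-sample reference cohort (90% random XCI) is
    simulated and modelled; 10 skewed patients (rho in [0.85, 0.99]) and
    10 random-XCI patients (rho in [0.5, 0.6]) sharing the cohort's site
    map are then scored and classified at the fixed threshold.
    """
    tp = fn = tn = fp = 0
    for r in range(n_seeds):
        spec = SimulationSpec(seed=seed + r)
        cohort, _, site_map = simulate_reference_cohort(spec)
        model = build_reference_model(cohort, seed=7)
        rng = np.random.default_rng([seed, 3, r])
        rhos = np.concatenate(
            [
                rng.uniform(0.85, 0.99, size=n_skewed),
                rng.uniform(0.50, 0.60, size=n_random),
            ]
        )
        truth = [True] * n_skewed + [False] * n_random
        for j, (rho, is_skewed) in enumerate(zip(rhos, truth)):
            recs, _ = simulate_sample(
                spec, 10_000 + j, rho=float(rho), site_map=site_map
            )
            _, summary = test_sample(recs, model)
            called = classify_sample(summary.pct_skewed, threshold) == SKEWED
            if is_skewed:
                tp += called
                fn += not called
            else:
                fp += called
                tn += not called
    return {
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "n_patients": tp + fn + tn + fp,
    }


def eligibility_match_fraction(seed: int) -> float:
    """Jaccard agreement between the fitted position-model key set and a
    brute-force recount of the >=3-reads-in->=10-samples rule (1.0 means
    identical key sets), on a shallow cohort where depth matters."""
    spec = SimulationSpec(
        n_samples=40, n_sites=80, depth_mean=6.0, depth_dispersion=1.0, seed=seed
    )
    cohort, _, _ = simulate_reference_cohort(spec)

    brute: dict[tuple[str, int], set] = {}
    for row in cohort.itertuples(index=False):
        if row.ref_count + row.alt_count >= 3:
            brute.setdefault((row.chrom, int(row.pos)), set()).add(row.sample_id)
    expected = {f"{c}:{p}" for (c, p), s in brute.items() if len(s) >= 10}

    fitted = set(build_position_models(cohort, min_reads=3, min_samples=10))
    fast = eligible_position_keys(cohort, min_reads=3, min_samples=10)
    if not expected and not fitted:
        return 1.0
    union = expected | fitted | fast
    inter = expected & fitted & fast
    return len(inter) / len(union)
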