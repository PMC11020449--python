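"""Beta-binomial distribution in the (mu, sigma) mean/dispersion parameterization.

The allele-count null model used throughout this package is a beta-binomial
in the GAMLSS ``BB`` parameterization: the shape parameters of the latent
beta are ``alpha = mu / sigma`` and ``beta = (1 - mu) / sigma``, so ``mu`` is
the mean reference-allele fraction and ``sigma`` controls the between-sample
overdispersion (``sigma -> 0`` recovers the plain binomial; the intraclass
correlation is ``sigma / (1 + sigma)``).

Counts may be non-integral: Laplace-smoothed pairs ``(r + k, a + k)`` with
fractional ``k`` are supported by the log-gamma form of the pmf.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, expit, logit

__all__ = [
    "BetaBinParams",
    "FitError",
    "EligibilityError",
    "laplace_smooth",
    "betabinom_logpmf",
    "betabinom_pmf_grid",
    "fit_betabinom",
]

MU_LO, MU_HI = 1e-6, 1.0 - 1e-6
SIGMA_LO, SIGMA_HI = 1e-8, 1e3

Tier = Literal["position", "gene", "global"]


class FitError(RuntimeError):
    """Raised when the beta-binomial optimizer fails to converge."""


class EligibilityError(ValueError):
    """Raised when too few count pairs are available to fit a model tier."""


@dataclasses.dataclass(frozen=True)
class BetaBinParams:
    """A fitted beta-binomial null for one model tier.

    Attributes
    ----------
    mu : float
        Mean reference-allele fraction, in (0, 1).
    sigma : float
        Dispersion, > 0 (GAMLSS BB scale).
    n_observations : int
        Number of (ref, alt) count pairs used in the fit.
    tier : str
        One of ``position``, ``gene``, ``global``.
    key : str
        ``chrom:pos`` for position models, gene symbol for gene models,
        ``"global"`` for the global model.
    loglik : float
        Log-likelihood at the optimum (smoothed counts).
    converged : bool
    """

    mu: float
    sigma: float
    n_observations: int
    tier: Tier
    key: str
    loglik: float = math.nan
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.mu < 1.0):
            raise ValueError(f"mu must be in (0,1), got {self.mu}")
        if self.sigma <= 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def alpha(self) -> float:
        return self.mu / self.sigma

    @property
    def beta(self) -> float:
        return (1.0 - self.mu) / self.sigma


def laplace_smooth(
    ref_count: float, alt_count: float, k: float
) -> tuple[float, float]:
    """Add pseudo-count ``k`` to each allele: ``(r + k, a + k)``.

    Applied to reference-cohort counts before model fitting so that
    zero-count sites contribute finite likelihood terms. ``k`` may be
    fractional; it must be positive.
    """
    if k <= 0:
        raise ValueError(f"Laplace smoothing constant must be > 0, got {k}")
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    return ref_count + k, alt_count + k


def _check_mu_sigma(mu: float, sigma: float) -> None:
    if not (0.0 < mu < 1.0):
        raise ValueError(f"mu out of (0,1): {mu}")
    if sigma <= 0.0:
        raise ValueError(f"sigma must be positive: {sigma}")


def betabinom_logpmf(x, n, mu: float, sigma: float):
    """Log-pmf of the beta-binomial, vectorized over ``x`` and ``n``.

        log C(n, x) + log B(x + a, n - x + b) - log B(a, b)

    with ``a = mu/sigma``, ``b = (1-mu)/sigma``. ``x`` and ``n`` may be
    non-integral (smoothed counts); the binomial coefficient generalizes via
    log-gamma. Raises for ``x`` outside ``[0, n]``.
    """
    _check_mu_sigma(mu, sigma)
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("x must satisfy 0 <= x <= n")
    a = mu / sigma
    b = (1.0 - mu) / sigma
    logcomb = gammaln(n + 1.0) - gammaln(x + 1.0) - gammaln(n - x + 1.0)
    return logcomb + betaln(x + a, n - x + b) - betaln(a, b)


def betabinom_pmf_grid(n: int, mu: float, sigma: float) -> np.ndarray:
    """Full pmf over ``x = 0..n`` for integer ``n`` (used by tail tests)."""
    if n < 0 or n != int(n):
        raise ValueError(f"n must be a non-negative integer, got {n}")
    k = np.arange(int(n) + 1)
    return np.exp(betabinom_logpmf(k, int(n), mu, sigma))


def _neg_loglik(theta: np.ndarray, x: np.ndarray, n: np.ndarray) -> float:
    mu = expit(theta[0])
    sigma = math.exp(theta[1])
    mu = min(max(mu, MU_LO), MU_HI)
    sigma = min(max(sigma, SIGMA_LO), SIGMA_HI)
    return -float(np.sum(betabinom_logpmf(x, n, mu, sigma)))


def _moment_start(x: np.ndarray, n: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (mu, sigma) initialization.

    mu from the pooled allele fraction; the intraclass correlation rho from
    the excess variance of per-pair fractions over binomial expectation,
    mapped to sigma = rho / (1 - rho).
    """
    mu = float(np.sum(x) / np.sum(n))
    mu = min(max(mu, MU_LO), MU_HI)
    frac = x / n
    v = float(np.var(frac, ddof=1)) if len(frac) > 1 else 0.0
    nbar = float(np.mean(n))
    denom = mu * (1.0 - mu) * (1.0 - 1.0 / nbar)
    if denom <= 0:
        rho = 0.0
    else:
        rho = (v - mu * (1.0 - mu) / nbar) / denom
    rho = min(max(rho, 1e-6), 1.0 - 1e-6)
    sigma = rho / (1.0 - rho)
    sigma = min(max(sigma, SIGMA_LO), SIGMA_HI)
    return mu, sigma


def fit_betabinom(
    count_pairs: Sequence[tuple[float, float]],
    k_smooth: float = 1.0,
    min_pairs: int = 10,
    tier: Tier = "global",
    key: str = "global",
) -> BetaBinParams:
    """Maximum-likelihood beta-binomial fit on Laplace-smoothed count pairs.

    Parameters
    ----------
    count_pairs : sequence of (ref_count, alt_count)
        Raw cohort counts; smoothing with ``k_smooth`` is applied here.
    k_smooth : float
        Laplace pseudo-count added to each allele before fitting.
    min_pairs : int
        Eligibility floor; fewer pairs raises :class:`EligibilityError` so
        the caller can skip the tier.

    Notes
    -----
    Optimizes over ``(logit mu, log sigma)`` with L-BFGS-B from a
    method-of-moments start, falling back to Nelder–Mead if the gradient
    path stalls. ``mu`` is clamped to ``(1e-6, 1-1e-6)`` and ``sigma`` to
    ``(1e-8, 1e3)``; the returned solution never has lower likelihood than
    the moment start.
    """
    pairs = list(count_pairs)
    if len(pairs) < min_pairs:
        raise EligibilityError(
            f"{len(pairs)} count pairs < required minimum {min_pairs}"
        )
    smoothed = [laplace_smooth(r, a, k_smooth) for r, a in pairs]
    x = np.array([s[0] for s in smoothed], dtype=float)
    tot = np.array([s[0] + s[1] for s in smoothed], dtype=float)

    mu0, sigma0 = _moment_start(x, tot)
    theta0 = np.array([logit(mu0), math.log(sigma0)])
    bounds = [
        (logit(MU_LO), logit(MU_HI)),
        (math.log(SIGMA_LO), math.log(SIGMA_HI)),
    ]
    res = minimize(
        _neg_loglik, theta0, args=(x, tot), method="L-BFGS-B", bounds=bounds
    )
    best = res
    if not res.success or res.fun > _neg_loglik(theta0, x, tot) + 1e-9:
        res2 = minimize(_neg_loglik, theta0, args=(x, tot), method="Nelder-Mead")
        if res2.fun < best.fun:
            best = res2
    if best.fun > _neg_loglik(theta0, x, tot) + 1e-6:
        raise FitError(
            f"optimizer did not improve on moment start for {tier}:{key} "
            f"(start NLL {_neg_loglik(theta0, x, tot):.6g}, "
            f"final NLL {best.fun:.6g})"
        )
    mu = float(min(max(expit(best.x[0]), MU_LO), MU_HI))
    sigma = float(min(max(math.exp(best.x[1]), SIGMA_LO), SIGMA_HI))
    return BetaBinParams(
        mu=mu,
        sigma=sigma,
        n_observations=len(pairs),
        tier=tier,
        key=key,
        loglik=-float(best.fun),
        converged=bool(best.success),
    )
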