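"""Threshold derivation, sample classification and assay concordance."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import binom

from xciskew.classify import (
    RANDOM,
    SKEWED,
    ThresholdConfig,
    classify_sample,
    concordance_stats,
    derive_threshold,
    summarize_cohort,
)
from xciskew.outlier import SampleSkewResult

# published per-sample percentages of significantly skewed sites for the
# 11-sample clinical validation cohort
VALIDATION_PCTS = [
    73.04, 22.43, 46.32, 40.85, 25.93,  # assay: highly/moderately skewed
    2.35, 8.24, 2.94, 2.63,             # assay: random, concordant
    18.37,                               # assay: random, discordant
    25.84,                               # assay: uninformative
]


class TestClassify:
    def test_threshold_is_strict(self):
        assert classify_sample(14.0, 14.0) == RANDOM
        assert classify_sample(14.01, 14.0) == SKEWED

    @pytest.mark.parametrize("pct,expected", [(73.04, SKEWED), (2.35, RANDOM)])
    def test_published_examples(self, pct, expected):
        assert classify_sample(pct, 14.0) == expected

    def test_validation_cohort_calls(self):
        calls = [classify_sample(p, 14.0) for p in VALIDATION_PCTS]
        assert calls.count(SKEWED) == 7
        assert calls.count(RANDOM) == 4

    def test_monotone_in_pct(self):
        thr = 14.0
        grid = np.linspace(0, 100, 401)
        calls = [classify_sample(p, thr) for p in grid]
        first_skew = next(i for i, c in enumerate(calls) if c == SKEWED)
        assert all(c == SKEWED for c in calls[first_skew:])

    def test_out_of_range_pct_rejected(self):
        with pytest.raises(ValueError):
            classify_sample(101.0, 14.0)


class TestDeriveThreshold:
    def _bimodal(self, seed=123):
        rng = np.random.default_rng(seed)
        low = rng.normal(5, 2, size=90)
        high = rng.normal(25, 4, size=10)
        return np.clip(np.concatenate([low, high]), 0, 100)

    def test_bimodal_cohort_threshold_between_modes(self):
        pcts = self._bimodal()
        res = derive_threshold(pcts, ThresholdConfig(mode="density_minimum"))
        assert res.mode_used == "density_minimum"
        assert 10.0 < res.threshold < 20.0

    def test_unimodal_cohort_falls_back(self, caplog):
        rng = np.random.default_rng(4)
        pcts = rng.normal(5, 1.0, size=60).clip(0, 100)
        with caplog.at_level("WARNING"):
            res = derive_threshold(pcts, ThresholdConfig(mode="density_minimum"))
        assert res.mode_used == "fixed_fallback"
        assert res.threshold == 14.0

    def test_too_few_samples_falls_back(self):
        res = derive_threshold([5.0] * 10, ThresholdConfig(mode="density_minimum"))
        assert res.mode_used == "fixed_fallback"

    def test_translation_equivariance(self):
        pcts = self._bimodal()
        cfg = ThresholdConfig(mode="density_minimum")
        base = derive_threshold(pcts, cfg).threshold
        shift = 3.0
        cfg2 = ThresholdConfig(
            mode="density_minimum",
            search_range=(5.0 + shift, 25.0 + shift),
        )
        shifted = derive_threshold(pcts + shift, cfg2).threshold
        # grid spacing bounds the achievable agreement
        grid_step = (pcts.max() + shift + 5) / 511
        assert shifted == pytest.approx(base + shift, abs=2 * grid_step)

    def test_deterministic(self):
        pcts = self._bimodal()
        cfg = ThresholdConfig(mode="density_minimum")
        assert derive_threshold(pcts, cfg).threshold == derive_threshold(pcts, cfg).threshold


def _cp_oracle(k, n, alpha=0.05):
    """Clopper–Pearson by direct root-finding on the binomial tails."""
    lo = 0.0 if k == 0 else brentq(
        lambda p: binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    hi = 1.0 if k == n else brentq(
        lambda p: binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    return lo, hi


class TestConcordance:
    # the published 2x3 confusion table as paired calls:
    # NGS random x assay random = 4; NGS skewed x assay random = 1;
    # NGS skewed x assay skewed = 5; NGS skewed x assay uninformative = 1
    NGS = ["random"] * 4 + ["skewed"] * 7
    ASSAY = (
        ["random"] * 4
        + ["random"]
        + ["highly skewed"] * 3
        + ["moderately skewed"] * 2
        + ["uninformative"]
    )

    def test_published_confusion_matrix(self):
        s = concordance_stats(self.NGS, self.ASSAY)
        assert s.table.loc["random", "random"] == 4
        assert s.table.loc["skewed", "random"] == 1
        assert s.table.loc["skewed", "skewed"] == 5
        assert s.table.loc["skewed", "uninformative"] == 1
        assert s.n_informative == 10
        assert s.concordance_pct == pytest.approx(90.0)
        assert round(s.ci_lower, 2) == 0.55

    def test_exact_ci_for_9_of_10(self):
        s = concordance_stats(self.NGS, self.ASSAY)
        lo, hi = _cp_oracle(9, 10)
        assert s.ci_lower == pytest.approx(lo, abs=1e-6)
        assert s.ci_upper == pytest.approx(hi, abs=1e-6)

    def test_perfect_agreement(self):
        s = concordance_stats(["skewed"] * 10, ["skewed"] * 10)
        assert s.concordance_pct == 100.0
        assert s.ci_upper == 1.0

    def test_order_invariance(self):
        import random as pyrandom

        idx = list(range(len(self.NGS)))
        pyrandom.Random(0).shuffle(idx)
        a = concordance_stats(self.NGS, self.ASSAY)
        b = concordance_stats([self.NGS[i] for i in idx], [self.ASSAY[i] for i in idx])
        assert a.concordance_pct == b.concordance_pct
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_ci_matches_root_finding_small_n(self):
        for n in (1, 5, 17, 50):
            for k in range(n + 1):
                s = concordance_stats(
                    ["skewed"] * k + ["random"] * (n - k), ["skewed"] * n
                )
                lo, hi = _cp_oracle(k, n)
                assert s.ci_lower == pytest.approx(lo, abs=1e-6)
                assert s.ci_upper == pytest.approx(hi, abs=1e-6)

    def test_all_uninformative_errors(self):
        with pytest.raises(ValueError):
            concordance_stats(["skewed"], ["uninformative"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            concordance_stats(["skewed"], ["random", "random"])


class TestSummarizeCohort:
    def _result(self, sid, pct, n=100):
        n_sig = round(pct * n / 100)
        return SampleSkewResult(
            sample_id=sid, n_sites_tested=n, n_significant=n_sig,
            pct_skewed=100 * n_sig / n, alpha=0.05, min_test_depth=10,
            model_usage={"position": 1.0, "gene": 0.0, "global": 0.0},
        )

    def test_validation_percentages_give_seven_skewed(self):
        results = [
            self._result(f"Sample_{i}", p, n=10000)
            for i, p in enumerate(VALIDATION_PCTS, 1)
        ]
        df = summarize_cohort(results, threshold=14.0)
        assert (df["status"] == SKEWED).sum() == 7
        assert (df["status"] == RANDOM).sum() == 4

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            summarize_cohort([], threshold=14.0)

    def test_identical_pcts_give_degenerate_rate(self):
        results = [self._result(f"s{i}", 20.0) for i in range(5)]
        df = summarize_cohort(results, threshold=14.0)
        assert df.attrs["skew_call_rate"] == 1.0
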