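"""Two-sided outlier p-values, the model hierarchy, and per-sample summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xciskew.betabinom import BetaBinParams, betabinom_pmf_grid
from xciskew.intervals import GenomicIntervalSet
from xciskew.outlier import (
    UnreportableSampleError,
    exclude_site_lists,
    model_usage_agreement,
    select_model,
    two_sided_pvalue,
)
from xciskew.outlier import test_sample as score_sample
from xciskew.refmodel import ReferenceModel
from xciskew.simulate import SimulationSpec, simulate_sample
from xciskew.sites import NO_GENE, CvacRecord


def _params(mu=0.5, sigma=0.1, tier="global", key="global"):
    return BetaBinParams(mu=mu, sigma=sigma, n_observations=100, tier=tier, key=key)


class TestTwoSidedPvalue:
    def test_center_is_capped_at_one(self):
        assert two_sided_pvalue(10, 20, _params()) == 1.0

    def test_symmetry_at_half(self):
        p = _params(mu=0.5, sigma=0.2)
        for x in range(0, 31):
            assert two_sided_pvalue(x, 30, p) == pytest.approx(
                two_sided_pvalue(30 - x, 30, p), abs=1e-12
            )

    def test_extreme_count_equals_doubled_point_mass(self):
        p = _params(mu=0.5, sigma=0.1)
        pmf = betabinom_pmf_grid(30, 0.5, 0.1)
        assert two_sided_pvalue(0, 30, p) == pytest.approx(2 * pmf[0], rel=1e-12)

    def test_enumeration_oracle(self):
        # brute-force full-pmf tail sums, independent of the cdf path
        for n in (5, 20, 50):
            for mu in (0.2, 0.5, 0.8):
                for sigma in (0.01, 0.3):
                    pmf = betabinom_pmf_grid(n, mu, sigma)
                    params = _params(mu=mu, sigma=sigma)
                    for x in range(n + 1):
                        lower = pmf[: x + 1].sum()
                        upper = pmf[x:].sum()
                        expected = min(1.0, 2 * min(lower, upper))
                        assert two_sided_pvalue(x, n, params) == pytest.approx(
                            expected, abs=1e-12
                        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(n=st.integers(2, 150), sigma=st.floats(0.01, 1.0))
    def test_monotone_in_distance_from_center(self, n, sigma):
        params = _params(mu=0.5, sigma=sigma)
        pvals = [two_sided_pvalue(x, n, params) for x in range(n + 1)]
        center = n / 2
        order = sorted(range(n + 1), key=lambda x: abs(x - center))
        for a, b in zip(order, order[1:]):
            if abs(a - center) < abs(b - center):
                assert pvals[a] >= pvals[b] - 1e-12

    def test_validity_under_null(self):
        # P(p < alpha) <= alpha for the exact discrete test
        rng = np.random.default_rng(17)
        mu, sigma = 0.5, 0.15
        params = _params(mu=mu, sigma=sigma)
        n = 40
        q = rng.beta(mu / sigma, (1 - mu) / sigma, size=4000)
        xs = rng.binomial(n, q)
        pv = np.array([two_sided_pvalue(int(x), n, params) for x in xs])
        for alpha in (0.01, 0.05, 0.1):
            mc_tol = 3 * math.sqrt(alpha * (1 - alpha) / len(pv))
            assert (pv < alpha).mean() <= alpha + mc_tol

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            two_sided_pvalue(5, 0, _params())
        with pytest.raises(ValueError):
            two_sided_pvalue(-1, 10, _params())
        with pytest.raises(ValueError):
            two_sided_pvalue(11, 10, _params())

    def test_minlike_alternative(self):
        params = _params(mu=0.5, sigma=0.1)
        pmf = betabinom_pmf_grid(20, 0.5, 0.1)
        expected = pmf[pmf <= pmf[3] * (1 + 1e-12)].sum()
        assert two_sided_pvalue(3, 20, params, method="minlike") == pytest.approx(
            float(expected), abs=1e-12
        )


def _model():
    pos = {"X:100": _params(tier="position", key="X:100")}
    gene = {"GENE_A": _params(mu=0.55, tier="gene", key="GENE_A")}
    glob = _params(mu=0.5, sigma=0.3)
    return ReferenceModel(pos, gene, glob, {})


class TestHierarchy:
    def test_position_preferred(self):
        params, tier = select_model("X", 100, "GENE_A", _model())
        assert tier == "position" and params.key == "X:100"

    def test_gene_fallback(self):
        params, tier = select_model("X", 999, "GENE_A", _model())
        assert tier == "gene" and params.key == "GENE_A"

    def test_global_fallback_for_intergenic_unseen(self):
        params, tier = select_model("X", 999, NO_GENE, _model())
        assert tier == "global"

    def test_unmodeled_gene_falls_to_global(self):
        _, tier = select_model("X", 999, "GENE_UNSEEN", _model())
        assert tier == "global"


def _rec(pos, ref_count, alt_count, gene=NO_GENE, sid="s1"):
    return CvacRecord(sid, "X", pos, "C", "T", ref_count, alt_count, gene)


class TestTestSample:
    def test_depth_threshold_strict(self):
        model = _model()
        recs = [_rec(1, 5, 5), _rec(2, 5, 6)]  # depths 10 and 11
        results, summary = score_sample(recs, model, min_test_depth=10)
        assert summary.n_sites_tested == 1
        assert results[0].pos == 2

    def test_all_shallow_is_unreportable(self):
        with pytest.raises(UnreportableSampleError):
            score_sample([_rec(1, 5, 5)], _model(), min_test_depth=10)

    def test_tier_counts_sum_to_tested(self):
        model = _model()
        recs = [_rec(100, 30, 2, "GENE_A"), _rec(200, 6, 6, "GENE_A"),
                _rec(300, 6, 6)]
        results, summary = score_sample(recs, model)
        assert sum(summary.model_usage.values()) == pytest.approx(1.0)
        tiers = [r.model_used for r in results]
        assert tiers == ["position", "gene", "global"]

    def test_significance_flag_matches_alpha(self):
        model = _model()
        results, summary = score_sample(
            [_rec(100, 30, 2, "GENE_A"), _rec(200, 16, 15)], model, alpha=0.05
        )
        for r in results:
            assert r.significant == (r.p_value < 0.05)
        assert summary.pct_skewed == pytest.approx(
            100 * summary.n_significant / summary.n_sites_tested
        )

    def test_pct_invariant_to_site_order(self):
        model = _model()
        recs = [_rec(100, 30, 2, "GENE_A"), _rec(200, 16, 15), _rec(300, 40, 1)]
        _, a = score_sample(recs, model)
        _, b = score_sample(list(reversed(recs)), model)
        assert a.pct_skewed == b.pct_skewed

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError, match="multiple samples"):
            score_sample([_rec(1, 6, 6, sid="a"), _rec(2, 6, 6, sid="b")], _model())

    def test_skewed_sample_scores_above_paired_random(self, ref_setup):
        spec, _, _, site_map, model = ref_setup
        wins = 0
        for k in range(20):
            pair_spec = SimulationSpec(
                n_samples=1, n_sites=spec.n_sites, seed=1000 + k
            )
            skew, _ = simulate_sample(pair_spec, 1, rho=0.9, site_map=site_map)
            rand, _ = simulate_sample(pair_spec, 2, rho=0.5, site_map=site_map)
            _, s_skew = score_sample(skew, model)
            _, s_rand = score_sample(rand, model)
            wins += s_skew.pct_skewed > s_rand.pct_skewed
        assert wins == 20


class TestExclusionLists:
    def _results(self):
        # tight global null so the two 30:2 sites are clear outliers
        model = ReferenceModel({}, {}, _params(mu=0.5, sigma=0.02), {})
        recs = [_rec(p, 30, 2) for p in (10, 20)] + [
            _rec(p, 15, 16) for p in (30, 40, 50, 60, 70, 80, 90, 95)
        ]
        return score_sample(recs, model)

    def test_no_overlap_keeps_percentages(self):
        results, summary = self._results()
        escape = GenomicIntervalSet.from_intervals([("X", 100000, 100100)], "escape_genes")
        out = exclude_site_lists(results, summary, escape=escape)
        assert out.pct_skewed_no_escape == pytest.approx(out.pct_skewed)

    def test_numerator_and_denominator_shrink(self):
        results, summary = self._results()
        # remove one significant (pos 10) and one non-significant (pos 30)
        escape = GenomicIntervalSet.from_intervals(
            [("X", 9, 10), ("X", 29, 30)], "escape_genes"
        )
        out = exclude_site_lists(results, summary, escape=escape)
        assert summary.n_sites_tested == 10 and summary.n_significant == 2
        assert out.pct_skewed_no_escape == pytest.approx(100 / 8)

    def test_empty_lists_are_identity(self):
        results, summary = self._results()
        out = exclude_site_lists(results, summary)
        assert out.pct_skewed_no_escape == pytest.approx(summary.pct_skewed)


class TestModelAgreement:
    def test_symmetric_and_total(self, ref_setup):
        spec, _, _, site_map, model = ref_setup
        recs, _ = simulate_sample(
            SimulationSpec(n_samples=1, n_sites=spec.n_sites, seed=77),
            1, rho=0.55, site_map=site_map,
        )
        agree = model_usage_agreement(recs, model)
        assert set(agree) == {("position", "gene"), ("gene", "global"),
                              ("position", "global")}
        for v in agree.values():
            assert 0 <= v <= 100

    def test_null_cohort_agreement_floor(self, ref_setup):
        # on null-ish samples the three tiers rarely disagree
        spec, _, _, site_map, model = ref_setup
        for k in range(3):
            recs, _ = simulate_sample(
                SimulationSpec(n_samples=1, n_sites=spec.n_sites, seed=200 + k),
                1, rho=0.55, site_map=site_map,
            )
            agree = model_usage_agreement(recs, model)
            for v in agree.values():
                assert math.isnan(v) or v >= 80.0

    def test_no_coevaluable_sites_gives_nan(self):
        glob = _params(mu=0.5, sigma=0.3)
        model = ReferenceModel({}, {}, glob, {})
        agree = model_usage_agreement([_rec(1, 20, 20)], model)
        assert math.isnan(agree[("position", "gene")])
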