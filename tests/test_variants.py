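"""Somatic calling: error-model fitting against a maximum-likelihood
oracle, the three-filter rule with a brute-force tail oracle, the expected
VAF formula and clonality stratification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrevo.errors import DegenerateSiteError, InvalidInputError, NoDataError
from mrevo.variants import (SiteErrorModel, call_somatic_variant,
                            classify_clonality, expected_vaf,
                            fit_site_error_model, platform_concordance,
                            presence_threshold)


def betabinom_tail_bruteforce(alt, depth, alpha, beta):
    """Independent oracle: P(X >= alt) by explicit summation of the
    beta-binomial pmf written from first principles (log-gamma form)."""
    def log_pmf(k):
        return (math.lgamma(depth + 1) - math.lgamma(k + 1)
                - math.lgamma(depth - k + 1)
                + math.lgamma(k + alpha) + math.lgamma(depth - k + beta)
                - math.lgamma(depth + alpha + beta)
                + math.lgamma(alpha + beta)
                - math.lgamma(alpha) - math.lgamma(beta))
    return sum(math.exp(log_pmf(k)) for k in range(alt, depth + 1))


class TestErrorModel:
    def test_clean_controls_give_pseudocount_dominated_mean(self):
        model = fit_site_error_model([(0, 100)] * 5)
        assert model.mean <= 0.005
        assert not model.overdispersed

    def test_method_of_moments_mean_matches_hand_computation(self):
        # ten controls at 1/100: pooled mean (10 + 0.5) / (1000 + 1)
        model = fit_site_error_model([(1, 100)] * 10)
        assert model.mean == pytest.approx(10.5 / 1001, rel=1e-6)
        assert model.mean == pytest.approx(0.01, abs=2e-3)

    def test_overdispersed_controls_fit_beta_binomial(self):
        rng = np.random.default_rng(0)
        p = rng.beta(2, 198, size=50)
        counts = [(int(rng.binomial(1000, pi)), 1000) for pi in p]
        model = fit_site_error_model(counts)
        assert model.overdispersed
        assert model.mean == pytest.approx(0.01, rel=0.5)

    def test_fit_close_to_grid_search_maximum_likelihood(self):
        # MoM vs an independent numerical ML oracle on simulated sites
        rng = np.random.default_rng(7)
        alpha0, beta0, depth = 2.0, 198.0, 1000
        p = rng.beta(alpha0, beta0, size=50)
        counts = [(int(rng.binomial(depth, pi)), depth) for pi in p]
        model = fit_site_error_model(counts)

        x = np.array([c[0] for c in counts])
        means = np.linspace(0.003, 0.03, 60)
        concs = np.geomspace(10, 5000, 80)
        best, best_ll = None, -np.inf
        for m in means:
            for c in concs:
                ll = stats.betabinom.logpmf(x, depth, m * c,
                                            (1 - m) * c).sum()
                if ll > best_ll:
                    best_ll, best = ll, (m * c, (1 - m) * c)
        rel = [abs(model.alpha - best[0]) / best[0],
               abs(model.beta - best[1]) / best[1]]
        assert np.mean(rel) < 0.20

    def test_no_usable_controls_raises(self):
        with pytest.raises(NoDataError):
            fit_site_error_model([(0, 0), (0, 0)])


class TestSomaticCall:
    MODEL = SiteErrorModel(alpha=1.0, beta=199.0)

    def test_low_tumour_vaf_rejected_as_candidate(self):
        call = call_somatic_variant((5, 100), (0, 100), self.MODEL)
        assert call.status == "rejected_candidate"

    def test_high_control_vaf_rejected_as_candidate(self):
        call = call_somatic_variant((30, 100), (6, 100), self.MODEL)
        assert call.status == "rejected_candidate"

    def test_decision_matches_bruteforce_tail(self):
        call = call_somatic_variant((20, 100), (0, 100), self.MODEL)
        tail = betabinom_tail_bruteforce(20, 100, 1.0, 199.0)
        assert call.p_value == pytest.approx(tail, rel=1e-9)
        assert call.is_somatic == (tail < 0.001)

    def test_zero_depth_rejected(self):
        with pytest.raises(InvalidInputError):
            call_somatic_variant((0, 0), (0, 100), self.MODEL)

    @given(st.integers(min_value=0, max_value=99))
    @settings(max_examples=40, deadline=None)
    def test_monotone_in_alt_count(self, alt):
        lo = call_somatic_variant((alt, 100), (0, 100), self.MODEL)
        hi = call_somatic_variant((alt + 1, 100), (0, 100), self.MODEL)
        rank = {"rejected_candidate": 0, "rejected_error_model": 1,
                "somatic": 2}
        assert rank[hi.status] >= rank[lo.status]


class TestExpectedVaf:
    @pytest.mark.parametrize("args,expected", [
        ((1.0, 1.0, 2, 1), 0.5),
        ((1.0, 0.6, 2, 1), 0.30),
        ((1.0, 0.6, 1, 1), 0.6 / 1.4),
        ((0.5, 0.8, 2, 1), 0.5 * 0.8 / 2.0),
        ((1.0, 0.6, 4, 2), 1.2 / 3.2),
    ])
    def test_formula(self, args, expected):
        assert expected_vaf(*args) == pytest.approx(expected)

    def test_no_dna_site_is_an_error(self):
        with pytest.raises(DegenerateSiteError):
            expected_vaf(1.0, 1.0, 0, 1)

    def test_invalid_purity(self):
        with pytest.raises(InvalidInputError):
            expected_vaf(1.0, 0.0, 2, 1)


class TestClonality:
    def test_all_samples_above_threshold_is_clonal(self):
        call = classify_clonality([0.35, 0.22, 0.15], [0.6] * 3, [2] * 3)
        assert call.category == "clonal"

    def test_single_sample_is_subclonal_specific(self):
        call = classify_clonality([0.40, 0.0, 0.0], [0.6] * 3, [2] * 3)
        assert call.category == "subclonal_specific"

    def test_subset_of_samples_is_subclonal(self):
        call = classify_clonality([0.40, 0.35, 0.0], [0.6] * 3, [2] * 3)
        assert call.category == "subclonal"

    def test_copy_number_adjusted_threshold(self):
        # C_t = 4 at purity 0.6: t = 0.10 * (0.6 / 3.2) / 0.30 = 0.0625
        assert presence_threshold(0.6, 4) == pytest.approx(0.0625)
        call = classify_clonality([0.12], [0.6], [4])
        assert bool(call.presence[0])

    def test_diploid_anchor_keeps_plain_ten_percent(self):
        assert presence_threshold(0.6, 2) == pytest.approx(0.10)

    def test_missing_segment_assumes_diploid_and_flags(self):
        call = classify_clonality([0.2, 0.2], [0.6, 0.6], None)
        assert call.diploid_assumed

    def test_no_samples_is_an_error(self):
        with pytest.raises(InvalidInputError):
            classify_clonality([], [], [])

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_clonal_snvs_recovered_at_stated_coverage(self, seed):
        # purity 0.6, 346x: >= 95% of clonal diploid-het SNVs present per sample
        from mrevo.synthetic import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(n_samples=3, n_clones=1, n_trunk_snvs=80,
                               purity_range=(0.6, 0.6), cn_event_rate=0.0,
                               msai_probability=0.0, seed=seed)
        _, tables = simulate_cohort(cfg)
        vaf = tables.variants["alt_count"] / tables.variants["depth"]
        assert (vaf >= 0.10).mean() >= 0.95


class TestConcordance:
    def test_identical_call_sets(self):
        calls = {f"v{i}": "clonal" for i in range(10)}
        frac, dis = platform_concordance(calls, dict(calls))
        assert frac == 1.0 and dis == []

    def test_seven_of_eight(self):
        a = {f"v{i}": "clonal" for i in range(8)}
        b = dict(a)
        b["v0"] = "subclonal"
        frac, dis = platform_concordance(a, b)
        assert frac == pytest.approx(0.875)
        assert dis == ["v0"]

    def test_empty_intersection_is_an_error(self):
        with pytest.raises(NoDataError):
            platform_concordance({"a": "clonal"}, {"b": "clonal"})
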