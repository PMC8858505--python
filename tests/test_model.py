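"""Closed-form model: conversions, posterior combination, ESS."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subborrow import (
    InteractionPrior,
    PlanningDesign,
    SubgroupSummary,
    effective_sample_size,
    implied_prior_range,
    max_weight,
    planning_se,
    pooled_estimate,
    posterior_combine,
    relative_weight,
    se_from_ci,
    sigma_delta_from_weight,
)
from subborrow.model import round_half_away

summaries = st.builds(
    SubgroupSummary,
    estimate=st.floats(-0.5, 0.5),
    se=st.floats(0.01, 0.5),
)
sigma_deltas = st.floats(0.0, 0.5)


class TestSeFromCi:
    @pytest.mark.parametrize("lower,upper,expected", [
        (-0.10, 0.24, 0.086736),   # 0.34 / (2 * 1.959964)
        (-0.08, 0.04, 0.030613),   # 0.12 / (2 * 1.959964)
    ])
    def test_printed_ci_widths(self, lower, upper, expected):
        assert se_from_ci(lower, upper) == pytest.approx(expected, abs=5e-6)

    @given(x=st.floats(0.01, 1.0), level=st.floats(0.5, 0.999))
    def test_symmetric_interval_recovers_half_width(self, x, level):
        from scipy.stats import norm

        z = norm.ppf((1 + level) / 2)
        assert se_from_ci(-x, x, level) * z == pytest.approx(x, rel=1e-12)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            se_from_ci(0.05, 0.05)
        with pytest.raises(ValueError):
            se_from_ci(0.1, -0.1)
        with pytest.raises(ValueError):
            se_from_ci(-0.1, 0.1, level=1.0)


class TestPlanningSe:
    def test_known_subgroup_sizes(self):
        assert planning_se(85, 0.18) == pytest.approx(math.sqrt(0.5904 / 85), rel=1e-12)
        assert planning_se(85, 0.18) == pytest.approx(0.08334, abs=5e-6)
        assert planning_se(707, 0.18) == pytest.approx(0.02890, abs=5e-6)

    def test_unequal_allocation_formula(self):
        # 2:1 allocation at n=90: 60 vs 30 participants
        expected = math.sqrt(0.18 * 0.82 * (1 / 60 + 1 / 30))
        assert planning_se(90, 0.18, alloc=2 / 3) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_failure_probability_rejected(self, p):
        with pytest.raises(ValueError):
            planning_se(100, p)


class TestRelativeWeight:
    def test_sample_size_only_weight_at_elicitation_sizes(self):
        # with equal failure rates the sigma_delta=0 weight is n0/(n0+n1)
        design = PlanningDesign(n_target=80, n_source=700, p_fail=0.18)
        target, source = design.summaries()
        w = relative_weight(InteractionPrior(0.0), target, source)
        assert w == pytest.approx(700 / 780, rel=1e-12)
        assert round_half_away(100 * w) == 90

    def test_elicited_sigma_delta_gives_78_percent(self):
        design = PlanningDesign(n_target=85, n_source=707, p_fail=0.18)
        target, source = design.summaries()
        w = relative_weight(InteractionPrior(0.03353), target, source)
        assert w == pytest.approx(0.780, abs=5e-4)

    def test_infinite_interaction_uncertainty_kills_borrowing(self):
        design = PlanningDesign(n_target=85, n_source=707, p_fail=0.18)
        target, source = design.summaries()
        assert relative_weight(InteractionPrior(1e6), target, source) < 1e-6

    @given(target=summaries, source=summaries,
           sd1=sigma_deltas, sd2=sigma_deltas)
    def test_strictly_decreasing_in_sigma_delta(self, target, source, sd1, sd2):
        lo, hi = sorted((sd1, sd2))
        w_lo = relative_weight(InteractionPrior(hi), target, source)
        w_hi = relative_weight(InteractionPrior(lo), target, source)
        if hi - lo > 1e-6:
            assert w_lo < w_hi
        assert 0 < w_lo <= max_weight(target, source) + 1e-12


class TestSigmaDeltaFromWeight:
    def test_odyssey_weight_back_derivation(self):
        design = PlanningDesign(n_target=85, n_source=707, p_fail=0.18)
        target, source = design.summaries()
        prior = sigma_delta_from_weight(0.78, target, source)
        assert prior.sigma_delta == pytest.approx(0.0335, abs=5e-5)

    def test_full_pooling_weight_gives_zero(self):
        design = PlanningDesign(n_target=85, n_source=707, p_fail=0.18)
        target, source = design.summaries()
        prior = sigma_delta_from_weight(max_weight(target, source), target, source)
        assert prior.sigma_delta == 0.0

    def test_weight_beyond_pooling_bound_rejected(self):
        design = PlanningDesign(n_target=85, n_source=707, p_fail=0.18)
        target, source = design.summaries()
        assert max_weight(target, source) == pytest.approx(0.893, abs=5e-4)
        with pytest.raises(ValueError, match="pooling bound"):
            sigma_delta_from_weight(0.95, target, source)
        with pytest.raises(ValueError):
            sigma_delta_from_weight(0.0, target, source)

    @given(target=summaries, source=summaries, frac=st.floats(0.01, 0.999))
    def test_weight_round_trip_identity(self, target, source, frac):
        w = frac * max_weight(target, source)
        prior = sigma_delta_from_weight(w, target, source)
        assert relative_weight(prior, target, source) == pytest.approx(w, abs=1e-10)


class TestPosteriorCombine:
    def test_example_one_reproduces_printed_results(self, example1):
        res = posterior_combine(example1.target, example1.source, example1.prior)
        assert round_half_away(100 * res.mean) == 0
        assert round_half_away(100 * res.cri_lower) == -8
        assert round_half_away(100 * res.cri_upper) == 8

    def test_agreeing_subgroups_stay_put(self):
        a = SubgroupSummary(0.05, 0.03)
        b = SubgroupSummary(0.05, 0.02)
        res = posterior_combine(a, b, InteractionPrior(0.0))
        assert res.mean == pytest.approx(0.05, rel=1e-12)

    @given(target=summaries, source=summaries, sd=sigma_deltas)
    def test_precision_additivity_and_convexity(self, target, source, sd):
        prior = InteractionPrior(sd)
        res = posterior_combine(target, source, prior)
        prec = 1 / target.se**2 + 1 / (source.se**2 + sd**2)
        assert 1 / res.sd**2 == pytest.approx(prec, rel=1e-12)
        lo = min(target.estimate, source.estimate)
        hi = max(target.estimate, source.estimate)
        assert lo - 1e-12 <= res.mean <= hi + 1e-12
        assert res.cri_lower < res.mean < res.cri_upper
        assert 0 <= res.weight_source <= 1

    @given(target=summaries, source=summaries,
           sd1=sigma_deltas, sd2=sigma_deltas)
    def test_monotone_borrowing(self, target, source, sd1, sd2):
        lo, hi = sorted((sd1, sd2))
        if hi - lo < 1e-6:
            return
        r_lo = posterior_combine(target, source, InteractionPrior(lo))
        r_hi = posterior_combine(target, source, InteractionPrior(hi))
        assert r_hi.sd > r_lo.sd
        assert r_hi.weight_source < r_lo.weight_source

    @given(target=summaries, source=summaries)
    def test_limits_pooling_and_standalone(self, target, source):
        pooled = pooled_estimate(target, source)
        at_zero = posterior_combine(target, source, InteractionPrior(0.0))
        assert at_zero.mean == pooled.mean and at_zero.sd == pooled.sd
        vague = posterior_combine(target, source, InteractionPrior(1e3))
        assert vague.mean == pytest.approx(target.estimate, abs=1e-6)
        assert vague.sd == pytest.approx(target.se, abs=1e-6)


class TestPooledEstimate:
    def test_printed_pooled_means(self, example1, example2):
        p1 = pooled_estimate(example1.target, example1.source)
        p2 = pooled_estimate(example2.target, example2.source)
        assert round_half_away(100 * p1.mean) == -1
        assert round_half_away(100 * p2.mean) == -3

    def test_equal_ses_average(self):
        a = SubgroupSummary(0.10, 0.05)
        b = SubgroupSummary(-0.02, 0.05)
        assert pooled_estimate(a, b).mean == pytest.approx(0.04, rel=1e-12)


class TestEffectiveSampleSize:
    def test_odyssey_ess(self, odyssey):
        assert effective_sample_size(odyssey.prior, odyssey.design) == (301, 386)

    def test_full_pooling_borrows_whole_source(self, odyssey):
        borrowed, total = effective_sample_size(InteractionPrior(0.0), odyssey.design)
        assert borrowed == 707
        assert total == 707 + 85

    def test_vague_prior_borrows_nothing(self, odyssey):
        borrowed, _ = effective_sample_size(InteractionPrior(1e3), odyssey.design)
        assert borrowed == 0

    @given(sd1=sigma_deltas, sd2=sigma_deltas)
    def test_nonincreasing_in_sigma_delta(self, odyssey, sd1, sd2):
        lo, hi = sorted((sd1, sd2))
        b_lo, _ = effective_sample_size(InteractionPrior(hi), odyssey.design)
        b_hi, _ = effective_sample_size(InteractionPrior(lo), odyssey.design)
        assert b_lo <= b_hi


class TestImpliedPriorRange:
    def test_odyssey_feedback_range(self, odyssey):
        lo, hi = implied_prior_range(-0.05, odyssey.prior)
        assert lo == pytest.approx(-0.1157, abs=5e-4)
        assert hi == pytest.approx(0.0157, abs=5e-4)
        assert (round_half_away(100 * lo), round_half_away(100 * hi)) == (-12, 2)

    def test_certainty_collapses_to_point(self):
        assert implied_prior_range(-0.03, InteractionPrior(0.0)) == (-0.03, -0.03)

    def test_symmetric_half_width(self):
        lo, hi = implied_prior_range(0.0, InteractionPrior(0.0335))
        assert hi == -lo
        assert hi == pytest.approx(1.959964 * 0.0335, abs=1e-5)


class TestValidation:
    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            SubgroupSummary(0.1, 0.0)

    def test_negative_sigma_delta_rejected(self):
        with pytest.raises(ValueError):
            InteractionPrior(-0.01)

    @pytest.mark.parametrize("kwargs", [
        dict(n_target=85, n_source=707, p_fail=1.8),
        dict(n_target=1, n_source=707, p_fail=0.18),
        dict(n_target=85, n_source=707, p_fail=0.18, ltfu=1.0),
        dict(n_target=85, n_source=707, p_fail=0.18, margin=0.0),
    ])
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PlanningDesign(**kwargs)
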