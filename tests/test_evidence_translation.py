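"""Bayes-factor translation from reported summary statistics."""

import math

import numpy as np
import pytest

from bayes_audit import (
    BfMethod,
    BfMethodSpec,
    ConfigurationError,
    ContractError,
    Direction,
    DomainError,
    Sidedness,
    StudySummary,
    bf_from_reported,
    bic_bf_from_t,
    jzs_bf_from_t,
    min_bf_from_p,
    onesided_adjust,
)
from bayes_audit.evidence_translation import studies_from_csv, studies_to_csv
from oracles import mc_jzs_bf, mc_sign_mass


def summary(t, df=28, n1=15, n2=15, **kw):
    return StudySummary(t_value=t, df=df, n1=n1, n2=n2, **kw)


class TestStudySummary:
    def test_effective_and_total_n(self):
        s = summary(1.0)
        assert s.effective_n == pytest.approx(7.5)
        assert s.total_n == 30
        one_sample = StudySummary(t_value=1.0, df=14, n1=15)
        assert one_sample.effective_n == 15.0
        assert one_sample.total_n == 15

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(t_value=1.0, df=40, n1=15, n2=15),  # df beyond design
            dict(t_value=1.0, df=15, n1=15),  # one-sample df beyond n-1
            dict(t_value=1.0, df=5, n1=0, n2=10),
            dict(t_value=1.0, df=5, n1=10, n2=10, p_value=1.5),
            dict(t_value=math.inf, df=5, n1=10),
        ],
    )
    def test_invalid_summaries_rejected(self, kwargs):
        with pytest.raises(DomainError):
            StudySummary(**kwargs)

    def test_csv_round_trip(self, bargh_summary):
        studies = [bargh_summary, StudySummary(t_value=-0.3, df=19, n1=20)]
        text = studies_to_csv(studies)
        assert studies_from_csv(text) == studies


class TestJzsBayesFactor:
    def test_zero_signal_favors_null(self):
        assert jzs_bf_from_t(summary(0.0)).bf10 < 1.0

    def test_large_t_gives_overwhelming_evidence(self):
        assert jzs_bf_from_t(summary(10.0)).bf10 > 100.0

    def test_matches_monte_carlo_oracle_at_case_study_point(self):
        ev = jzs_bf_from_t(summary(2.0))
        bf_mc, se = mc_jzs_bf(2.0, 28, 7.5, math.sqrt(2) / 2, 400_000, seed=11)
        assert abs(ev.bf10 - bf_mc) <= 3 * se

    def test_matches_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        for t in (0.0, 1.5, 2.0, 3.0):
            ours = jzs_bf_from_t(summary(t)).bf10
            theirs = float(pingouin.bayesfactor_ttest(t, 15, 15))
            assert ours == pytest.approx(theirs, rel=1e-3)

    def test_symmetric_in_sign_of_t(self):
        assert jzs_bf_from_t(summary(2.0)).bf10 == pytest.approx(
            jzs_bf_from_t(summary(-2.0)).bf10, rel=1e-10
        )

    def test_monotone_in_abs_t(self):
        values = [jzs_bf_from_t(summary(t)).bf10 for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert np.all(np.diff(values) > 0)

    def test_rouder_original_scale_configurable(self):
        wide = jzs_bf_from_t(summary(2.0), BfMethodSpec(prior_scale=1.0)).bf10
        default = jzs_bf_from_t(summary(2.0)).bf10
        bf_mc, se = mc_jzs_bf(2.0, 28, 7.5, 1.0, 400_000, seed=13)
        assert abs(wide - bf_mc) <= 3 * se
        assert wide != pytest.approx(default, rel=1e-3)

    def test_method_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            jzs_bf_from_t(summary(2.0), BfMethodSpec(method=BfMethod.BIC))


class TestBicBayesFactor:
    def test_zero_t_reduces_to_inverse_sqrt_n(self):
        assert bic_bf_from_t(
            summary(0.0), BfMethodSpec(method=BfMethod.BIC)
        ).bf10 == pytest.approx(1 / math.sqrt(30), rel=1e-12)

    def test_case_study_closed_form(self):
        # hand-evaluated: BF01 = sqrt(30) * (1 + 4/28)^(-15)
        expected = 1.0 / (math.sqrt(30) * (1 + 4 / 28) ** -15)
        ev = bic_bf_from_t(summary(2.0), BfMethodSpec(method=BfMethod.BIC))
        assert ev.bf10 == pytest.approx(expected, rel=1e-12)

    def test_sample_size_penalty_at_fixed_t(self):
        small = bic_bf_from_t(summary(2.0), BfMethodSpec(method=BfMethod.BIC)).bf10
        large = bic_bf_from_t(
            StudySummary(t_value=2.0, df=298, n1=150, n2=150),
            BfMethodSpec(method=BfMethod.BIC),
        ).bf10
        assert large < small

    def test_no_overflow_at_extreme_t(self):
        ev = bic_bf_from_t(
            StudySummary(t_value=50.0, df=198, n1=100, n2=100),
            BfMethodSpec(method=BfMethod.BIC),
        )
        assert math.isfinite(ev.bf10) and ev.bf10 > 1e10


class TestMinimumBfBound:
    def test_boundary_at_one_over_e(self):
        assert min_bf_from_p(1 / math.e).bf10 == 1.0
        assert min_bf_from_p(0.9).bf10 == 1.0

    def test_hand_arithmetic_at_p_05(self):
        expected = -1.0 / (math.e * 0.05 * math.log(0.05))
        ev = min_bf_from_p(0.05)
        assert ev.bf10 == pytest.approx(expected, rel=1e-12)
        assert 2.0 < ev.bf10 < 3.0
        assert ev.method is BfMethod.MIN_BOUND

    def test_monotone_decreasing_in_p(self):
        assert min_bf_from_p(0.005).bf10 > min_bf_from_p(0.05).bf10

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 2.0])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            min_bf_from_p(bad)

    def test_upper_bounds_jzs_on_grid(self):
        from scipy import stats

        for t in (2.0, 2.5, 3.0, 4.0):
            s = summary(t)
            p = 2 * stats.t.sf(t, s.df)
            assert min_bf_from_p(p).bf10 >= jzs_bf_from_t(s).bf10


class TestOneSidedAdjustment:
    def test_symmetric_posterior_leaves_bf_unchanged(self):
        s = summary(0.0, direction=Direction.PREDICTED_POSITIVE)
        two = jzs_bf_from_t(s)
        one = onesided_adjust(two, s)
        assert one.bf10 == pytest.approx(two.bf10, rel=1e-6)

    def test_matching_direction_increases_bounded_by_doubling(self):
        s = summary(2.0, direction=Direction.PREDICTED_POSITIVE)
        two = jzs_bf_from_t(s)
        one = onesided_adjust(two, s)
        assert two.bf10 < one.bf10 <= 2 * two.bf10
        mass = mc_sign_mass(2.0, 28, 7.5, math.sqrt(2) / 2, 400_000, seed=17)
        assert one.bf10 == pytest.approx(2 * mass * two.bf10, rel=5e-3)

    def test_wrong_direction_penalized(self):
        s = summary(2.0, direction=Direction.PREDICTED_NEGATIVE)
        two = jzs_bf_from_t(s)
        assert onesided_adjust(two, s).bf10 < two.bf10

    def test_undirected_claim_rejected(self):
        s = summary(2.0)
        with pytest.raises(ContractError, match="two-sided"):
            onesided_adjust(jzs_bf_from_t(s), s)


class TestDispatch:
    def test_routes_match_direct_calls(self, bargh_summary, jzs_spec):
        assert bf_from_reported(bargh_summary, jzs_spec).bf10 == pytest.approx(
            jzs_bf_from_t(bargh_summary, jzs_spec).bf10
        )
        assert bf_from_reported(
            bargh_summary, BfMethodSpec(method=BfMethod.MIN_BOUND)
        ).bf10 == pytest.approx(min_bf_from_p(0.05).bf10)

    def test_stipulated_passes_through(self, bargh_summary):
        ev = bf_from_reported(bargh_summary, stipulated_bf10=1.0)
        assert ev.bf10 == 1.0
        assert ev.method is BfMethod.STIPULATED

    def test_min_bound_without_p_names_the_field(self):
        s = StudySummary(t_value=2.0, df=28, n1=15, n2=15)
        with pytest.raises(ConfigurationError, match="p_value"):
            bf_from_reported(s, BfMethodSpec(method=BfMethod.MIN_BOUND))

    def test_one_sided_spec_applies_adjustment(self, bargh_summary):
        one = bf_from_reported(
            bargh_summary, BfMethodSpec(sided=Sidedness.ONE_SIDED)
        )
        two = bf_from_reported(bargh_summary, BfMethodSpec())
        assert one.sided is Sidedness.ONE_SIDED
        assert one.bf10 > two.bf10

    def test_inconsistent_t_and_p_warns(self):
        s = StudySummary(t_value=3.5, df=28, n1=15, n2=15, p_value=0.5)
        with pytest.warns(UserWarning, match="disagrees"):
            jzs_bf_from_t(s)


def test_case_study_translation_spread():
    """All translation routes for t(28)=2, p=.05 land in the anecdotal-to-
    moderate range around the published BF of 3."""
    s = StudySummary(
        t_value=2.0, df=28, n1=15, n2=15, p_value=0.05,
        direction=Direction.PREDICTED_POSITIVE,
    )
    values = {
        "jzs_two": jzs_bf_from_t(s).bf10,
        "jzs_one": bf_from_reported(s, BfMethodSpec(sided=Sidedness.ONE_SIDED)).bf10,
        "bic": bic_bf_from_t(s, BfMethodSpec(method=BfMethod.BIC)).bf10,
        "min_bound": min_bf_from_p(0.05).bf10,
    }
    for name, v in values.items():
        assert 1.0 < v < 3.5, (name, v)
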