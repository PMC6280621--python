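"""Markov cohort engine: discounting, evolution, accrual conventions."""

import dataclasses

import numpy as np
import pytest

from brcacea import (
    Arm,
    EFF_CANCER_FREE_YEARS,
    EFF_PER100,
    StrategyModel,
    discount_factor,
    run_cohort,
    strategy_outcome,
)


def single_arm(pb=0.0, po=0.0, oneoff=0.0, percyc=0.0, label="arm"):
    return StrategyModel(name="toy", arms=(Arm(label, 1.0, pb, po, oneoff, percyc),))


class TestDiscountFactor:
    def test_time_zero_and_zero_rate(self):
        assert discount_factor(0.05, 0) == 1.0
        assert discount_factor(0.0, 17) == 1.0

    def test_one_cycle_at_five_percent(self):
        assert discount_factor(0.05, 1) == pytest.approx(1 / 1.05, abs=1e-15)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(0.05, -1)
        with pytest.raises(ValueError):
            discount_factor(-0.01, 3)


class TestZeroRiskCohort:
    def test_cost_is_oneoff_plus_annuity_due(self):
        # oracle: direct summation of the 40-term discount series
        annuity = sum(1.05 ** (-t) for t in range(40))
        assert annuity == pytest.approx(18.0170, abs=5e-5)  # hand check of the sum
        C = 123.45
        trace = run_cohort(single_arm(percyc=C, oneoff=10.0), 40, 0.05)
        assert trace.expected_cases == 0.0
        assert trace.expected_cost == pytest.approx(10.0 + C * annuity, abs=1e-9)

    def test_effectiveness_boundaries(self):
        trace = run_cohort(single_arm(), 40, 0.05)
        assert strategy_outcome(trace, EFF_PER100).effectiveness == pytest.approx(100.0)
        annuity = sum(1.05 ** (-t) for t in range(40))
        assert strategy_outcome(trace, EFF_CANCER_FREE_YEARS).effectiveness == pytest.approx(annuity)


class TestTransitions:
    def test_certain_transition_single_cycle(self):
        trace = run_cohort(single_arm(pb=1.0), 1, 0.0)
        assert trace.occupancy[0, 1].tolist() == [0.0, 1.0, 0.0]
        assert trace.expected_cases == pytest.approx(1.0)

    def test_joint_event_mass_assigned_to_breast(self):
        trace = run_cohort(single_arm(pb=0.3, po=0.4), 1, 0.0)
        occ = trace.occupancy[0, 1]
        assert occ[1] == pytest.approx(0.3)            # all of p_b, incl. joint mass
        assert occ[2] == pytest.approx(0.7 * 0.4)      # ovarian only from breast survivors
        assert occ[0] == pytest.approx(0.7 * 0.6)

    def test_cancer_states_absorbing(self):
        trace = run_cohort(single_arm(pb=0.5, po=0.2), 10, 0.0)
        cancer = trace.occupancy[0, :, 1] + trace.occupancy[0, :, 2]
        assert np.all(np.diff(cancer) >= -1e-15)

    @pytest.mark.parametrize("pb, po", [(0.02, 0.01), (0.5, 0.5), (0.0, 0.013)])
    def test_zero_discount_cases_match_closed_form_absorption(self, pb, po):
        n = 40
        trace = run_cohort(single_arm(pb=pb, po=po), n, 0.0)
        analytic = 1.0 - ((1 - pb) * (1 - po)) ** n
        assert trace.expected_cases == pytest.approx(analytic, abs=1e-12)

    def test_mixture_weighted_absorption_zero_discount(self, usual_strategy):
        n = 40
        trace = run_cohort(usual_strategy, n, 0.0)
        analytic = sum(
            a.weight * (1.0 - ((1 - a.annual_p_breast) * (1 - a.annual_p_ovarian)) ** n)
            for a in usual_strategy.arms
        )
        assert trace.expected_cases == pytest.approx(analytic, abs=1e-12)


class TestInvariants:
    @pytest.mark.parametrize("which", ["testing", "usual"])
    def test_occupancy_conservation_every_cycle(self, which, testing_strategy, usual_strategy):
        strategy = testing_strategy if which == "testing" else usual_strategy
        trace = run_cohort(strategy, 40, 0.05)
        sums = trace.occupancy.sum(axis=2)
        assert np.max(np.abs(sums - 1.0)) <= 1e-12
        assert np.min(trace.occupancy) >= -1e-15

    def test_cumulative_totals_nondecreasing(self, testing_strategy):
        trace = run_cohort(testing_strategy, 40, 0.05)
        cum = trace.cumulative()
        assert (cum["cum_disc_cost"].diff().dropna() >= 0).all()
        assert (cum["cum_disc_cases"].diff().dropna() >= 0).all()

    def test_cost_scaling_linearity(self, params):
        from brcacea import build_testing_strategy

        k = 3.7
        scaled = params
        for name in params.costs:
            scaled = scaled.with_cost_amount(name, params.cost(name) * k)
        base = run_cohort(build_testing_strategy(params), 40, 0.05)
        big = run_cohort(build_testing_strategy(scaled), 40, 0.05)
        assert big.expected_cost == pytest.approx(k * base.expected_cost, rel=1e-12)
        assert big.expected_cases == pytest.approx(base.expected_cases, abs=1e-15)

    def test_null_intervention_equalises_strategies(self, params):
        """With surgical effects and all intervention costs removed, the two
        strategies are the same model and must produce identical outcomes."""
        from brcacea import build_strategies

        neutral = params
        for gene in ("brca1", "brca2"):
            for post in ("post_mx", "post_rrso", "post_both"):
                neutral = neutral.with_prob_point(
                    f"p_breast_ca_{gene}_{post}", params.prob(f"p_breast_ca_{gene}")
                )
            neutral = neutral.with_prob_point(
                f"p_ov_ca_{gene}_post_rrso", params.prob(f"p_ov_ca_{gene}")
            )
        for cost in ("counseling", "ngs_plus_mlpa", "mastectomy", "rrso",
                     "screening_mutation_carrier_annual", "screening_high_risk_annual"):
            neutral = neutral.with_cost_amount(cost, 0.0)
        testing, usual = build_strategies(neutral)
        out_t = strategy_outcome(run_cohort(testing, 40, 0.05))
        out_u = strategy_outcome(run_cohort(usual, 40, 0.05))
        assert out_t.expected_cost == pytest.approx(out_u.expected_cost, abs=1e-9)
        assert out_t.expected_cases == pytest.approx(out_u.expected_cases, abs=1e-12)

    def test_tiebreak_convention_immaterial_at_model_risks(self, usual_strategy):
        """Assigning the tiny joint-event mass to ovarian instead of breast
        moves total discounted cases by less than 1e-3."""
        flipped_arms = tuple(
            dataclasses.replace(a) for a in usual_strategy.arms
        )
        base = run_cohort(usual_strategy, 40, 0.05).expected_cases
        # ovarian-first variant: swap the roles of the two risks and the states
        swapped = StrategyModel(
            name="swapped",
            arms=tuple(
                dataclasses.replace(a, annual_p_breast=a.annual_p_ovarian, annual_p_ovarian=a.annual_p_breast)
                for a in flipped_arms
            ),
        )
        alt = run_cohort(swapped, 40, 0.05).expected_cases
        assert abs(base - alt) < 1e-3


class TestOrderings:
    def test_testing_more_effective_and_more_costly(self, testing_strategy, usual_strategy):
        out_t = strategy_outcome(run_cohort(testing_strategy, 40, 0.05))
        out_u = strategy_outcome(run_cohort(usual_strategy, 40, 0.05))
        assert out_t.effectiveness > out_u.effectiveness
        assert out_t.expected_cost > out_u.expected_cost

    def test_conventions_agree_on_ordering(self, testing_strategy, usual_strategy):
        t_trace = run_cohort(testing_strategy, 40, 0.05)
        u_trace = run_cohort(usual_strategy, 40, 0.05)
        for conv in (EFF_PER100, EFF_CANCER_FREE_YEARS):
            assert (
                strategy_outcome(t_trace, conv).effectiveness
                > strategy_outcome(u_trace, conv).effectiveness
            )

    def test_unknown_convention_rejected(self, testing_strategy):
        trace = run_cohort(testing_strategy, 1, 0.0)
        with pytest.raises(ValueError, match="convention"):
            strategy_outcome(trace, "qalys")


def test_trace_export_long_format(usual_strategy):
    trace = run_cohort(usual_strategy, 5, 0.05)
    frame = trace.to_frame()
    # one row per (arm, cycle incl. terminal, state)
    assert len(frame) == 3 * 6 * 3
    assert set(frame["state"]) == {"well", "breast_cancer", "ovarian_cancer"}
    pivot = frame.groupby(["arm", "cycle"])["occupancy"].sum()
    assert np.allclose(pivot, 1.0, atol=1e-12)
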