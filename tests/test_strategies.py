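"""Construction of the two comparator strategies from the parameter set."""

import pytest

from brcacea import (
    Arm,
    StrategyModel,
    build_testing_strategy,
    build_usual_care_strategy,
    carrier_proportions,
    arm_table,
    lifetime_to_annual,
)
from brcacea.parameters import ParameterError


class TestCarrierProportions:
    def test_published_split_rounds_to_45_5_50(self):
        p1, p2, p0 = carrier_proportions(0.17, 0.02, 0.5)
        assert p1 == pytest.approx(0.17 / 0.19 * 0.5)
        assert p2 == pytest.approx(0.02 / 0.19 * 0.5)
        assert (round(p1 * 100), round(p2 * 100), round(p0 * 100)) == (45, 5, 50)

    def test_single_gene_degenerate_case(self):
        assert carrier_proportions(0.19, 0.0, 0.5) == pytest.approx((0.5, 0.0, 0.5))

    def test_certain_transmission_leaves_no_noncarriers(self):
        p1, p2, p0 = carrier_proportions(0.17, 0.02, 1.0)
        assert p1 == pytest.approx(0.17 / 0.19)
        assert p0 == pytest.approx(0.0, abs=1e-15)

    def test_zero_prevalence_rejected(self):
        with pytest.raises(ValueError):
            carrier_proportions(0.0, 0.0, 0.5)


class TestTestingStrategy:
    def test_weights_sum_to_one(self, testing_strategy):
        assert sum(a.weight for a in testing_strategy.arms) == pytest.approx(1.0, abs=1e-12)

    def test_no_mutation_arm_weight_is_half(self, testing_strategy):
        (arm,) = [a for a in testing_strategy.arms if a.label == "no_mutation"]
        assert arm.weight == pytest.approx(0.50)

    def test_brca1_arms_total_weight(self, testing_strategy):
        total = sum(a.weight for a in testing_strategy.arms if a.label.startswith("brca1/"))
        assert total == pytest.approx(0.45)

    def test_adherence_independence_joint_weight(self, testing_strategy):
        (arm,) = [a for a in testing_strategy.arms if a.label == "brca1/mastectomy+rrso"]
        assert arm.weight == pytest.approx(0.45 * 0.18 * 0.57)

    def test_full_adherence_collapses_refusal_arms(self, params):
        full = params.with_prob_point("p_adhere_mastectomy", 1.0).with_prob_point("p_adhere_rrso", 1.0)
        strategy = build_testing_strategy(full)
        nonzero = [a.label for a in strategy.arms if a.weight > 0]
        assert sorted(nonzero) == ["brca1/mastectomy+rrso", "brca2/mastectomy+rrso", "no_mutation"]

    def test_every_arm_charged_counseling_plus_test(self, testing_strategy, params):
        base = params.cost("counseling") + params.cost("ngs_plus_mlpa")
        assert all(a.oneoff_cost >= base for a in testing_strategy.arms)

    def test_surgical_arms_add_procedure_costs(self, testing_strategy, params):
        base = params.cost("counseling") + params.cost("ngs_plus_mlpa")
        by_label = {a.label: a for a in testing_strategy.arms}
        assert by_label["brca1/mastectomy+rrso"].oneoff_cost == pytest.approx(
            base + params.cost("mastectomy") + params.cost("rrso")
        )
        assert by_label["brca2/rrso"].oneoff_cost == pytest.approx(base + params.cost("rrso"))
        assert by_label["no_mutation"].oneoff_cost == pytest.approx(base)

    def test_screening_only_for_carriers_refusing_mastectomy(self, testing_strategy, params):
        screen = params.cost("screening_mutation_carrier_annual")
        for arm in testing_strategy.arms:
            if arm.label == "no_mutation" or "mastectomy" in arm.label:
                assert arm.percycle_cost == 0.0
            else:  # carrier arms 'rrso' and 'no_surgery'
                assert arm.percycle_cost == screen == 333.75

    def test_no_mutation_arm_uses_population_risks(self, testing_strategy, params):
        (arm,) = [a for a in testing_strategy.arms if a.label == "no_mutation"]
        assert arm.annual_p_breast == pytest.approx(lifetime_to_annual(0.06, 40))
        assert arm.annual_p_ovarian == pytest.approx(lifetime_to_annual(0.006, 40))

    def test_post_surgery_risks_never_exceed_no_surgery(self, testing_strategy):
        by_label = {a.label: a for a in testing_strategy.arms}
        for gene in ("brca1", "brca2"):
            base = by_label[f"{gene}/no_surgery"]
            for surg in ("mastectomy", "rrso", "mastectomy+rrso"):
                arm = by_label[f"{gene}/{surg}"]
                assert arm.annual_p_breast <= base.annual_p_breast
                assert arm.annual_p_ovarian <= base.annual_p_ovarian

    def test_missing_parameter_build_error_names_it(self, params):
        import dataclasses

        probs = dict(params.probs)
        del probs["p_adhere_rrso"]
        broken = dataclasses.replace(params, probs=probs)
        with pytest.raises(ParameterError, match="p_adhere_rrso"):
            build_testing_strategy(broken)


class TestUsualCareStrategy:
    def test_every_arm_carries_expected_screening_cost(self, usual_strategy):
        assert all(a.percycle_cost == pytest.approx(80.10) for a in usual_strategy.arms)

    def test_no_oneoff_costs_anywhere(self, usual_strategy):
        assert all(a.oneoff_cost == 0.0 for a in usual_strategy.arms)

    def test_same_latent_carrier_mixture(self, usual_strategy):
        weights = {a.label: a.weight for a in usual_strategy.arms}
        assert weights == pytest.approx({"brca1": 0.45, "brca2": 0.05, "no_mutation": 0.50})

    def test_brca1_arm_uses_no_surgery_penetrance(self, usual_strategy):
        (arm,) = [a for a in usual_strategy.arms if a.label == "brca1"]
        assert arm.annual_p_ovarian == pytest.approx(lifetime_to_annual(0.40, 40), abs=1e-15)
        assert arm.annual_p_breast == pytest.approx(lifetime_to_annual(0.57, 40), abs=1e-15)


class TestModelTypes:
    def test_weight_sum_enforced(self):
        arm = Arm("a", 0.5, 0.01, 0.01, 0.0, 0.0)
        with pytest.raises(ValueError, match="sum"):
            StrategyModel("bad", (arm,))

    def test_arm_bounds_enforced(self):
        with pytest.raises(ValueError):
            Arm("a", 1.2, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            Arm("a", 0.5, -0.1, 0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            Arm("a", 0.5, 0.0, 0.0, -5.0, 0.0)

    def test_arm_table_dump(self, testing_strategy):
        table = arm_table(testing_strategy)
        assert len(table) == 9  # 2 genes x 4 adherence combos + no-mutation
        assert table["weight"].sum() == pytest.approx(1.0)
        assert set(table.columns) >= {"arm", "weight", "annual_p_breast", "oneoff_cost"}
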