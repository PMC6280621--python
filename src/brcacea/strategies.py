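"""The two comparator strategies as weighted decision-tree arms.

Each strategy is a mixture of *arms*: sub-cohorts fixed at time zero
(mutation status and, in the testing strategy, surgical uptake), each
carrying its own annual cancer risks, one-off costs and per-cycle costs.
The Markov engine evolves every arm independently and weights the results.

Testing strategy
    Every relative is counselled and tested at cycle 0.  Carriers are
    offered bilateral prophylactic mastectomy (uptake 0.18) and
    risk-reducing salpingo-oophorectomy (uptake 0.57), treated as
    independent choices, giving four adherence arms per gene; surgery
    happens at age 30 and the matching post-surgery penetrance applies.
    Carriers who refuse mastectomy get annual breast MRI + mammography
    (R$333.75/yr while cancer-free).  Non-carriers receive no further
    intervention.

Usual care
    Nobody is tested; the same latent carrier mixture applies with
    no-surgery penetrance.  Screening reaches the fraction whose risk
    algorithm flags them (24%), charged as its expected value
    0.24 x R$333.75 = R$80.10 per relative-year across all arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .hazard import lifetime_to_annual
from .parameters import ParameterError, ParameterSet

__all__ = [
    "Arm",
    "StrategyModel",
    "TESTING",
    "USUAL_CARE",
    "build_testing_strategy",
    "build_usual_care_strategy",
    "build_strategies",
    "carrier_proportions",
    "arm_table",
]

TESTING = "testing"
USUAL_CARE = "usual_care"

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class Arm:
    """One sub-cohort: fixed risks and cost schedule over the whole horizon."""

    label: str
    weight: float
    annual_p_breast: float
    annual_p_ovarian: float
    oneoff_cost: float
    percycle_cost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"arm {self.label!r}: weight {self.weight} outside [0, 1]")
        for name in ("annual_p_breast", "annual_p_ovarian"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"arm {self.label!r}: {name} {v} outside [0, 1]")
        if self.oneoff_cost < 0 or self.percycle_cost < 0:
            raise ValueError(f"arm {self.label!r}: costs must be >= 0")


@dataclass(frozen=True)
class StrategyModel:
    """A named, weight-normalised collection of arms."""

    name: str
    arms: tuple[Arm, ...]

    def __post_init__(self) -> None:
        total = sum(a.weight for a in self.arms)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"strategy {self.name!r}: arm weights sum to {total!r}, not 1")


def carrier_proportions(
    prev1: float, prev2: float, transmission: float
) -> tuple[float, float, float]:
    """Mutation mixture among first-degree relatives of carrier patients.

    Conditioning on the index patient carrying *some* pathogenic variant,
    the gene split follows the patient prevalences (``prev1``/``prev2``)
    renormalised, and each relative inherits with the autosomal-dominant
    transmission probability.  At the published inputs (0.17, 0.02, 0.5)
    this yields the 45% / 5% / 50% relative mixture.
    """
    for name, p in (("prev1", prev1), ("prev2", prev2), ("transmission", transmission)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} {p} outside [0, 1]")
    total = prev1 + prev2
    if total == 0.0:
        raise ValueError("prev1 + prev2 must be positive")
    if total > 1.0:
        raise ValueError(f"prev1 + prev2 = {total} exceeds 1")
    p1 = prev1 / total * transmission
    p2 = prev2 / total * transmission
    return p1, p2, 1.0 - p1 - p2


def _annual_risks(params: ParameterSet, breast_name: str, ovarian_name: str) -> tuple[float, float]:
    n = params.n_cycles
    return (
        lifetime_to_annual(params.prob(breast_name), n),
        lifetime_to_annual(params.prob(ovarian_name), n),
    )


def build_testing_strategy(params: ParameterSet) -> StrategyModel:
    """Genetic testing plus risk-reducing surgery for confirmed carriers.

    Arms: {BRCA1, BRCA2} x {both surgeries, mastectomy only, RRSO only,
    neither} plus one no-mutation arm.  Counselling and NGS+MLPA testing
    are charged once to every relative; surgical costs attach to the arms
    that undergo them; breast screening accrues per cycle only in carrier
    arms that refused mastectomy (screening stops on a cancer diagnosis,
    and no ovarian screening exists in any arm).
    """
    try:
        w1 = params.prob("p_relative_brca1")
        w2 = params.prob("p_relative_brca2")
        p_mx = params.prob("p_adhere_mastectomy")
        p_rrso = params.prob("p_adhere_rrso")
        base_oneoff = params.cost("counseling") + params.cost("ngs_plus_mlpa")
        c_mx = params.cost("mastectomy")
        c_rrso = params.cost("rrso")
        c_screen = params.cost("screening_mutation_carrier_annual")
    except ParameterError as exc:
        raise ParameterError(f"cannot build testing strategy: {exc}") from exc

    arms: list[Arm] = []
    for gene, w_gene in (("brca1", w1), ("brca2", w2)):
        # (mastectomy?, rrso?) -> (breast penetrance row, ovarian penetrance row)
        combos = {
            (True, True): (f"p_breast_ca_{gene}_post_both", f"p_ov_ca_{gene}_post_rrso"),
            (True, False): (f"p_breast_ca_{gene}_post_mx", f"p_ov_ca_{gene}"),
            (False, True): (f"p_breast_ca_{gene}_post_rrso", f"p_ov_ca_{gene}_post_rrso"),
            (False, False): (f"p_breast_ca_{gene}", f"p_ov_ca_{gene}"),
        }
        for (mx, rrso), (b_name, o_name) in combos.items():
            weight = w_gene * (p_mx if mx else 1 - p_mx) * (p_rrso if rrso else 1 - p_rrso)
            pb, po = _annual_risks(params, b_name, o_name)
            label = gene + "/" + {
                (True, True): "mastectomy+rrso",
                (True, False): "mastectomy",
                (False, True): "rrso",
                (False, False): "no_surgery",
            }[(mx, rrso)]
            arms.append(
                Arm(
                    label=label,
                    weight=weight,
                    annual_p_breast=pb,
                    annual_p_ovarian=po,
                    oneoff_cost=base_oneoff + (c_mx if mx else 0.0) + (c_rrso if rrso else 0.0),
                    percycle_cost=0.0 if mx else c_screen,
                )
            )
    pb, po = _annual_risks(params, "p_breast_ca_nomut", "p_ov_ca_nomut")
    arms.append(
        Arm(
            label="no_mutation",
            weight=1.0 - w1 - w2,
            annual_p_breast=pb,
            annual_p_ovarian=po,
            oneoff_cost=base_oneoff,
            percycle_cost=0.0,
        )
    )
    return StrategyModel(name=TESTING, arms=tuple(arms))


def build_usual_care_strategy(params: ParameterSet) -> StrategyModel:
    """Comparator: no testing, no surgery, risk-algorithm-triggered screening.

    The latent carrier mixture is identical to the testing strategy; every
    arm uses no-surgery penetrance and carries the expected screening cost
    p_high_risk x annual screening cost (R$80.10 at defaults) per cycle
    while cancer-free.  No one-off testing or surgical cost exists.
    """
    try:
        w1 = params.prob("p_relative_brca1")
        w2 = params.prob("p_relative_brca2")
        expected_screen = params.p_high_risk_algorithm * params.cost(
            "screening_mutation_carrier_annual"
        )
    except ParameterError as exc:
        raise ParameterError(f"cannot build usual-care strategy: {exc}") from exc

    rows = (
        ("brca1", w1, "p_breast_ca_brca1", "p_ov_ca_brca1"),
        ("brca2", w2, "p_breast_ca_brca2", "p_ov_ca_brca2"),
        ("no_mutation", 1.0 - w1 - w2, "p_breast_ca_nomut", "p_ov_ca_nomut"),
    )
    arms = []
    for label, weight, b_name, o_name in rows:
        pb, po = _annual_risks(params, b_name, o_name)
        arms.append(
            Arm(
                label=label,
                weight=weight,
                annual_p_breast=pb,
                annual_p_ovarian=po,
                oneoff_cost=0.0,
                percycle_cost=expected_screen,
            )
        )
    return StrategyModel(name=USUAL_CARE, arms=tuple(arms))


def build_strategies(params: ParameterSet) -> tuple[StrategyModel, StrategyModel]:
    """(testing, usual_care) pair built from one parameter set."""
    return build_testing_strategy(params), build_usual_care_strategy(params)


def arm_table(strategy: StrategyModel) -> pd.DataFrame:
    """Debug dump: one row per arm with weight, annual risks and costs."""
    return pd.DataFrame(
        {
            "strategy": strategy.name,
            "arm": a.label,
            "weight": a.weight,
            "annual_p_breast": a.annual_p_breast,
            "annual_p_ovarian": a.annual_p_ovarian,
            "oneoff_cost": a.oneoff_cost,
            "percycle_cost": a.percycle_cost,
        }
        for a in strategy.arms
    )
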