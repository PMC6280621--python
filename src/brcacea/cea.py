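"""Incremental cost-effectiveness analysis and population arithmetic.

The ICER compares the testing-plus-prophylaxis strategy (intervention)
against usual care (comparator):

    ICER = (C_int - C_comp) / (E_int - E_comp)

A ratio is only meaningful in the trade-off quadrants; an intervention
that is cheaper and more effective is *dominant*, costlier and less
effective *dominated*, and equal effectiveness yields no ratio at all.
Defined ICERs are classified against the willingness-to-pay band
R$7,543.50 - R$23,786.70 per case prevented (both bounds inclusive on the
favourable side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .engine import EFF_PER100, run_cohort, strategy_outcome, StrategyOutcome
from .parameters import ParameterSet
from .strategies import build_strategies

__all__ = [
    "STATUS_ICER",
    "STATUS_DOMINANT",
    "STATUS_DOMINATED",
    "STATUS_NO_TRADEOFF",
    "CLASS_DOMINANT",
    "CLASS_COST_EFFECTIVE_LOW",
    "CLASS_COST_EFFECTIVE_HIGH",
    "CLASS_NOT_COST_EFFECTIVE",
    "CLASS_DOMINATED",
    "CEAResult",
    "icer",
    "classify",
    "eligible_population",
    "expected_screening_cost",
    "full_analysis",
]

STATUS_ICER = "icer"
STATUS_DOMINANT = "dominant"
STATUS_DOMINATED = "dominated"
STATUS_NO_TRADEOFF = "no_tradeoff"

CLASS_DOMINANT = "dominant"
CLASS_COST_EFFECTIVE_LOW = "cost_effective_low"
CLASS_COST_EFFECTIVE_HIGH = "cost_effective_high"
CLASS_NOT_COST_EFFECTIVE = "not_cost_effective"
CLASS_DOMINATED = "dominated"

_DELTA_TOL = 1e-9


@dataclass(frozen=True)
class CEAResult:
    """One intervention-vs-comparator comparison.

    ``icer`` is ``None`` whenever ``status`` is not ``"icer"`` (dominance or
    equal effectiveness); ``classification`` may be ``None`` for a bare
    ratio computation that has not been held against the thresholds yet.
    """

    cost_intervention: float
    cost_comparator: float
    eff_intervention: float
    eff_comparator: float
    delta_cost: float
    delta_eff: float
    status: str
    icer: float | None = None
    classification: str | None = None
    convention: str | None = None
    outcome_intervention: StrategyOutcome | None = None
    outcome_comparator: StrategyOutcome | None = None
    fingerprint: str | None = None


def icer(c1: float, e1: float, c0: float, e0: float) -> CEAResult:
    """Incremental ratio of intervention (c1, e1) over comparator (c0, e0).

    Dominance short-circuits the ratio: cheaper-and-better is dominant,
    costlier-and-worse dominated.  Equal effectiveness (within 1e-9) gives
    no ratio.  A cheaper-and-worse intervention also yields a ratio (the
    south-west quadrant's saving per unit of effect forgone).
    """
    for name, v in (("c1", c1), ("e1", e1), ("c0", c0), ("e0", e0)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    dc = c1 - c0
    de = e1 - e0
    base = dict(
        cost_intervention=c1,
        cost_comparator=c0,
        eff_intervention=e1,
        eff_comparator=e0,
        delta_cost=dc,
        delta_eff=de,
    )
    if abs(de) <= _DELTA_TOL:
        return CEAResult(status=STATUS_NO_TRADEOFF, **base)
    if dc < 0 and de > 0:
        return CEAResult(status=STATUS_DOMINANT, classification=CLASS_DOMINANT, **base)
    if dc > 0 and de < 0:
        return CEAResult(status=STATUS_DOMINATED, classification=CLASS_DOMINATED, **base)
    return CEAResult(status=STATUS_ICER, icer=dc / de, **base)


def classify(icer_value: float, params: ParameterSet) -> str:
    """Hold a defined ICER against the willingness-to-pay band.

    At or below the lower threshold -> ``cost_effective_low`` (cost
    effective even at the strictest willingness to pay); within the band
    -> ``cost_effective_high``; above -> ``not_cost_effective``.  Both
    boundaries are inclusive on the favourable side.
    """
    if not math.isfinite(icer_value):
        raise ValueError(f"icer_value must be finite, got {icer_value!r}")
    if icer_value <= params.threshold_low:
        return CLASS_COST_EFFECTIVE_LOW
    if icer_value <= params.threshold_high:
        return CLASS_COST_EFFECTIVE_HIGH
    return CLASS_NOT_COST_EFFECTIVE


def eligible_population(
    cases_per_year: float,
    prop_mutation: float,
    relatives_per_patient: float,
    transmission: float,
) -> int:
    """Relatives per year eligible for cascade testing, rounded to a count.

    cases x mutation prevalence x female first-degree relatives per patient
    x transmission probability; at the published inputs
    6150 x 0.19 x 3.5 x 0.5 = 2,045.
    """
    for name, v in (
        ("cases_per_year", cases_per_year),
        ("prop_mutation", prop_mutation),
        ("relatives_per_patient", relatives_per_patient),
        ("transmission", transmission),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return round(cases_per_year * prop_mutation * relatives_per_patient * transmission)


def expected_screening_cost(p_high_risk: float, annual_cost: float) -> float:
    """Expected annual screening spend per untested relative, to 2 decimals.

    The risk algorithm refers a fraction ``p_high_risk`` of untested
    relatives to annual breast imaging; the rest incur nothing.
    """
    if not 0.0 <= p_high_risk <= 1.0:
        raise ValueError(f"p_high_risk {p_high_risk} outside [0, 1]")
    if annual_cost < 0:
        raise ValueError(f"annual_cost must be >= 0, got {annual_cost}")
    return round(p_high_risk * annual_cost, 2)


def full_analysis(params: ParameterSet, convention: str = EFF_PER100) -> CEAResult:
    """Build both strategies, run the cohort engine, compare.

    Deterministic given ``params`` and the effectiveness ``convention``;
    the result carries both strategy outcomes, the threshold
    classification, and the parameter-set fingerprint for reproducibility.
    """
    testing, usual = build_strategies(params)
    n, r = params.n_cycles, params.discount_rate
    out_t = strategy_outcome(run_cohort(testing, n, r), convention)
    out_u = strategy_outcome(run_cohort(usual, n, r), convention)

    result = icer(out_t.expected_cost, out_t.effectiveness, out_u.expected_cost, out_u.effectiveness)
    classification = result.classification
    if result.status == STATUS_ICER:
        classification = classify(result.icer, params)  # type: ignore[arg-type]
    return replace(
        result,
        classification=classification,
        convention=convention,
        outcome_intervention=out_t,
        outcome_comparator=out_u,
        fingerprint=params.fingerprint(),
    )
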