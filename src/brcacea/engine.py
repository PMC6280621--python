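"""Annual-cycle Markov cohort engine.

Three health states per arm — ``well``, ``breast_cancer``,
``ovarian_cancer`` — with both cancer states absorbing (no death state; the
outcome of interest is cancer cases, not survival).  Per cycle, well
occupants face the arm's annual breast risk ``p_b`` and ovarian risk
``p_o``; the two transitions compete within a cycle and the joint-event
mass ``p_b * p_o`` is assigned to breast cancer, so

    P(well -> breast)  = p_b
    P(well -> ovarian) = (1 - p_b) * p_o
    P(stay well)       = (1 - p_b) * (1 - p_o)

Accrual conventions (no half-cycle correction):

* one-off costs at cycle 0, undiscounted;
* per-cycle costs for well occupants at the *start* of cycle t, discounted
  by (1+r)^-t, t = 0..n-1;
* a transition during cycle t counts as a new case at t+1, discounted by
  (1+r)^-(t+1);
* effects are discounted at the same rate as costs.

Two effectiveness conventions are supported because the source figures'
units are unstated: a per-100 discounted cancer-free index
(``(1 - E[discounted cases]) * 100``) and discounted cancer-free
person-years (sum of discounted well occupancy over cycle starts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .strategies import StrategyModel

__all__ = [
    "EngineError",
    "STATES",
    "EFF_PER100",
    "EFF_CANCER_FREE_YEARS",
    "EFF_CONVENTIONS",
    "CycleTrace",
    "StrategyOutcome",
    "discount_factor",
    "run_cohort",
    "strategy_outcome",
]

STATES = ("well", "breast_cancer", "ovarian_cancer")
_WELL, _BREAST, _OVARIAN = 0, 1, 2

EFF_PER100 = "per100"
EFF_CANCER_FREE_YEARS = "cancer_free_years"
EFF_CONVENTIONS = (EFF_PER100, EFF_CANCER_FREE_YEARS)

_CONS_TOL = 1e-12


class EngineError(RuntimeError):
    """Internal consistency failure during cohort evolution (never silent)."""


def discount_factor(rate: float, t: int) -> float:
    """Present-value factor (1 + rate)^-t for cycle index ``t``."""
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if not float(t).is_integer() or t < 0:
        raise ValueError(f"t must be a nonnegative integer, got {t!r}")
    return float((1.0 + rate) ** (-t))


@dataclass(frozen=True)
class CycleTrace:
    """Full per-cycle record of one strategy's cohort run.

    Arrays are indexed ``[arm, cycle]``; ``occupancy`` additionally by state.
    Per-arm cost/case accruals are *per person in that arm*; the
    ``expected_*`` properties apply the arm weights.
    """

    strategy_name: str
    arm_labels: tuple[str, ...]
    weights: np.ndarray            # (n_arms,)
    occupancy: np.ndarray          # (n_arms, n_cycles + 1, 3)
    disc_cost: np.ndarray          # (n_arms, n_cycles) incl. one-off at t=0
    disc_cases: np.ndarray         # (n_arms, n_cycles), discounted at t+1
    disc_free_years: np.ndarray    # (n_arms, n_cycles) discounted well occupancy
    rate: float
    n_cycles: int

    @property
    def expected_cost(self) -> float:
        return float(self.weights @ self.disc_cost.sum(axis=1))

    @property
    def expected_cases(self) -> float:
        return float(self.weights @ self.disc_cases.sum(axis=1))

    @property
    def cancer_free_years(self) -> float:
        return float(self.weights @ self.disc_free_years.sum(axis=1))

    def cumulative(self) -> pd.DataFrame:
        """Weighted cumulative discounted cost and cases per cycle."""
        cost = np.cumsum(self.weights @ self.disc_cost)
        cases = np.cumsum(self.weights @ self.disc_cases)
        return pd.DataFrame(
            {"cycle": np.arange(self.n_cycles), "cum_disc_cost": cost, "cum_disc_cases": cases}
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (arm, cycle, state).

        Occupancy is evaluated at cycle start; the per-cycle discounted
        cost/case accruals of that (arm, cycle) are repeated on each of its
        three state rows (they are arm-level, not state-level, quantities).
        """
        rows = []
        for i, label in enumerate(self.arm_labels):
            for t in range(self.n_cycles + 1):
                in_horizon = t < self.n_cycles
                for s, state in enumerate(STATES):
                    rows.append(
                        {
                            "strategy": self.strategy_name,
                            "arm": label,
                            "weight": self.weights[i],
                            "cycle": t,
                            "state": state,
                            "occupancy": self.occupancy[i, t, s],
                            "disc_cost": self.disc_cost[i, t] if in_horizon else 0.0,
                            "disc_cases": self.disc_cases[i, t] if in_horizon else 0.0,
                        }
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted expectations for one strategy, on a chosen effectiveness scale."""

    strategy_name: str
    expected_cost: float
    expected_cases: float
    cancer_free_years: float
    effectiveness: float
    convention: str


def run_cohort(strategy: StrategyModel, n_cycles: int, rate: float) -> CycleTrace:
    """Evolve every arm of ``strategy`` over ``n_cycles`` annual cycles.

    Raises
    ------
    EngineError
        If occupancy conservation (each arm's state vector summing to 1
        within 1e-12) is breached at any cycle.
    """
    if not float(n_cycles).is_integer() or n_cycles < 1:
        raise ValueError(f"n_cycles must be a positive integer, got {n_cycles!r}")
    n_cycles = int(n_cycles)

    arms = strategy.arms
    A = len(arms)
    w = np.array([a.weight for a in arms])
    pb = np.array([a.annual_p_breast for a in arms])
    po = np.array([a.annual_p_ovarian for a in arms])
    oneoff = np.array([a.oneoff_cost for a in arms])
    percyc = np.array([a.percycle_cost for a in arms])

    df = (1.0 + rate) ** (-np.arange(n_cycles + 1, dtype=float))

    occ = np.zeros((A, n_cycles + 1, 3))
    occ[:, 0, _WELL] = 1.0
    cost = np.zeros((A, n_cycles))
    cases = np.zeros((A, n_cycles))
    free = np.zeros((A, n_cycles))
    cost[:, 0] += oneoff  # charged at cycle 0, undiscounted

    for t in range(n_cycles):
        well = occ[:, t, _WELL]
        cost[:, t] += percyc * well * df[t]
        free[:, t] = well * df[t]
        new_breast = well * pb
        new_ovarian = well * (1.0 - pb) * po
        cases[:, t] = (new_breast + new_ovarian) * df[t + 1]
        occ[:, t + 1, _WELL] = well * (1.0 - pb) * (1.0 - po)
        occ[:, t + 1, _BREAST] = occ[:, t, _BREAST] + new_breast
        occ[:, t + 1, _OVARIAN] = occ[:, t, _OVARIAN] + new_ovarian
        total = occ[:, t + 1].sum(axis=1)
        if np.any(np.abs(total - 1.0) > _CONS_TOL) or np.any(occ[:, t + 1] < -_CONS_TOL):
            worst = int(np.argmax(np.abs(total - 1.0)))
            raise EngineError(
                f"occupancy conservation breached at cycle {t + 1}, arm "
                f"{arms[worst].label!r}: states sum to {total[worst]!r}"
            )

    return CycleTrace(
        strategy_name=strategy.name,
        arm_labels=tuple(a.label for a in arms),
        weights=w,
        occupancy=occ,
        disc_cost=cost,
        disc_cases=cases,
        disc_free_years=free,
        rate=rate,
        n_cycles=n_cycles,
    )


def strategy_outcome(trace: CycleTrace, convention: str = EFF_PER100) -> StrategyOutcome:
    """Collapse a trace into (cost, cases, effectiveness) totals.

    ``convention`` selects the effectiveness scale: ``"per100"`` gives
    (1 - discounted cases) x 100; ``"cancer_free_years"`` gives discounted
    cancer-free person-years.
    """
    if convention not in EFF_CONVENTIONS:
        raise ValueError(f"unknown effectiveness convention {convention!r}; choose from {EFF_CONVENTIONS}")
    cases = trace.expected_cases
    free_years = trace.cancer_free_years
    eff = (1.0 - cases) * 100.0 if convention == EFF_PER100 else free_years
    return StrategyOutcome(
        strategy_name=trace.strategy_name,
        expected_cost=trace.expected_cost,
        expected_cases=cases,
        cancer_free_years=free_years,
        effectiveness=eff,
        convention=convention,
    )
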