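"""Individual-level Monte-Carlo oracle for the cohort engine.

Simulates annual Bernoulli trajectories for ``n`` synthetic relatives:
each individual draws an arm by its weight, then faces the identical
per-cycle risks, cost schedule, discounting and breast-first tie-break the
cohort engine applies to expected values.  By the law of large numbers the
sample means converge on the cohort expectations, which makes this module
both the package's synthetic-data generator and an independent check on
the deterministic engine.

Randomness comes from a counter-based Philox generator keyed by the seed.
Draws are made for *all* individuals at every cycle, whether or not their
state can still change, so individual ``i``'s randomness occupies fixed
counter positions: results are bit-reproducible for a seed and invariant
to how trajectories are stored or traversed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import STATES
from .strategies import StrategyModel

__all__ = [
    "MicrosimEstimate",
    "simulate",
    "simulate_trajectories",
    "write_trajectories",
    "read_trajectories",
]

_WELL, _BREAST, _OVARIAN = 0, 1, 2

_TRAJ_COLUMNS = ("individual", "arm", "terminal_state", "case_cycle", "disc_cost", "disc_cases")


@dataclass(frozen=True)
class MicrosimEstimate:
    """Sample means with standard errors from ``n`` simulated relatives."""

    n: int
    seed: int
    mean_cost: float
    se_cost: float
    mean_cases: float
    se_cases: float
    mean_free_years: float
    se_free_years: float


def _simulate_arrays(
    strategy: StrategyModel, n: int, seed: int, n_cycles: int, rate: float
) -> dict[str, np.ndarray]:
    if n < 2:
        raise ValueError(f"n must be >= 2 (standard errors need a sample), got {n}")
    if not float(n_cycles).is_integer() or n_cycles < 1:
        raise ValueError(f"n_cycles must be a positive integer, got {n_cycles!r}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    n, n_cycles = int(n), int(n_cycles)

    arms = strategy.arms
    weights = np.array([a.weight for a in arms])
    pb = np.array([a.annual_p_breast for a in arms])
    po = np.array([a.annual_p_ovarian for a in arms])
    oneoff = np.array([a.oneoff_cost for a in arms])
    percyc = np.array([a.percycle_cost for a in arms])
    df = (1.0 + rate) ** (-np.arange(n_cycles + 2, dtype=float))

    rng = np.random.Generator(np.random.Philox(seed))
    arm = np.searchsorted(np.cumsum(weights), rng.random(n), side="right")
    arm = np.minimum(arm, len(arms) - 1)  # guard the top edge against fp roundoff

    state = np.zeros(n, dtype=np.int8)
    cost = oneoff[arm].copy()
    disc_cases = np.zeros(n)
    free_years = np.zeros(n)
    case_cycle = np.full(n, -1, dtype=np.int64)

    for t in range(n_cycles):
        # draws for everyone each cycle -> fixed counter positions per individual
        u_breast = rng.random(n)
        u_ovarian = rng.random(n)
        well = state == _WELL
        cost[well] += percyc[arm[well]] * df[t]
        free_years[well] += df[t]
        to_breast = well & (u_breast < pb[arm])
        to_ovarian = well & ~to_breast & (u_ovarian < po[arm])
        state[to_breast] = _BREAST
        state[to_ovarian] = _OVARIAN
        new_case = to_breast | to_ovarian
        disc_cases[new_case] += df[t + 1]
        case_cycle[new_case] = t

    return {
        "arm": arm,
        "state": state,
        "cost": cost,
        "disc_cases": disc_cases,
        "free_years": free_years,
        "case_cycle": case_cycle,
    }


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


def simulate(
    strategy: StrategyModel, n: int, seed: int, n_cycles: int = 40, rate: float = 0.05
) -> MicrosimEstimate:
    """Monte-Carlo estimate of one strategy's discounted cost and cases.

    Bit-reproducible for a fixed ``(strategy, n, seed, n_cycles, rate)``.
    Standard errors use the between-individual sample variance (ddof=1).
    """
    a = _simulate_arrays(strategy, n, seed, n_cycles, rate)
    mean_cost, se_cost = _mean_se(a["cost"])
    mean_cases, se_cases = _mean_se(a["disc_cases"])
    mean_free, se_free = _mean_se(a["free_years"])
    return MicrosimEstimate(
        n=int(n),
        seed=int(seed),
        mean_cost=mean_cost,
        se_cost=se_cost,
        mean_cases=mean_cases,
        se_cases=se_cases,
        mean_free_years=mean_free,
        se_free_years=se_free,
    )


def simulate_trajectories(
    strategy: StrategyModel, n: int, seed: int, n_cycles: int = 40, rate: float = 0.05
) -> pd.DataFrame:
    """Per-individual records: arm, terminal state, case cycle, discounted cost.

    Shares the random stream with :func:`simulate`, so the frame's column
    means reproduce the estimate's means exactly for the same arguments.
    """
    a = _simulate_arrays(strategy, n, seed, n_cycles, rate)
    labels = np.array([arm.label for arm in strategy.arms])
    return pd.DataFrame(
        {
            "individual": np.arange(n, dtype=np.int64),
            "arm": labels[a["arm"]],
            "terminal_state": np.array(STATES)[a["state"]],
            "case_cycle": pd.array(
                np.where(a["case_cycle"] >= 0, a["case_cycle"], pd.NA), dtype="Int64"
            ),
            "disc_cost": a["cost"],
            "disc_cases": a["disc_cases"],
        }
    )


def write_trajectories(trajectories: pd.DataFrame, path: str | Path) -> None:
    """CSV export, one row per simulated individual (round-trippable)."""
    missing = [c for c in _TRAJ_COLUMNS if c not in trajectories.columns]
    if missing:
        raise ValueError(f"trajectory frame missing columns: {missing}")
    trajectories.loc[:, list(_TRAJ_COLUMNS)].to_csv(path, index=False)


def read_trajectories(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back with the exact dtypes ``write`` produced."""
    return pd.read_csv(
        path,
        float_precision="round_trip",
        dtype={
            "individual": "int64",
            "arm": "string",
            "terminal_state": "string",
            "case_cycle": "Int64",
            "disc_cost": "float64",
            "disc_cases": "float64",
        },
    ).astype({"arm": object, "terminal_state": object})
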