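"""One-way deterministic sensitivity analysis (tornado diagram data).

Each probability that carries a 95% range is pushed to its low and high
bound in turn, all other inputs held at their point values, and the full
analysis is recomputed at each excursion.  Entries are ranked by the
absolute ICER spread, largest first — the order the tornado diagram plots.
Parameters without a published range are not swept (no invented spreads);
an excursion that destroys the trade-off structure (dominance or equal
effectiveness) is flagged on the entry, never raised.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import pandas as pd

from .cea import CEAResult, STATUS_ICER, full_analysis
from .engine import EFF_PER100
from .parameters import ParameterSet

__all__ = ["TornadoEntry", "DSAResult", "one_way_dsa", "restore_check", "tornado_frame", "plot_tornado"]


@dataclass(frozen=True)
class TornadoEntry:
    """One parameter's low/high ICER excursion."""

    parameter: str
    low: float
    high: float
    icer_at_low: float | None
    icer_at_high: float | None
    status_at_low: str
    status_at_high: str
    classification_at_low: str | None
    classification_at_high: str | None
    spread: float

    @property
    def structural(self) -> bool:
        """True if either excursion left quadrant I (no defined ICER)."""
        return self.status_at_low != STATUS_ICER or self.status_at_high != STATUS_ICER


@dataclass(frozen=True)
class DSAResult:
    baseline: CEAResult
    entries: tuple[TornadoEntry, ...]
    convention: str


def _entry(params: ParameterSet, name: str, convention: str) -> TornadoEntry:
    p = params.probs[name]
    res_low = full_analysis(params.with_prob_point(name, p.low), convention)
    res_high = full_analysis(params.with_prob_point(name, p.high), convention)
    if res_low.icer is not None and res_high.icer is not None:
        spread = abs(res_high.icer - res_low.icer)
    else:
        # a structural break is the largest possible excursion; rank it first
        spread = float("inf")
    return TornadoEntry(
        parameter=name,
        low=p.low,  # type: ignore[arg-type]
        high=p.high,  # type: ignore[arg-type]
        icer_at_low=res_low.icer,
        icer_at_high=res_high.icer,
        status_at_low=res_low.status,
        status_at_high=res_high.status,
        classification_at_low=res_low.classification,
        classification_at_high=res_high.classification,
        spread=spread,
    )


def one_way_dsa(params: ParameterSet, convention: str = EFF_PER100) -> DSAResult:
    """Sweep every ranged probability; entries sorted by spread, descending.

    Ties (and the deterministic order generally) break alphabetically by
    parameter name.  ``params`` is never mutated; every excursion works on
    a derived copy.
    """
    ranged = sorted(name for name, p in params.probs.items() if p.has_range)
    entries = [_entry(params, name, convention) for name in ranged]
    entries.sort(key=lambda e: (-e.spread, e.parameter))
    return DSAResult(
        baseline=full_analysis(params, convention),
        entries=tuple(entries),
        convention=convention,
    )


def _baseline_blob(params: ParameterSet, convention: str) -> str:
    res = full_analysis(params, convention)
    d = asdict(res)
    return json.dumps(d, sort_keys=True, default=repr)


def restore_check(params: ParameterSet, convention: str = EFF_PER100) -> dict:
    """Guard against stateful mutation: baseline must survive a sweep bit-for-bit.

    Runs the baseline analysis, the full sweep, then the baseline again and
    compares the two baseline serialisations exactly.  Returns a report
    dict; raises ``RuntimeError`` if the baselines differ (shared parameter
    state was mutated somewhere).
    """
    before = _baseline_blob(params, convention)
    result = one_way_dsa(params, convention)
    after = _baseline_blob(params, convention)
    if before != after:
        raise RuntimeError("baseline analysis changed across the DSA sweep: parameter state was mutated")
    return {
        "consistent": True,
        "n_ranged_parameters": len(result.entries),
        "baseline_icer": result.baseline.icer,
        "convention": convention,
    }


def tornado_frame(result: DSAResult) -> pd.DataFrame:
    """Tornado table: parameter, bounds, ICER excursions, spread, rank."""
    return pd.DataFrame(
        {
            "parameter": e.parameter,
            "low": e.low,
            "high": e.high,
            "icer_low": e.icer_at_low,
            "icer_high": e.icer_at_high,
            "spread": e.spread,
            "rank": rank,
            "structural_break": e.structural,
        }
        for rank, e in enumerate(result.entries, start=1)
    )


def plot_tornado(result: DSAResult, path: str, max_entries: int = 15) -> None:
    """Render the tornado diagram to ``path`` (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = [e for e in result.entries if not e.structural][:max_entries]
    base = result.baseline.icer
    if base is None or not entries:
        raise ValueError("tornado plot needs a defined baseline ICER and at least one non-structural entry")
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(entries) + 1.5))
    ypos = range(len(entries))[::-1]
    for y, e in zip(ypos, entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))  # type: ignore[type-var]
        ax.barh(y, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.axvline(base, color="black", lw=1, ls="--", label=f"baseline {base:,.2f}")
    ax.set_yticks(list(ypos))
    ax.set_yticklabels([e.parameter for e in entries], fontsize=8)
    ax.set_xlabel("ICER (BRL per unit effectiveness)")
    ax.set_title("One-way deterministic sensitivity analysis")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
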