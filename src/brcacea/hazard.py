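"""Constant-hazard bridge between cumulative and annual cancer risks.

The published penetrance figures are cumulative probabilities over the
40-year horizon (ages 30-70); the cohort engine needs a per-annual-cycle
transition probability.  Under a constant hazard the two are linked by
complement compounding:

    p_annual = 1 - (1 - p_lifetime)^(1/n)        (and its inverse)

which is the only reconstruction a single cumulative figure supports.
"""

from __future__ import annotations

import math

__all__ = ["lifetime_to_annual", "annual_to_lifetime"]


def _check_n_years(n_years: int) -> None:
    if not float(n_years).is_integer() or n_years < 1:
        raise ValueError(f"n_years must be a positive integer, got {n_years!r}")


def lifetime_to_annual(p_lifetime: float, n_years: int) -> float:
    """Per-cycle probability whose n-year compounding equals ``p_lifetime``.

    Raises
    ------
    ValueError
        If ``p_lifetime`` is 1 or more (the implied hazard is infinite) or
        negative, or if ``n_years`` is not a positive integer.
    """
    _check_n_years(n_years)
    if not 0.0 <= p_lifetime < 1.0:
        raise ValueError(
            f"p_lifetime must lie in [0, 1), got {p_lifetime!r} "
            "(a certain event has no finite annual hazard)"
        )
    return -math.expm1(math.log1p(-p_lifetime) / n_years)


def annual_to_lifetime(p_annual: float, n_years: int) -> float:
    """Cumulative probability after ``n_years`` cycles at a constant annual risk."""
    _check_n_years(n_years)
    if not 0.0 <= p_annual < 1.0:
        raise ValueError(f"p_annual must lie in [0, 1), got {p_annual!r}")
    return -math.expm1(n_years * math.log1p(-p_annual))
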