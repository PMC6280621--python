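"""Model inputs: probabilities, unit costs and structural constants.

Every quantity driving the model lives in a :class:`ParameterSet`, loaded
from a YAML/JSON file (or the packaged default) with two top-level maps,
``probabilities`` and ``costs``, plus a ``structure`` map of scalars.
The set is immutable; the sensitivity module derives perturbed copies via
:meth:`ParameterSet.with_prob_point` so a sweep can never corrupt shared
state.

Probabilities optionally carry a 95% range (``low``/``high``); parameters
without a range are held fixed in the deterministic sensitivity analysis
rather than being assigned an invented spread.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ParameterError",
    "ProbParam",
    "CostParam",
    "ParameterSet",
    "load_parameters",
    "default_parameters",
    "save_parameters",
    "validate",
    "REQUIRED_PROB_NAMES",
    "REQUIRED_COST_NAMES",
    "ONE_OFF",
    "PER_CYCLE",
]


class ParameterError(ValueError):
    """Raised when a parameter file cannot be loaded into a valid set."""


ONE_OFF = "one_off"
PER_CYCLE = "per_cycle"
_RECURRENCES = (ONE_OFF, PER_CYCLE)

#: Canonical probability names the model structure depends on.
REQUIRED_PROB_NAMES: tuple[str, ...] = (
    "p_relative_brca1",
    "p_relative_brca2",
    "p_adhere_mastectomy",
    "p_adhere_rrso",
    "p_breast_ca_brca1",
    "p_breast_ca_brca2",
    "p_breast_ca_nomut",
    "p_ov_ca_brca1",
    "p_ov_ca_brca2",
    "p_ov_ca_nomut",
    "p_breast_ca_brca1_post_mx",
    "p_breast_ca_brca2_post_mx",
    "p_breast_ca_brca1_post_rrso",
    "p_breast_ca_brca2_post_rrso",
    "p_breast_ca_brca1_post_both",
    "p_breast_ca_brca2_post_both",
    "p_ov_ca_brca1_post_rrso",
    "p_ov_ca_brca2_post_rrso",
    "p_high_risk_algorithm",
)

#: Canonical cost names (2014 BRL).
REQUIRED_COST_NAMES: tuple[str, ...] = (
    "counseling",
    "ngs_plus_mlpa",
    "mastectomy",
    "rrso",
    "screening_mutation_carrier_annual",
    "screening_high_risk_annual",
)

#: Extra parameters are admitted only under this name prefix.
EXTRA_PREFIX = "extra_"


@dataclass(frozen=True)
class ProbParam:
    """A point probability with an optional 95% range and a citation tag."""

    name: str
    point: float
    low: float | None = None
    high: float | None = None
    source: str = ""

    @property
    def has_range(self) -> bool:
        return self.low is not None and self.high is not None

    def violations(self) -> list[str]:
        v: list[str] = []
        if not 0.0 <= self.point <= 1.0:
            v.append(f"{self.name}: point {self.point} outside [0, 1]")
        if (self.low is None) != (self.high is None):
            v.append(f"{self.name}: range must give both low and high or neither")
        if self.has_range:
            if not 0.0 <= self.low:  # type: ignore[operator]
                v.append(f"{self.name}: low {self.low} < 0")
            if not self.high <= 1.0:  # type: ignore[operator]
                v.append(f"{self.name}: high {self.high} > 1")
            if not self.low <= self.point:  # type: ignore[operator]
                v.append(f"{self.name}: low {self.low} must be <= point {self.point}")
            if not self.point <= self.high:  # type: ignore[operator]
                v.append(f"{self.name}: point {self.point} must be <= high {self.high}")
        return v


@dataclass(frozen=True)
class CostParam:
    """A unit cost in 2014 BRL, charged once or per annual cycle."""

    name: str
    amount: float
    recurrence: str = ONE_OFF

    def violations(self) -> list[str]:
        v: list[str] = []
        if not self.amount >= 0.0:
            v.append(f"{self.name}: amount {self.amount} must be >= 0")
        if self.recurrence not in _RECURRENCES:
            v.append(
                f"{self.name}: recurrence {self.recurrence!r} must be one of "
                f"{_RECURRENCES}"
            )
        return v


@dataclass(frozen=True)
class ParameterSet:
    """Immutable bundle of every input the model consumes.

    ``probs`` and ``costs`` are keyed by canonical name; structural scalars
    (horizon, discount rate, prevalences, thresholds, population counts)
    are plain fields.  ``n_cycles`` is derived: one annual cycle per year of
    the age horizon (40 at the defaults, ages 30 to 70).
    """

    probs: Mapping[str, ProbParam]
    costs: Mapping[str, CostParam]
    discount_rate: float = 0.05
    age_start: int = 30
    age_end: int = 70
    prevalence_brca1_patients: float = 0.17
    prevalence_brca2_patients: float = 0.02
    threshold_low: float = 7543.50
    threshold_high: float = 23786.70
    annual_ov_cancer_cases: float = 6150
    relatives_per_patient: float = 3.5
    transmission_prob: float = 0.5

    @property
    def n_cycles(self) -> int:
        return int(self.age_end - self.age_start)

    @property
    def p_high_risk_algorithm(self) -> float:
        return self.prob("p_high_risk_algorithm")

    def prob(self, name: str) -> float:
        """Point value of a probability parameter; loud error if absent."""
        try:
            return self.probs[name].point
        except KeyError:
            raise ParameterError(f"missing required probability parameter {name!r}") from None

    def cost(self, name: str) -> float:
        try:
            return self.costs[name].amount
        except KeyError:
            raise ParameterError(f"missing required cost parameter {name!r}") from None

    def with_prob_point(self, name: str, point: float) -> "ParameterSet":
        """A new set with one probability's point moved (range preserved).

        Used by the sensitivity sweep; ``low``/``high`` ordering is not
        re-enforced here because an excursion sets the point *to* a bound.
        """
        if name not in self.probs:
            raise ParameterError(f"missing required probability parameter {name!r}")
        probs = dict(self.probs)
        probs[name] = dataclasses.replace(probs[name], point=point)
        return dataclasses.replace(self, probs=probs)

    def with_cost_amount(self, name: str, amount: float) -> "ParameterSet":
        if name not in self.costs:
            raise ParameterError(f"missing required cost parameter {name!r}")
        costs = dict(self.costs)
        costs[name] = dataclasses.replace(costs[name], amount=amount)
        return dataclasses.replace(self, costs=costs)

    def to_dict(self) -> dict[str, Any]:
        """Serialise back to the file schema (probabilities/costs/structure)."""
        probs: dict[str, Any] = {}
        for name, p in self.probs.items():
            d: dict[str, Any] = {"point": p.point}
            if p.low is not None:
                d["low"] = p.low
            if p.high is not None:
                d["high"] = p.high
            if p.source:
                d["source"] = p.source
            probs[name] = d
        costs = {
            name: {"amount": c.amount, "recurrence": c.recurrence}
            for name, c in self.costs.items()
        }
        structure = {
            "discount_rate": self.discount_rate,
            "age_start": self.age_start,
            "age_end": self.age_end,
            "prevalence_brca1_patients": self.prevalence_brca1_patients,
            "prevalence_brca2_patients": self.prevalence_brca2_patients,
            "threshold_low": self.threshold_low,
            "threshold_high": self.threshold_high,
            "annual_ov_cancer_cases": self.annual_ov_cancer_cases,
            "relatives_per_patient": self.relatives_per_patient,
            "transmission_prob": self.transmission_prob,
        }
        return {"probabilities": probs, "costs": costs, "structure": structure}

    def fingerprint(self) -> str:
        """SHA-256 of the canonical JSON serialisation (key-order invariant)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()


_STRUCTURE_FIELDS = (
    "discount_rate",
    "age_start",
    "age_end",
    "prevalence_brca1_patients",
    "prevalence_brca2_patients",
    "threshold_low",
    "threshold_high",
    "annual_ov_cancer_cases",
    "relatives_per_patient",
    "transmission_prob",
)


def _parse_prob(name: str, raw: Any) -> ProbParam:
    if isinstance(raw, (int, float)):
        raw = {"point": raw}
    if not isinstance(raw, Mapping) or "point" not in raw:
        raise ParameterError(f"probability {name!r}: expected a map with a 'point' entry")
    unknown = set(raw) - {"point", "low", "high", "source"}
    if unknown:
        raise ParameterError(f"probability {name!r}: unknown keys {sorted(unknown)}")
    return ProbParam(
        name=name,
        point=float(raw["point"]),
        low=None if raw.get("low") is None else float(raw["low"]),
        high=None if raw.get("high") is None else float(raw["high"]),
        source=str(raw.get("source", "")),
    )


def _parse_cost(name: str, raw: Any) -> CostParam:
    if isinstance(raw, (int, float)):
        raw = {"amount": raw}
    if not isinstance(raw, Mapping) or "amount" not in raw:
        raise ParameterError(f"cost {name!r}: expected a map with an 'amount' entry")
    unknown = set(raw) - {"amount", "recurrence"}
    if unknown:
        raise ParameterError(f"cost {name!r}: unknown keys {sorted(unknown)}")
    return CostParam(
        name=name,
        amount=float(raw["amount"]),
        recurrence=str(raw.get("recurrence", ONE_OFF)),
    )


def _default_text() -> str:
    return (
        resources.files("brcacea.data")
        .joinpath("default_parameters.yaml")
        .read_text(encoding="utf-8")
    )


def load_parameters(source: str | Path | None = None) -> ParameterSet:
    """Load and validate a :class:`ParameterSet`.

    Parameters
    ----------
    source
        Path to a YAML or JSON parameter file, or ``None`` / ``"default"``
        for the packaged defaults (the published model inputs).

    Raises
    ------
    ParameterError
        On schema problems, missing required names, or any invariant
        violation — loading never returns a set that fails :func:`validate`.
    """
    if source is None or source == "default":
        text = _default_text()
        label = "<packaged default>"
    else:
        path = Path(source)
        if not path.exists():
            raise ParameterError(f"parameter file not found: {path}")
        text = path.read_text(encoding="utf-8")
        label = str(path)

    try:
        raw = yaml.safe_load(text)  # YAML is a JSON superset: both dialects accepted
    except yaml.YAMLError as exc:
        raise ParameterError(f"{label}: cannot parse parameter file: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ParameterError(f"{label}: parameter file must be a mapping")
    unknown_top = set(raw) - {"probabilities", "costs", "structure"}
    if unknown_top:
        raise ParameterError(f"{label}: unknown top-level sections {sorted(unknown_top)}")

    probs = {
        str(name): _parse_prob(str(name), entry)
        for name, entry in (raw.get("probabilities") or {}).items()
    }
    costs = {
        str(name): _parse_cost(str(name), entry)
        for name, entry in (raw.get("costs") or {}).items()
    }

    structure = dict(raw.get("structure") or {})
    unknown_struct = set(structure) - set(_STRUCTURE_FIELDS)
    if unknown_struct:
        raise ParameterError(f"{label}: unknown structure fields {sorted(unknown_struct)}")
    kwargs: dict[str, Any] = {}
    for fld in _STRUCTURE_FIELDS:
        if fld in structure:
            kwargs[fld] = (
                int(structure[fld]) if fld in ("age_start", "age_end") else float(structure[fld])
            )

    params = ParameterSet(probs=probs, costs=costs, **kwargs)
    problems = validate(params)
    if problems:
        raise ParameterError(f"{label}: invalid parameter set:\n  " + "\n  ".join(problems))
    return params


def default_parameters() -> ParameterSet:
    """The packaged default inputs (the published model's Tables of inputs)."""
    return load_parameters(None)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a parameter set back out as YAML (round-trips with load)."""
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=True, default_flow_style=False),
        encoding="utf-8",
    )


def validate(params: ParameterSet) -> list[str]:
    """Return every invariant violation in the set (empty list iff valid).

    Violations are returned, never raised, so callers can report all of them
    at once; :func:`load_parameters` turns a non-empty list into a
    :class:`ParameterError`.
    """
    v: list[str] = []
    for name in REQUIRED_PROB_NAMES:
        if name not in params.probs:
            v.append(f"missing required probability parameter {name!r}")
    for name in REQUIRED_COST_NAMES:
        if name not in params.costs:
            v.append(f"missing required cost parameter {name!r}")
    for name in params.probs:
        if name not in REQUIRED_PROB_NAMES and not name.startswith(EXTRA_PREFIX):
            v.append(
                f"unknown probability parameter {name!r} "
                f"(prefix extras with {EXTRA_PREFIX!r})"
            )
    for name in params.costs:
        if name not in REQUIRED_COST_NAMES and not name.startswith(EXTRA_PREFIX):
            v.append(f"unknown cost parameter {name!r} (prefix extras with {EXTRA_PREFIX!r})")

    for p in params.probs.values():
        v.extend(p.violations())
    for c in params.costs.values():
        v.extend(c.violations())

    if not params.age_end > params.age_start:
        v.append(f"age_end {params.age_end} must be > age_start {params.age_start}")
    if not params.discount_rate >= 0.0:
        v.append(f"discount_rate {params.discount_rate} must be >= 0")
    for fld in ("prevalence_brca1_patients", "prevalence_brca2_patients", "transmission_prob"):
        val = getattr(params, fld)
        if not 0.0 <= val <= 1.0:
            v.append(f"{fld} {val} outside [0, 1]")
    if params.prevalence_brca1_patients + params.prevalence_brca2_patients > 1.0:
        v.append("prevalence_brca1_patients + prevalence_brca2_patients exceeds 1")
    if not 0.0 < params.threshold_low <= params.threshold_high:
        v.append(
            f"thresholds must satisfy 0 < low <= high, got "
            f"{params.threshold_low} / {params.threshold_high}"
        )
    if not params.annual_ov_cancer_cases >= 0:
        v.append(f"annual_ov_cancer_cases {params.annual_ov_cancer_cases} must be >= 0")
    if not params.relatives_per_patient >= 0:
        v.append(f"relatives_per_patient {params.relatives_per_patient} must be >= 0")

    if "p_relative_brca1" in params.probs and "p_relative_brca2" in params.probs:
        tot = params.prob("p_relative_brca1") + params.prob("p_relative_brca2")
        if tot > 1.0 + 1e-12:
            v.append(f"carrier probabilities sum to {tot} > 1")
    return v
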