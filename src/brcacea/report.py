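"""Result-document assembly and human-readable reporting.

``build_document`` gathers everything one run produced — strategy
outcomes, the incremental comparison, threshold verdict, optional tornado
and microsimulation sections, and the population arithmetic — into a
plain-JSON-serialisable dict.  ``render_report`` turns such a document
into a markdown summary.  Monetary figures render with 2 decimals and a
BRL label; internal arithmetic is never rounded, which is why a ratio of
printed rounded numbers can differ from the full-precision ICER.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

from . import __version__
from .cea import CEAResult, STATUS_ICER, eligible_population, expected_screening_cost
from .microsim import MicrosimEstimate
from .parameters import ParameterSet
from .sensitivity import DSAResult

__all__ = ["ReportError", "build_document", "render_report", "write_document", "load_document"]


class ReportError(KeyError):
    """A result document is missing a field the report needs."""


def _outcome_dict(outcome: Any) -> dict:
    return dataclasses.asdict(outcome)


def build_document(
    params: ParameterSet,
    result: CEAResult,
    dsa: DSAResult | None = None,
    microsim: dict[str, MicrosimEstimate] | None = None,
) -> dict:
    """Assemble the JSON result document for one analysis run."""
    prop_mutation = params.prevalence_brca1_patients + params.prevalence_brca2_patients
    doc: dict[str, Any] = {
        "schema": "brcacea/result/v1",
        "version": __version__,
        "parameter_fingerprint": result.fingerprint or params.fingerprint(),
        "convention": result.convention,
        "strategies": {
            "testing": _outcome_dict(result.outcome_intervention),
            "usual_care": _outcome_dict(result.outcome_comparator),
        },
        "incremental": {
            "delta_cost": result.delta_cost,
            "delta_eff": result.delta_eff,
            "status": result.status,
            "icer": result.icer,
            "classification": result.classification,
        },
        "thresholds": {"low": params.threshold_low, "high": params.threshold_high},
        "population": {
            "annual_ov_cancer_cases": params.annual_ov_cancer_cases,
            "prop_mutation": prop_mutation,
            "relatives_per_patient": params.relatives_per_patient,
            "transmission_prob": params.transmission_prob,
            "eligible_relatives_per_year": eligible_population(
                params.annual_ov_cancer_cases,
                prop_mutation,
                params.relatives_per_patient,
                params.transmission_prob,
            ),
            "expected_screening_cost_per_year": expected_screening_cost(
                params.p_high_risk_algorithm,
                params.cost("screening_mutation_carrier_annual"),
            ),
        },
        "dsa": None,
        "microsim": None,
    }
    if dsa is not None:
        doc["dsa"] = {
            "baseline_icer": dsa.baseline.icer,
            "convention": dsa.convention,
            "entries": [dataclasses.asdict(e) for e in dsa.entries],
        }
    if microsim is not None:
        doc["microsim"] = {name: dataclasses.asdict(est) for name, est in microsim.items()}
    return doc


def write_document(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def load_document(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def _get(doc: dict, *keys: str) -> Any:
    node: Any = doc
    for key in keys:
        if not isinstance(node, dict) or key not in node:
            raise ReportError(".".join(keys))
        node = node[key]
    return node


def _brl(x: float) -> str:
    return f"R${x:,.2f}"


def render_report(doc: dict) -> str:
    """Markdown summary of a result document.

    Raises
    ------
    ReportError
        Naming the first missing field if the document does not follow the
        result schema.
    """
    lines: list[str] = []
    lines.append("# Cascade BRCA1/2 testing cost-effectiveness report")
    lines.append("")
    lines.append(f"- package version: {_get(doc, 'version')}")
    lines.append(f"- parameter fingerprint: `{_get(doc, 'parameter_fingerprint')[:16]}...`")
    lines.append(f"- effectiveness convention: {_get(doc, 'convention')}")
    lines.append("")

    lines.append("## Strategy outcomes (per relative, discounted)")
    lines.append("")
    lines.append("| strategy | expected cost | discounted cases | effectiveness |")
    lines.append("|---|---|---|---|")
    for name in ("testing", "usual_care"):
        out = _get(doc, "strategies", name)
        lines.append(
            f"| {name} | {_brl(_get(out, 'expected_cost'))} "
            f"| {_get(out, 'expected_cases'):.4f} "
            f"| {_get(out, 'effectiveness'):.2f} |"
        )
    lines.append("")

    inc = _get(doc, "incremental")
    thresholds = _get(doc, "thresholds")
    lines.append("## Incremental comparison")
    lines.append("")
    lines.append(f"- incremental cost: {_brl(_get(inc, 'delta_cost'))}")
    lines.append(f"- incremental effectiveness: {_get(inc, 'delta_eff'):.4f}")
    status = _get(inc, "status")
    if status == STATUS_ICER:
        lines.append(f"- ICER: {_brl(_get(inc, 'icer'))} per unit effectiveness")
    else:
        lines.append(f"- ICER: not defined ({status})")
    lines.append(
        f"- verdict: **{_get(inc, 'classification')}** against the threshold band "
        f"{_brl(_get(thresholds, 'low'))} - {_brl(_get(thresholds, 'high'))}"
    )
    lines.append("")

    lines.append("## Sensitivity analysis (tornado)")
    lines.append("")
    dsa = doc.get("dsa")
    if dsa is None:
        lines.append("not run")
    else:
        entries = _get(dsa, "entries")
        lines.append(f"baseline ICER {_brl(_get(dsa, 'baseline_icer'))}; top excursions:")
        lines.append("")
        lines.append("| rank | parameter | ICER at low | ICER at high | spread |")
        lines.append("|---|---|---|---|---|")
        for rank, e in enumerate(entries[:10], start=1):
            ilow, ihigh = e.get("icer_at_low"), e.get("icer_at_high")
            lines.append(
                f"| {rank} | {_get(e, 'parameter')} "
                f"| {_brl(ilow) if ilow is not None else e.get('status_at_low')} "
                f"| {_brl(ihigh) if ihigh is not None else e.get('status_at_high')} "
                f"| {_get(e, 'spread'):,.2f} |"
            )
    lines.append("")

    lines.append("## Microsimulation cross-check")
    lines.append("")
    micro = doc.get("microsim")
    if micro is None:
        lines.append("not run")
    else:
        for name, est in micro.items():
            lines.append(
                f"- {name}: n={_get(est, 'n'):,}, seed={_get(est, 'seed')}, "
                f"mean cost {_brl(_get(est, 'mean_cost'))} (SE {_get(est, 'se_cost'):.2f}), "
                f"mean discounted cases {_get(est, 'mean_cases'):.4f} "
                f"(SE {_get(est, 'se_cases'):.5f})"
            )
    lines.append("")

    pop = _get(doc, "population")
    lines.append("## Population arithmetic")
    lines.append("")
    lines.append(
        f"- eligible relatives per year: **{_get(pop, 'eligible_relatives_per_year'):,}** "
        f"({_get(pop, 'annual_ov_cancer_cases'):,.0f} ovarian-cancer cases x "
        f"{_get(pop, 'prop_mutation'):.0%} mutation prevalence x "
        f"{_get(pop, 'relatives_per_patient')} relatives x "
        f"{_get(pop, 'transmission_prob'):.0%} transmission)"
    )
    lines.append(
        f"- expected screening cost per untested relative-year: "
        f"{_brl(_get(pop, 'expected_screening_cost_per_year'))}"
    )
    lines.append("")
    return "\n".join(lines)
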