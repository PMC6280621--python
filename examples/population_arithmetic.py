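"""Desk arithmetic behind the programme: who is eligible, what screening costs.

These are the precursor figures for a budget-impact analysis: the annual
eligible cascade-testing population and the expected screening spend per
untested relative.
"""

from brcacea import carrier_proportions, default_parameters, eligible_population, expected_screening_cost

params = default_parameters()

p1, p2, p0 = carrier_proportions(
    params.prevalence_brca1_patients, params.prevalence_brca2_patients, params.transmission_prob
)
print(f"carrier mix among first-degree relatives: "
      f"{p1:.1%} BRCA1, {p2:.1%} BRCA2, {p0:.1%} no mutation "
      f"(rounds to {round(p1*100)}% / {round(p2*100)}% / {round(p0*100)}%)")

prop = params.prevalence_brca1_patients + params.prevalence_brca2_patients
n_eligible = eligible_population(
    params.annual_ov_cancer_cases, prop, params.relatives_per_patient, params.transmission_prob
)
print(f"eligible relatives per year: {n_eligible:,} "
      f"({params.annual_ov_cancer_cases:,.0f} cases x {prop:.0%} x "
      f"{params.relatives_per_patient} relatives x {params.transmission_prob:.0%} transmission)")

screen = expected_screening_cost(
    params.p_high_risk_algorithm, params.cost("screening_mutation_carrier_annual")
)
print(f"expected screening cost per untested relative-year: R${screen:.2f} "
      f"({params.p_high_risk_algorithm:.0%} referred x R${params.cost('screening_mutation_carrier_annual'):.2f})")
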