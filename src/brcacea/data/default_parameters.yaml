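# Packaged default inputs: cascade germline BRCA1/2 testing of first-degree
# female relatives of ovarian-cancer patients with a confirmed pathogenic
# variant, public-payer perspective, all monetary values in 2014 BRL.
#
# Probabilities carry 95% ranges where the source literature reports one;
# a missing low/high means the parameter is excluded from the one-way
# deterministic sensitivity sweep unless the user supplies a range.
#
# Note on penetrance vs adherence: breast-cancer penetrance in carriers
# (0.57 BRCA1 / 0.49 BRCA2, Chen 2007) and surgical adherence
# (0.18 mastectomy / 0.57 RRSO, Metcalfe 2008) are easily conflated because
# both are probability pairs of similar magnitude; here they are stored under
# explicit names so the model structure, not row order, decides their role.

probabilities:
  p_relative_brca1: {point: 0.45, source: "Maistro 2016"}
  p_relative_brca2: {point: 0.05, source: "Maistro 2016"}
  p_adhere_mastectomy: {point: 0.18, low: 0.16, high: 0.20, source: "Metcalfe 2008"}
  p_adhere_rrso: {point: 0.57, low: 0.55, high: 0.59, source: "Metcalfe 2008"}
  p_breast_ca_brca1: {point: 0.57, low: 0.47, high: 0.66, source: "Chen 2007"}
  p_breast_ca_brca2: {point: 0.49, low: 0.40, high: 0.57, source: "Chen 2007"}
  p_breast_ca_nomut: {point: 0.06, low: 0.03, high: 0.08, source: "Ferlay 2013"}
  p_ov_ca_brca1: {point: 0.40, low: 0.35, high: 0.46, source: "Chen 2007"}
  p_ov_ca_brca2: {point: 0.18, low: 0.13, high: 0.23, source: "Chen 2007"}
  p_ov_ca_nomut: {point: 0.006, low: 0.005, high: 0.01, source: "Ferlay 2013"}
  p_breast_ca_brca1_post_mx: {point: 0.04, low: 0.03, high: 0.05, source: "De Felice 2015; Chen 2007"}
  p_breast_ca_brca2_post_mx: {point: 0.03, low: 0.03, high: 0.04, source: "De Felice 2015; Chen 2007"}
  p_breast_ca_brca1_post_rrso: {point: 0.28, low: 0.23, high: 0.32, source: "Rebbeck 2009; Chen 2007"}
  p_breast_ca_brca2_post_rrso: {point: 0.24, low: 0.20, high: 0.28, source: "Rebbeck 2009; Chen 2007"}
  p_breast_ca_brca1_post_both: {point: 0.02, low: 0.01, high: 0.03, source: "De Felice 2015; Rebbeck 2009; Chen 2007"}
  p_breast_ca_brca2_post_both: {point: 0.02, low: 0.01, high: 0.02, source: "De Felice 2015; Rebbeck 2009; Chen 2007"}
  p_ov_ca_brca1_post_rrso: {point: 0.08, low: 0.07, high: 0.10, source: "Rebbeck 2009; Chen 2007"}
  p_ov_ca_brca2_post_rrso: {point: 0.04, low: 0.03, high: 0.05, source: "Rebbeck 2009; Chen 2007"}
  p_high_risk_algorithm: {point: 0.24, source: "share of untested relatives whose mutation-risk algorithm is >= 10%"}

costs:
  counseling: {amount: 200.00, recurrence: one_off}
  ngs_plus_mlpa: {amount: 683.61, recurrence: one_off}
  mastectomy: {amount: 3158.04, recurrence: one_off}
  rrso: {amount: 542.46, recurrence: one_off}
  screening_mutation_carrier_annual: {amount: 333.75, recurrence: per_cycle}
  screening_high_risk_annual: {amount: 80.10, recurrence: per_cycle}

structure:
  discount_rate: 0.05
  age_start: 30
  age_end: 70
  prevalence_brca1_patients: 0.17
  prevalence_brca2_patients: 0.02
  threshold_low: 7543.50
  threshold_high: 23786.70
  annual_ov_cancer_cases: 6150
  relatives_per_patient: 3.5
  transmission_prob: 0.5
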