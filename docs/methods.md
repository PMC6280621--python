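# Methods

## Decision problem and model structure

The model compares two management strategies for first-degree female
relatives of ovarian-cancer patients with a confirmed germline BRCA1/2
mutation, over a 40-year horizon (ages 30–70, one-year cycles), from a
public-payer perspective in 2014 BRL.

**Testing strategy.** Every relative receives genetic counselling
(R$200) and NGS+MLPA testing (R$683.61) at cycle 0. Carriers are offered
bilateral prophylactic mastectomy (uptake 0.18) and risk-reducing
salpingo-oophorectomy (uptake 0.57); the two choices are treated as
independent, giving four adherence arms per gene. Surgery happens at age
30 (cycle 0) and switches the arm to the corresponding post-surgery
penetrance. Carriers who refuse mastectomy receive annual breast MRI +
mammography (R$333.75/yr while cancer-free); no screening after
mastectomy, and no ovarian screening anywhere (available methods are not
effective). Test-negative relatives receive no further intervention.

**Usual care.** Nobody is tested; the same latent carrier mixture
(45% BRCA1 / 5% BRCA2 / 50% none) applies with no-surgery penetrance.
Screening reaches the 24% of relatives whose mutation-risk algorithm
flags them, charged as its expected value 0.24 × R$333.75 = R$80.10 per
relative-year on every arm — mirroring the published cost construction
rather than splitting arms by algorithm outcome, whose correlation with
carrier status is not derivable from the printed inputs.

Each arm evolves through three states — well, breast cancer, ovarian
cancer — with both cancer states absorbing. There is no death state and
no background mortality: the outcome is *cancer cases prevented*, not
life-years, and adding mortality would change the question being asked.
An individual therefore contributes at most one case.

## Parameters

All inputs live in one YAML file (`src/brcacea/data/default_parameters.yaml`);
19 probabilities, 6 unit costs, and structural scalars. Probabilities
carry 95% ranges where the source literature reports one; the carrier
splits (0.45/0.05), the 24% risk-algorithm probability and all costs have
no published range and are therefore *excluded* from the sensitivity
sweep rather than given an invented ±20% spread.

One curation decision deserves emphasis: the input table in the source
material prints two near-identical "probability of adherence" row pairs.
The pair citing Chen et al. (0.57/0.49) numerically matches the
carriers' breast-cancer penetrances quoted in the surrounding text, and
Chen 2007 is a penetrance study; the pair citing Metcalfe et al.
(0.18/0.57) is an adherence study. The packaged defaults accordingly
store 0.57/0.49 as BRCA1/BRCA2 breast-cancer penetrance and 0.18/0.57 as
mastectomy/RRSO adherence. Swapping them back reproduces neither the
quoted penetrances nor a plausible uptake pattern.

## Numerical conventions

* **Hazard conversion.** Only lifetime (40-year) cumulative penetrances
  are available, so a constant annual hazard is assumed:
  p_annual = 1 − (1 − P)^(1/40), implemented with `log1p`/`expm1` for
  accuracy near zero; the round-trip inverse is exact to 1e-12.
  Post-surgery figures are parallel replacement cumulative risks over the
  same span, not hazard ratios. Age-specific hazard curves are a
  deliberate non-goal — the printed data cannot support them.
* **Competing transitions.** Within a cycle breast and ovarian
  transitions compete; the joint-event mass p_b·p_o goes to breast
  cancer (the higher-incidence site). At the model's annual risks the
  choice moves total discounted cases by < 1e-3 (covered by a test).
* **Accrual and discounting.** One-off costs at cycle 0 undiscounted;
  per-cycle costs for well occupants at cycle start, discounted
  (1.05)^−t; a transition during cycle t counts as a case at t+1,
  discounted (1.05)^−(t+1). Effects are discounted at the same 5% rate
  as costs. No half-cycle correction is applied. Internal arithmetic is
  never rounded; only rendering rounds to 2 decimals, which is why a
  ratio of printed rounded outputs (908.02) can differ from a
  full-precision ICER.
* **Effectiveness scales.** The published effectiveness values carry no
  units. Two conventions are implemented: `per100` = (1 − E[discounted
  cases]) × 100 (library default), and `cancer_free_years` = Σ_t
  (1.05)^−t · P(well at start of t). Our reconstruction's cancer-free
  person-years (16.17 / 14.96) land within 1% of the published
  effectiveness pair (16.13 / 14.85), so reproduction-oriented outputs
  use that scale; the verdict (cost-effective at the lower threshold) is
  identical under both.
* **ICER and thresholds.** Dominance short-circuits the ratio;
  |Δeff| ≤ 1e-9 yields a flagged "no trade-off". Threshold
  classification is boundary-inclusive on the favourable side (an ICER
  exactly at R$7,543.50 counts as cost-effective at the stricter
  threshold) — boundaries are measure-zero, the convention is documented
  here.

## Reconstruction fidelity

The original analysis was produced with closed-source software whose
cycle mechanics (hazard conversion, cost timing, effectiveness units) are
not published. Our reconstruction reproduces the desk arithmetic exactly
(45/5/50 split, R$80.10, 2,045 eligible relatives), the effectiveness
pair to < 1%, the quadrant-I structure, and the cost-effectiveness
verdict with ample margin. It does **not** reproduce the printed expected
costs: usual care at R$80.10/yr accrued over the discounted horizon gives
≈ R$1,198 per relative, whereas the printed R$78.96 is approximately a
*single* year of screening, and the testing strategy's one-off costs
alone (test + counselling + adherence-weighted surgeries ≈ R$1,322)
exceed its printed R$1,241.22 before any screening accrual. No accrual
convention consistent with the printed per-cycle inputs yields those
values; they appear to reflect recurring costs charged once. We keep the
per-cycle accrual the model description implies and report the resulting
ICER (R$1,731.72 per discounted cancer-free year) as this package's
estimate — on the same side of every threshold as the published
R$908.59.

## Sensitivity analysis

One-way deterministic: each ranged parameter is set to its low and high
bound in turn, all others at their point values, and the full analysis is
recomputed on derived parameter-set copies (the baseline provably
survives a sweep bit-for-bit; `restore_check` guards this). Entries are
ranked by absolute ICER spread, ties broken alphabetically. An excursion
that destroys the trade-off structure would be flagged on the entry, not
raised; at the defaults none does, and every excursion stays below the
lower threshold. BRCA1 breast-cancer penetrance dominates the ranking.
Correlation between penetrance parameters is deliberately ignored
(one-at-a-time semantics).

## Microsimulation

The synthetic-data generator draws, per relative, an arm by its weight
and then annual Bernoulli transitions with exactly the cohort engine's
probabilities, costs, discounting and tie-break. It emulates the
*model's* population — it does not add age structure, family clustering,
competing mortality or behavioural correlation, so agreement with the
cohort engine validates the implementation, not the model's realism.
Randomness comes from a counter-based Philox generator keyed by the
user's seed; draws are emitted for every individual at every cycle
regardless of state, so each individual's randomness occupies fixed
counter positions and results are bit-reproducible and independent of
storage or traversal order. Estimates carry standard errors from the
between-individual sample variance; the acceptance-level check uses
n = 200,000 per strategy (≈ 1 s vectorised), at which 3 SE ≈ R$18 on the
testing-strategy cost and ≈ 0.0016 on discounted cases. Convergence at
the n^−1/2 rate is tested at n = 1,000 / 4,000 / 16,000.

## Degenerate inputs and guarantees

Certain-event lifetime risks (P = 1) are rejected — the implied hazard is
infinite. Occupancy conservation is asserted every cycle at 1e-12 and
breaches raise, never pass silently. A parameter set never validates
partially: loading fails loudly naming every violation, while the
`validate()` API returns the violation list for tooling. Zero-risk,
zero-discount, full-adherence and neutral-intervention limits all reduce
to closed forms that the test suite pins.

## Known limitations

* No mortality, no competing risks, no quality-of-life weighting: the
  ICER denominator is cancer cases (or cancer-free time), not QALYs, and
  is not comparable across disease areas.
* Constant hazards flatten the real age-incidence curve of both cancers;
  discounted case timing is therefore approximate even where cumulative
  risk is exact.
* Surgical uptake is modelled as an instantaneous age-30 decision;
  delayed uptake would shift both costs and benefits later.
* The 2014 BRL values are not inflated or currency-converted; results
  are internally consistent but dated in absolute terms.
* Parameters without published ranges are untested by the sensitivity
  sweep; the carrier-split and risk-algorithm inputs are the notable
  gaps.
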