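# riskmx

Risk-matrix decision support for clinical guideline development.

When a guideline group weighs a preventive intervention (should all
pregnant women take calcium supplements?) or a diagnostic threshold
(should growth restriction be called at the 10th or the 5th centile?),
the trade-off couples an event *probability* with a distribution of
*consequences* across the affected population. `riskmx` implements the
risk-matrix approach used for exactly these decisions in obstetric
guideline development: a 5×5 probability × impact grid with weighted
population-risk percentiles, plus the Likert-survey triage and consensus
arithmetic used to take the final decision with the professionals.

## The model

The matrix crosses five ordinal probability bands *b* ∈ {1..5}
(rare < 0.1 % … very likely > 10 %) with five ordinal impact levels
*i* ∈ {1..5} (managed in primary care … death). Each cell carries the
multiplicative risk score

> *s* = *b* × *i* ∈ {1, …, 25},

mapped to five categories: small (1–4, dark green), moderate (5–8, light
green), high (9–14, yellow), very high (15–19, orange), extreme (20–25,
red).

A **scenario** is an event probability *p* (which fixes the band) plus an
impact distribution *w*₁…*w*₅ — the percentages of the affected
population at each impact level, one matrix row summing to ~100 %. The
population risk is summarised by weighted percentiles of the score:
the q-th percentile is *b* × *j*\*, with *j*\* the smallest impact level
whose cumulative (renormalised) weight reaches at least *q*. The package
reports p50 with a p5–p95 interval, the severe-outcome tail
(*w*₄ + *w*₅ on the raw weights), per-impact category transitions
between a baseline and an intervention scenario, and whether the
intervention clears its invasiveness-dependent reduction threshold (two
categories for non-/moderate-invasive, three for very-invasive).

Survey statements scored on a 1–10 Likert scale are triaged by mean and
sample SD — accept if mean > 8 and SD < 2, reject if mean < 3 and
SD < 2, discuss otherwise — and team decisions are adopted at ≥ 85 % in
favour (exact integer arithmetic, boundary inclusive).

All probabilities and weights are **percent**, never fractions.

## Worked example

The bundled `calcium_preeclampsia` config holds the preeclampsia
scenarios: incidence 6.5 % without calcium supplementation (impact row
28/53/15/4.3/0.1 %) and 4.8 % with it (28/54/15/3.4/0.02 %).

```sh
riskmx score calcium-absent
```

```
scenario 'calcium-absent': event probability 6.5% -> band 4 ('likely')
  population risk p50 8 (p5-p95 4-12), category 'moderate' (light green)
  severe-outcome tail (disability+death): 4.4%
```

The median affected woman lands at impact level 2 (short
hospitalization), so her score is 4 × 2 = 8 — a moderate risk — with a
p5–p95 interval of 4–12.

```sh
riskmx compare calcium --invasiveness non-invasive
```

```
baseline 'calcium-absent' vs intervention 'calcium-present'
  p50: 8 -> 6 (delta -2); category moderate -> moderate (rank reduction 0)
  severe tail: 4.4% -> 3.4% (delta -1 pp)
  per-impact category transitions:
    ...
    4 disability/serious-morbidity: very high (orange) -> high (yellow)
    5 death: extreme (red) -> very high (orange)
  reduction threshold [non-invasive, scope: population]: not met (0 of 2 categories)
```

Supplementation drops the probability band from 4 to 3: the worst cells
each fall one category (death red → orange, disability orange → yellow)
and the median score falls from 8 to 6, but the *median category* stays
moderate — so the professionals' own bar for a non-invasive intervention
(a two-category reduction) is not met, and the decision moves to other
arguments. The same machinery drives the `sga_thresholds` config (10th
vs 5th growth centile: p50 8 (4–12) with a 0.9 % severe tail, vs 6 (3–9)
with a 4 % tail).

`riskmx survey table.csv` triages a long-format survey
(`statement_id, respondent_id, score`) into a mean/SD/verdict table, and
`riskmx fixtures` prints the bundled examples. Python API:
`riskmx.Scenario.from_weights`, `population_risk_summary`, `compare`,
`meets_reduction_threshold`, `statement_stats`, `triage`, `consensus`.

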