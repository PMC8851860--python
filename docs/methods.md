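# Methods

## The risk-matrix model

A scenario is scored on a fixed 5×5 grid. Rows are ordinal probability
bands; columns are ordinal impact levels; a cell's risk score is the
product of the two indices. The grid is deliberately coarse: it encodes
a consensus judgement device, not a statistical model, and every number
it produces is an integer in 1–25 whose meaning comes from the category
table (small 1–4, moderate 5–8, high 9–14, very high 15–19, extreme
20–25). Category ranges are irregular, so they are data (a lookup
table), not arithmetic.

### Probability-band convention

The published band labels are gapped at one-decimal granularity
(< 0.1 %, …, 1.1–5 %, 5.1–10 %, > 10 %), which leaves values such as
5.05 % formally unassigned. We use contiguous intervals

| band | label | interval (%) |
|---|---|---|
| 1 | rare | (0, 0.1) |
| 2 | unlikely | [0.1, 1] |
| 3 | possible | (1, 5] |
| 4 | likely | (5, 10] |
| 5 | very likely | (10, 100] |

i.e. half-open above, with each printed boundary belonging to the lower
band. This is forced by the worked examples: a 10 % screening
prevalence must score in band 4, and 5 % in band 3 by the symmetry of
the printed labels. Band 2's range is nowhere printed and is inferred
from its neighbours. The convention reproduces every published
classification; a grid sweep at 0.001 % steps verifies totality and
monotonicity. Band bounds, impact labels and category ranges are
overridable from the config file (the labels are profession-specific),
but the matrix stays 5×5.

### Weighted percentiles

An impact distribution is one matrix row: five percentages of the
affected population, least to most severe. Rows may miss 100 % by
rounding slack — the published rows sum to 100.4, 100.42, 99.9 and
100.0 — so validation accepts |sum − 100| ≤ 0.5 percentage points
(configurable) and renormalises to exactly 100 before quantile
arithmetic. The original sum and weights are retained for audit.

The q-th percentile of the population risk score is `band × j*` where
`j*` is the smallest impact level whose cumulative renormalised weight
is ≥ q. The ≥ (rather than >) at exact boundaries is the unique simple
convention that is deterministic there; both readings reproduce all
published triplets for these distributions. Numerically, a 1e-9
percentage-point slack absorbs float noise from renormalisation at
boundaries. Consequences of the convention: percentiles are monotone in
q, and every percentile is a multiple of the band index.

The severe-outcome tail (disability + death) is reported on the **raw**
weights, so printed sums (0.3 + 0.6 = 0.9; 1.4 + 2.6 = 4.0) are matched
digit for digit rather than perturbed by renormalisation.

### Intervention comparison and thresholds

A comparison requires the same impact labels on both scenarios and
reports: the p50 shift, the reduction in the p50 cell's category rank,
all five per-impact-level category transitions, and the tail change.
Both views matter in practice — in the calcium example the worst cells
each drop one category while the median category does not move.

The reduction threshold applies the professionals' own expectations:
non- and moderate-invasive interventions should lower the risk by two
categories, very-invasive by three, evaluated on the p50 category rank.
The expectation's scope (population vs highest-risk group) is carried
as metadata only: no quantitative definition of the highest-risk
subgroup exists, so the package does not invent one.

## Survey triage and consensus

Statements are summarised by mean and sample SD (divisor n − 1, the
survey-reporting norm; `ddof=0` switches to population SD). Triage:
accept iff mean > 8 and SD < 2; reject iff mean < 3 and SD < 2;
everything else — mean in the closed interval [3, 8], or SD ≥ 2 — is
discussed. SD exactly 2 is not covered by either published sentence;
discussing it is the conservative choice. A grid sweep verifies the
three regions partition the domain.

Team adoption requires ≥ 85 % in favour, compared as
`n_favor × 100 ≥ 85 × n_total` in integers so that 17/20 adopts exactly
and 1699/2000 (84.95 %) does not. "In favour" is an explicit vote
count, not derived from Likert scores.

## Configuration

One YAML dialect with a versioned `schema: 1` key. Unknown keys are
errors, not warnings — these files carry clinical inputs and a typo must
not silently fall back to a default. All percentages are numbers in
percent units throughout the package. `write_config(load_config(f))`
round-trips. The two bundled configs transcribe the worked examples at
full printed precision (including the 0.02 % maternal-death weight
whose row sums to 100.42).

## Synthetic generators

`random_scenario` draws weights from a symmetric Dirichlet
(concentration 1.0 by default, i.e. uniform on the simplex — a
deliberately adversarial spread of row shapes) scaled to 100 %, and an
event probability uniform in the central 90 % of the chosen band's
interval, keeping draws away from band-boundary conventions. It
emulates arbitrary valid matrix rows, not the epidemiology of any real
outcome; passing property tests show the quantile arithmetic is
correct, not that real rows look like Dirichlet draws.

`random_survey` draws integer Likert responses by rounding and clipping
normal draws per statement. Clipping at 1 and 10 slightly shrinks
extreme-mean/high-SD profiles, which the tests' recovery bounds
account for by applying the ±0.2 mean-recovery check only to low-SD
profiles (where the standard error at n = 200 is ≈ 0.04). Independent
raters only; no rater correlation or ordinal response styles.

## Verification strategy and problem sizes

The quantile rule is cross-checked against an independent brute-force
oracle: expand the renormalised row into 100 000 individuals
(largest-remainder apportionment), sort, and take the nearest-rank
percentile. Agreement is required exactly, except where q lies within
0.01 percentage points of a cumulative-weight boundary (there the
oracle's ±1-individual granularity is undefined by construction). The
test suite checks 200 random scenarios at five percentiles each; the
acceptance script re-runs a 50-scenario version of the same check,
seeded from its `--seed`, before reporting. These sizes keep the full
suite under a few seconds while leaving the oracle comfortably more
precise than the 0.01 pp exclusion zone.

## Known limitations

- Cell percentages are treated as point estimates, as in the source
  process; no uncertainty propagation over rows (a natural Dirichlet
  extension, deliberately out of scope).
- The matrix is fixed at 5×5; labels and bounds are configurable,
  dimensions are not.
- Text rendering only; colours are emitted as words, display rounding
  is half-even to one decimal, internal values are never rounded.
- The triage boundary semantics (mean exactly 3 or 8, SD exactly 2) and
  band 2's bounds follow the conventions documented above; other
  readings of the published wording are possible but change no worked
  example.
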