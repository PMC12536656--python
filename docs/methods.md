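# Methods

## Model and procedure

The package evaluates a coded policy corpus on two dimensions.

**Rubric scoring.**  The evaluation schema is a two-level hierarchy: ten
first-level variables (policy nature, timeliness, level, subject, objective,
content, incentive and constraint, function, evaluation, information
disclosure), of which the first nine own 6, 4, 4, 7, 3, 6, 7, 5 and 4 binary
second-level criteria respectively and the tenth is a direct 0/1 leaf.  Every
criterion is coded yes = 1 / no = 0 with equal weight.  A variable's score is
the arithmetic mean of its criteria; the PMC index is the sum of the ten
variable scores, so it ranges over [0, 10].  Rating classes are half-open
intervals closed on the left: perfect [9, 10], good [7, 9), acceptable
[5, 7), poor [0, 5).  The printed bounds "8.999" etc. are three-decimal
artifacts of that convention, and treating them as half-open intervals keeps
every real-valued index classifiable.

**Instrument analysis.**  Coding units (one per content-analysis fragment,
identifier `policy-chapter-unit` with positive integer parts) carry one
sub-tool label from a 3-category / 16-sub-tool taxonomy.  Frequency tables
count units per sub-tool with percentages against the group's grand total of
units.  The cross-analysis partitions the same units by the rating of the
policy they belong to.  Cross-tab percentages also use the group grand total
as denominator, not the rating-subset total: this is the only convention
under which the published per-rating percentages re-sum to the per-group
category totals (checked in the test suite with ±1 unit rounding slack).

## Numerical conventions

- **Rounding** is decimal half-up throughout, matching printed tables:
  variable scores and percentages to 3 decimals, usage ratios to 2.
  Variable scores are rounded *before* summation into the index; this
  reproduces the published worked rows exactly (e.g. 0.833 + 0.250 + … =
  8.547, where exact fractions would give 8.548).  Score arithmetic uses
  `decimal.Decimal`, so no binary-float rounding artifacts enter.
- **Ranking** is by descending index with ties broken by ascending policy id;
  ranks are 1..n without gaps.  The reference corpus contains no ties, so the
  tie-break is a package convention.
- **Group summaries** average the per-policy *rounded* indices.  Whether the
  published group means were taken over rounded or exact indices is not
  stated; the difference is below print precision.
- **Undefined ratios.**  A usage ratio with a zero denominator count is
  reported as an explicit undefined marker (`None`), never infinity or zero.
- **Concavity.**  The surface literature describes concavity qualitatively.
  This package quantifies it as the per-cell shortfall `1 − score` and its
  total over the 3×3 grid (equivalently `9 − cell sum`).  It is a documented
  artifact convention, monotone under cellwise dominance, and excluded from
  any comparison against published numbers.
- **Surface layout** is row-major X1..X9 with X10 excluded (constant at 1 in
  the reference corpus and dropped to keep the matrix square).  Charts draw
  the 3×3 lattice as-is with z fixed to [0, 1]; nothing is interpolated.

## Synthetic-data generator

The generator emulates the study conditions rather than any particular
corpus realisation:

- **Group sizes** default to 35 / 14 / 30 policies for (batch 1, phase 1),
  (batch 1, phase 2) and (batch 2, phase 2).  The combination (batch 2,
  phase 1) does not exist in the corpus layout; the generator refuses it and
  loaders warn.
- **Criterion codings** are independent Bernoulli draws.  Calibration assigns
  every criterion under a variable the variable's target mean (criteria are
  treated as exchangeable), so the expected variable score equals the target
  and the expected index equals the sum of targets.  Default targets are the
  published per-group variable means, giving expected group means of
  7.683 / 7.577 / 7.781 and an expected overall weighted mean of 7.701.
- **Corpora** draw 1,354 / 493 / 1,067 units per group from multinomial
  sub-tool mixes proportional to the published frequency table; units are
  assigned to the group's policies uniformly and numbered sequentially, ten
  units per synthetic chapter (the real per-policy unit counts are
  unpublished).
- **Streams**: corpora use an rng seeded from (seed, batch, phase) so corpus
  draws do not shift when coding draws change; identical config + seed gives
  identical output.

What the generator does **not** model, and hence what passing tests do not
show about real data: within-variable correlation between criteria (e.g. the
four timeliness horizons are partly mutually exclusive in real coding, yet
the published mean 0.307 suggests occasional multi-selection, so independence
is a workable approximation); correlation between a policy's rubric coding
and its instrument mix; and any per-policy heterogeneity in unit counts.
Tests that compare synthetic summaries against published means therefore use
Monte-Carlo tolerances (3 standard errors at the simulated sample size), not
exact equality.

## Data formats and validation

Coding sheets are UTF-8 CSV with a header row in one of two dialects,
auto-detected: FULL (46 binary criterion columns plus the X10 leaf) or
SUMMARY (ten pre-aggregated first-level scores, the form worked examples are
printed in — SUMMARY rows skip the aggregation step and feed scoring
directly).  Group metadata are `batch` and `phase` columns in {1, 2}.
Unknown extra columns are ignored with a logged warning to tolerate
annotation columns.  Schema and taxonomy are YAML; the packaged defaults
reproduce the reference rubric and taxonomy and round-trip through their
writers.  Loaders raise structured errors naming the offending row and
column; validity is enforced at the type level (binary values, unique ids,
ordered variables, positive unit-id components).

## Problem sizes

The test suite and the acceptance script run entirely from embedded fixtures
and fixed-seed simulation: the largest computations are one 790-policy
calibration check, one 350-policy parameter-recovery check, exhaustive
enumeration of all 2¹² codings of a reduced 12-criterion rubric against a
naive summation oracle, and synthetic corpora of 1,354 units.  These sizes
were chosen to make Monte-Carlo tolerances tight enough to be meaningful
while keeping the whole suite around a few seconds.

## Known limitations

- The full 79-policy corpus's 46-column binary codings are not published;
  only 15 per-policy first-level score rows are.  Exact reproduction is
  therefore limited to those rows, the frequency table, the group means and
  the headline ratios; everything else is covered by calibrated-simulation
  properties.
- One published reconstruction does not close: the acceptable-rated
  second-batch figures (ratios 4.67 and 7.78 with supply at 2.812%) are
  mutually inconsistent under every rounding convention tried, so they are
  not asserted anywhere.
- Variables are equally weighted by design; no re-weighting (e.g. AHP) is
  implemented.
- The rating/concavity ordering check (perfect flattest … poor most concave)
  is an empirical property of the fixture set, not a theorem; sets with
  extreme X10 values could violate it.
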