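# Methods

## The processing model

A two-part FFQ is processed line by line. Part 1 is a fixed food list; each
line carries one portion weight (grams per medium serving, standard unit or
household measure) and one of nine frequency categories. The engine's
defining computation is

    daily grams of line l = multiplier(category) × portion weight(l)

where the multiplier is the category's average occurrences per day. Each
line maps to between one and six food codes with proportions that must sum
to exactly 1; daily line grams are apportioned by those proportions and
joined to a composition table (nutrient amounts per 100 g edible food).
Food groups are treated as *pseudonutrients*: a group's daily "amount" is
the grams of its member foods consumed, accumulated exactly like a
nutrient. This yields four result granularities — per (line, food code),
per line, and participant totals in wide and long form — each an exact
componentwise roll-up of the one below it, which the test suite verifies
at both the in-memory and serialized level.

Assumptions worth stating plainly:

- **Missing is zero, not imputed.** A missing frequency (empty cell, the
  "not recorded" sentinel, or the legacy two-frequencies marker)
  contributes nothing to intake. Excessive missingness is penalized by the
  exclusion stage, not the engine.
- **Proportions sum to exactly 1** (tolerance 1e−9, appropriate for short
  decimals in text files). Edible/waste fractions are assumed to be baked
  into the portion weights.
- **All arithmetic in double precision**; rounding happens only at
  serialization (default 6 significant digits, configurable, or disabled).

## Frequency multipliers

The nine category labels constrain but do not fix the occurrences-per-day
midpoints, so the multipliers are data, not code — shipped as an editable
table with the convention: never = 0; 1–3/month = 2/30.44; once/week = 1/7;
2–4/week = 3/7; 5–6/week = 5.5/7; once/day = 1; 2–3/day = 2.5;
4–5/day = 4.5; 6+/day = 6. The "never" category must carry multiplier 0 and
multipliers must be non-decreasing in category code; the validator enforces
both.

## Part-2 resolution

Handwritten milk/cereal/fat varieties are matched against reference lists
after normalization (case-fold, punctuation stripped, whitespace
collapsed; idempotent). Matching is **exact-after-normalization only**: in
manual practice a near-miss is resolved by a researcher comparing nutrient
profiles, which is not reproducible in software, so the tool only *logs*
close candidates (stdlib edit-distance suggestions) and assigns the
list's default code. Precedence per kind is pre-assigned code > None/No
box > exact match > default; every default assignment is logged, and the
count of default notes in a run log equals the count of default
provenances, a tested invariant.

Up to four distinct cereal codes are kept (order preserved, truncation
logged) and the cereal slot's grams are split **equally** across them —
the assignment of multiple codes is documented behaviour but the weights
are not, so equal weights are the least-informative choice and are logged
per participant for auditability. A None/No box on a fat question yields a
NO_FAT sentinel contributing zero grams and zero nutrients; when both a
box and text are present the box wins and the conflict is logged. The milk
amount answer (a category such as pints per day) maps through an editable
table to a dimensionless scale factor applied to milk-*tagged* lines only;
lines merely containing milk as an ingredient are untouched. Both hooks
(code switch and amount scaling) are implemented; scaling can be disabled
via `EngineOptions(milk_scaling=False)`.

Disabling text matching (`--no-text-match`) suppresses only the free-text
step, leaving boxes, pre-assigned codes and defaults — the mechanism for
quantifying how much ranking by nutrient depends on text matching.

## Outlier exclusion

Stage 1 removes questionnaires with ≥ 10 missing part-1 lines. Stage 2
computes EI:BMR on the survivors: energy intake (the designated kJ
nutrient, converted to MJ by the exact factor 1000) over basal metabolic
rate predicted as slope × weight + intercept for the participant's sex and
age band. The coefficient table ships as data (`schofield.csv`), populated
with the standard adult bands of the widely used sex/age-specific BMR
equations (men 18–30: 0.063w + 2.896, 30–60: 0.048w + 3.653, 60+: 0.049w +
2.459; women 18–30: 0.062w + 2.036, 30–60: 0.034w + 3.538, 60+: 0.038w +
2.755 MJ/day), editable like every other table. Ages outside the bands are
an explicit error, never an extrapolation; a participant lacking age or
weight is reported BMR-ineligible and retained, never silently imputed.

Each tail flags floor(tail × n) participants (default tail 0.5 %), pooled
across sexes, with ties broken by participant id so the flagged set is a
deterministic function of the input. Floor semantics make the rule
rank-based (invariant to monotone transforms of the ratio) and reproduce
the natural bookkeeping at scale: from 25 102 stage-2-eligible
questionnaires, floor gives 125 + 125 = 250 exclusions. Pooled (rather
than per-sex) ranking is the default because the published per-sex
exclusion counts are consistent with pooled ranking; per-sex tails can be
obtained by running the stages per stratum.

## Quintile-shift comparison

Cut-points are the 20/40/60/80th percentiles of the *reference* run only;
both runs are binned with them, making the comparison deliberately
asymmetric (tested). The percentile definition is a named, swappable
policy (`inclusive_linear` by default — linear interpolation between
closest ranks, the common default in statistical software) so results can
be matched to other packages. Boundary ties go to the lower quintile:
value ≤ cutpoint_k ⇒ quintile ≤ k. Summary statistics use the sample
(n−1) standard deviation and midpoint median for even n. Stratified
comparison (`--by sex`) computes per-stratum cut-points, with pooled
available by omitting `--by`.

## Synthetic fixtures

The generator emulates the *structure* real cohorts exercise: tagged
milk/cereal/frying-fat/baking-fat lines, a modified without-fat food with
nonzero fat uptake, reference lists with defaults, a full adult BMR table,
participants aged 40–79 with sex-specific weights, missing/dual-frequency
sentinels at configurable rates, and part-2 texts drawn from the reference
lists with single-character typos (guaranteed to miss exact matching, so
the default-code path is exercised). It deliberately does **not** model
realistic British diets, nutrient correlations, or portion-size
distributions — so passing tests demonstrate algorithmic correctness
(conservation, identities, determinism, oracle agreement), not dietary
plausibility. One integer seed drives a single generator; identical seeds
give byte-identical bundles and cohorts.

Toy scale is 10 lines × 12 foods × 8 nutrients × 4 groups; a full-scale
*shape* preset (130 lines, 46 nutrients, 14 groups) checks that nothing
depends on toy dimensions. The acceptance script runs the toy pipeline at
60 participants and the oracle-equivalence suite uses 120 seeded
4-participant cohorts — small enough to be instant, large enough to cover
every code path (missing, dual, typo, None-box, fat substitution).

## Numerical choices and degenerate inputs

- Aggregation identities are asserted to 1e−9 relative (1e−12 absolute);
  the engine and the naive triple-loop reference agree to ~1e−15 in
  practice.
- An all-equal reference vector degenerates to four equal cut-points and
  every value in quintile 1 by the tie rule.
- Fewer than five reference values, empty summaries, empty eligible sets
  for the ratio tails, and unwritable sinks are explicit errors.
- Unknown food codes are never fatal by default: they contribute zero
  nutrients and an ERROR log entry (`--strict` promotes them to fatal).

## Known limitations

- No nutrient retention / cooking-loss modelling, no supplements.
- Exact-match-only text resolution will under-assign codes for misspelled
  answers relative to a human coder; the log's suggestion entries are the
  intended remediation path.
- The milk-amount scale table and frequency multipliers are conventions;
  studies with their own calibrations should edit the bundle.
- Per-sex percentile tails and alternative cereal weightings are not
  built-in options, only achievable by stratified runs / bundle edits.
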