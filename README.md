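# ffqkit

Processing engine for semi-quantitative food-frequency questionnaires
(FFQs): converts per-participant frequency responses and part-2 detail
answers (milk, breakfast-cereal and cooking-fat varieties) into average
daily nutrient and food-group intakes, identifies implausible reporters,
and compares two processing configurations by quintile shift.

It is aimed at nutritional epidemiologists who run cohort FFQs of the
classic two-part design: part 1 is a fixed food list (one portion weight
per line, nine frequency categories from "never or less than once a month"
to "6+ times per day"); part 2 asks which milk, cereals and fats the
participant actually uses, as free text, tick boxes and pre-assigned codes.

## The computation

For participant *i* and questionnaire line *l* with frequency category
*c(i,l)*, portion weight *w(l)* g and food-code mappings
*(f, p(l,f))* (proportions summing to 1, at most six codes per line):

```
grams(i,l)      = m(c(i,l)) · w(l)               m = occurrences/day multiplier
grams(i,l,f)    = grams(i,l) · p(l,f)
nutrient(i,n)   = Σ_l Σ_f grams(i,l,f) · comp(f,n) / 100
group(i,g)      = Σ_{l,f : group(f)=g} grams(i,l,f)   ("pseudonutrient": g/day)
```

Tagged substitutable slots take the participant's resolved part-2 codes:
the milk variety replaces the milk slot (optionally scaled by the milk
amount answer), and up to four resolved breakfast cereals split the cereal
slot's grams equally. Modified "without fat" fried/baked foods additionally
emit the participant's frying or baking fat at the mapping's uptake rate
(g fat per 100 g food); a ticked None/No box contributes no fat.

Outlier exclusion is two-staged: first questionnaires with ≥ 10 missing
part-1 lines, then the top and bottom 0.5 % (floor per tail) of the ratio
of energy intake to basal metabolic rate, EI:BMR, with BMR predicted from
sex- and age-band-specific linear coefficients (slope·weight + intercept,
MJ/day). Quintile-shift comparison bins both runs with cut-points (20/40/
60/80th percentiles) from the designated reference run and counts
participants whose quintile changes, and changes by more than one.

All lookups — lines, multipliers, composition per 100 g, groups, reference
lists, defaults, BMR coefficients — are delimited text files ("the data
model bundle"), so the tool is customised by editing data, not code.

## Worked example

```
$ ffqkit fixtures --preset toy --seed 5 --out demo
wrote bundle and cohort.csv (20 participants) to demo

$ ffqkit process --data-model demo/bundle --cohort demo/cohort.csv \
    --out demo/run --output-format 1,2
processed 20 participants; excluded 0 (missing lines) + 0 (EI:BMR); 20 remain
```

`demo/run/output1.csv` holds one row per participant (wide: nutrients then
food groups, average daily intakes), `output2.csv` the same data in long
format, and each output has a companion `.log` recording default-code
assignments, missing frequencies and food codes lacking nutrient data.
With 20 participants none fall in the floor-based 0.5 % tails
(floor(0.005·20) = 0 per tail), so nothing is excluded here. Comparing a
run against a re-run without free-text matching:

```
$ ffqkit process --data-model demo/bundle --cohort demo/cohort.csv \
    --out demo/run_nomatch --output-format 1 --no-text-match
$ ffqkit compare demo/run/output1.csv demo/run_nomatch/output1.csv \
    --out demo/cmp.csv
wrote 12 comparison rows to demo/cmp.csv
```

Each comparison row gives median/mean/SD/min/max for both runs and the
number and percentage of participants who changed quintile (and by > 1)
for that variable — nonzero only for variables downstream of the
milk/cereal/fat codes.

## Layout

- `src/ffqkit/data_model.py` — bundle loading, validation, round-trip
- `src/ffqkit/questionnaire_io.py` — cohort parsing, frequency sentinels
- `src/ffqkit/part2_resolution.py` — free-text matching, defaults, None/No
- `src/ffqkit/intake_engine.py` — the core grams/nutrients computation
- `src/ffqkit/exclusions.py` — BMR, EI:BMR tails, missing-line rule
- `src/ffqkit/outputs.py` — the four output formats + run log
- `src/ffqkit/compare.py` — summary stats, quintile cut-points and shifts
- `src/ffqkit/synthetic_fixtures.py` — seeded toy bundles and cohorts
- `src/ffqkit/cli.py` — `ffqkit process|compare|validate|fixtures`

See `docs/methods.md` for the model assumptions, parameter conventions and
design decisions.
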