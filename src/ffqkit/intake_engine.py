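"""Core intake computation.

For each answered part-1 line: frequency-category multiplier (occurrences
per day) x portion weight (g) gives grams of the line consumed per day.
Line grams are apportioned over the line's food-code mappings by proportion;
tagged substitutable slots take the participant's resolved part-2 codes
(milk variety, 1-4 breakfast cereals split equally). Modified "without fat"
foods additionally emit the participant's frying or baking fat at the
mapping's uptake rate (g fat per 100 g food). Nutrients follow by joining
the composition table (amount per 100 g), and food groups are accumulated as
pseudonutrients: a group's "amount" is grams per day of its member foods.

Results carry four granularities: per (line, food code), per line, and
participant totals — each an exact componentwise roll-up of the previous.
A missing frequency contributes nothing; the count of missing lines is kept
for the exclusion stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .data_model import NO_FAT, DataModel, FrequencyScheme, QuestionnaireLine
from .part2_resolution import Part2Resolution, resolve_part2
from .questionnaire_io import FrequencyValue, ParticipantRecord
from .runlog import RunLog

__all__ = [
    "EngineOptions",
    "FoodIntake",
    "LineIntake",
    "ParticipantIntake",
    "line_daily_grams",
    "apportion_to_foods",
    "apply_fat_substitution",
    "compute_participant",
    "compute_cohort",
]


@dataclass(frozen=True)
class EngineOptions:
    text_matching: bool = True
    milk_scaling: bool = True
    strict: bool = False  # promote unknown-code errors to exceptions


@dataclass
class FoodIntake:
    meal_id: int
    food_code: str
    grams_per_day: float
    nutrients: dict[str, float]
    group: str


@dataclass
class LineIntake:
    meal_id: int
    grams_per_day: float
    nutrients: dict[str, float]
    group_grams: dict[str, float]


@dataclass
class ParticipantIntake:
    participant_id: str
    nutrient_totals: dict[str, float]
    group_totals: dict[str, float]
    lines: list[LineIntake] = field(default_factory=list)
    foods: list[FoodIntake] = field(default_factory=list)
    missing_line_count: int = 0


def line_daily_grams(
    fv: FrequencyValue, line: QuestionnaireLine, scheme: FrequencyScheme
) -> float:
    """Grams of this line consumed per day: multiplier(code) x portion.

    Missing (or legacy two-frequencies) cells contribute 0 g; the caller
    counts them separately.
    """
    if not fv.answered:
        return 0.0
    return scheme.multiplier(fv.code) * line.portion_g


def apportion_to_foods(
    grams: float, line: QuestionnaireLine, res: Part2Resolution
) -> list[tuple[str, float, float]]:
    """Split line grams over food codes; returns (code, grams, fat_uptake).

    Non-substitutable mappings receive grams x proportion at their own code.
    A substitutable milk slot takes the participant's resolved milk code; a
    substitutable cereal slot's grams are split equally over the 1-4 resolved
    cereal codes. Output grams always sum to the input grams.
    """
    out: list[tuple[str, float, float]] = []
    for m in line.mappings:
        slot = grams * m.proportion
        if m.substitutable and line.part2_tag == "milk":
            out.append((res.milk_code, slot, m.fat_uptake_g_per_100g))
        elif m.substitutable and line.part2_tag == "cereal":
            share = slot / len(res.cereal_codes)
            for code in res.cereal_codes:
                out.append((code, share, m.fat_uptake_g_per_100g))
        else:
            out.append((m.food_code, slot, m.fat_uptake_g_per_100g))
    return out


def _nutrients_for(code: str, grams: float, dm: DataModel) -> tuple[dict[str, float], str, bool]:
    """(nutrients/day, group, known) for grams of a food code."""
    rec = dm.composition.get(code)
    if rec is None:
        return ({n: 0.0 for n in dm.nutrient_ids}, "", False)
    nutrients = {n: grams * rec.nutrients.get(n, 0.0) / 100.0 for n in dm.nutrient_ids}
    return (nutrients, rec.food_group, True)


def apply_fat_substitution(
    food: tuple[str, float],
    uptake_g_per_100g: float,
    line: QuestionnaireLine,
    res: Part2Resolution,
    dm: DataModel,
    log: RunLog,
    participant_id: str,
) -> list[FoodIntake]:
    """Emit the (without-fat) food intake plus its cooking-fat intake.

    The fat code comes from the line's tag (frying_fat or baking_fat); the
    NO_FAT sentinel — a ticked None/No box — yields no fat entry, as does a
    zero uptake. Fat grams are food grams x uptake / 100.
    """
    code, grams = food
    entries: list[FoodIntake] = []
    nutrients, group, known = _nutrients_for(code, grams, dm)
    if not known:
        log.error(participant_id, f"food code {code} has no nutrient data (meal_id {line.meal_id})")
    entries.append(FoodIntake(line.meal_id, code, grams, nutrients, group))

    if uptake_g_per_100g > 0 and line.part2_tag in ("frying_fat", "baking_fat"):
        fat_code = res.frying_fat_code if line.part2_tag == "frying_fat" else res.baking_fat_code
        if fat_code == NO_FAT:
            return entries
        fat_grams = grams * uptake_g_per_100g / 100.0
        fat_nutrients, fat_group, fat_known = _nutrients_for(fat_code, fat_grams, dm)
        if not fat_known:
            log.error(
                participant_id,
                f"fat code {fat_code} has no nutrient data (meal_id {line.meal_id})",
            )
        entries.append(FoodIntake(line.meal_id, fat_code, fat_grams, fat_nutrients, fat_group))
    return entries


def _zero(keys: Iterable[str]) -> dict[str, float]:
    return {k: 0.0 for k in keys}


def compute_participant(
    rec: ParticipantRecord,
    dm: DataModel,
    opts: EngineOptions = EngineOptions(),
) -> tuple[ParticipantIntake, RunLog]:
    """Full single-participant computation at all four granularities."""
    log = RunLog()
    res, notes = resolve_part2(rec.part2, dm, text_matching=opts.text_matching)
    for n in notes:
        log.note(rec.participant_id, n)

    milk_scale = dm.milk_scale(rec.part2.milk_amount_code) if opts.milk_scaling else 1.0

    intake = ParticipantIntake(
        participant_id=rec.participant_id,
        nutrient_totals=_zero(dm.nutrient_ids),
        group_totals=_zero(dm.group_scheme),
    )
    missing = 0
    for fv, line in zip(rec.part1, dm.lines):
        if not fv.answered:
            missing += 1
            log.note(rec.participant_id, f"missing frequency for meal_id {line.meal_id}")
        grams = line_daily_grams(fv, line, dm.frequency_scheme)
        if line.part2_tag == "milk":
            grams *= milk_scale
        line_intake = LineIntake(
            line.meal_id, 0.0, _zero(dm.nutrient_ids), _zero(dm.group_scheme)
        )
        for code, food_grams, uptake in apportion_to_foods(grams, line, res):
            for fi in apply_fat_substitution(
                (code, food_grams), uptake, line, res, dm, log, rec.participant_id
            ):
                if opts.strict and fi.group == "" and fi.food_code != NO_FAT:
                    raise KeyError(f"unknown food code {fi.food_code}")
                intake.foods.append(fi)
                line_intake.grams_per_day += fi.grams_per_day
                for n, v in fi.nutrients.items():
                    line_intake.nutrients[n] += v
                if fi.group:
                    line_intake.group_grams[fi.group] += fi.grams_per_day
        intake.lines.append(line_intake)
        for n, v in line_intake.nutrients.items():
            intake.nutrient_totals[n] += v
        for g, v in line_intake.group_grams.items():
            intake.group_totals[g] += v
    intake.missing_line_count = missing
    log.note(rec.participant_id, f"processed: {missing} missing part-1 frequencies")
    return intake, log


def compute_cohort(
    records: Sequence[ParticipantRecord],
    dm: DataModel,
    opts: EngineOptions = EngineOptions(),
) -> tuple[list[ParticipantIntake], RunLog]:
    """Order-preserving map of :func:`compute_participant` over a cohort.

    A participant whose computation fails is logged as an ERROR and skipped;
    the cohort run always completes.
    """
    log = RunLog()
    log.note("-", f"run start: {len(records)} participants, {len(dm.lines)} lines")
    intakes: list[ParticipantIntake] = []
    for rec in records:
        try:
            intake, plog = compute_participant(rec, dm, opts)
        except Exception as exc:  # noqa: BLE001 - cohort must not abort
            log.error(rec.participant_id, f"participant skipped: {exc}")
            continue
        intakes.append(intake)
        log.extend(plog)
    log.note("-", f"run end: {len(intakes)} participants processed")
    return intakes, log
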