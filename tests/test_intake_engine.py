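import dataclasses
import math
from dataclasses import replace

import numpy as np
import pytest

from ffqkit.data_model import (
    DEFAULT_FREQUENCIES,
    NO_FAT,
    CompositionRecord,
    FoodCodeMapping,
    FrequencyScheme,
    QuestionnaireLine,
)
from ffqkit.intake_engine import (
    EngineOptions,
    apportion_to_foods,
    apply_fat_substitution,
    compute_cohort,
    compute_participant,
    line_daily_grams,
)
from ffqkit.part2_resolution import Part2Resolution
from ffqkit.questionnaire_io import FrequencyValue, Part2Answers, ParticipantRecord
from ffqkit.runlog import RunLog
from ffqkit.synthetic_fixtures import FixtureSpec, build_data_model, generate_cohort
from ffqkit.questionnaire_io import read_cohort

from naive_oracle import naive_totals

SCHEME = FrequencyScheme(DEFAULT_FREQUENCIES)


def _line(**kw):
    defaults = dict(
        meal_id=1,
        label="x",
        portion_g=100.0,
        portion_kind="medium serving",
        part2_tag="none",
        mappings=(FoodCodeMapping("A", 1.0),),
    )
    defaults.update(kw)
    return QuestionnaireLine(**defaults)


def _res(**kw):
    defaults = dict(
        milk_code="M1",
        cereal_codes=("C1",),
        frying_fat_code="FF",
        baking_fat_code="BF",
        provenance={},
    )
    defaults.update(kw)
    return Part2Resolution(**defaults)


@pytest.mark.parametrize(
    "code, portion, expected",
    [
        (6, 60.0, 60.0),  # once a day
        (1, 999.0, 0.0),  # never
        (4, 140.0, 60.0),  # 2-4/week midpoint 3/7 -> 3/7*140
        (9, 10.0, 60.0),  # 6+/day
    ],
)
def test_line_daily_grams(code, portion, expected):
    fv = FrequencyValue("answered", code)
    assert line_daily_grams(fv, _line(portion_g=portion), SCHEME) == pytest.approx(expected)


@pytest.mark.parametrize("status", ["missing", "legacy_missing"])
def test_missing_frequency_contributes_zero(status):
    assert line_daily_grams(FrequencyValue(status), _line(), SCHEME) == 0.0


def test_apportion_proportional_split():
    line = _line(mappings=(FoodCodeMapping("A", 0.7), FoodCodeMapping("B", 0.3)))
    out = apportion_to_foods(100.0, line, _res())
    assert [(c, g) for c, g, _ in out] == [("A", pytest.approx(70.0)), ("B", pytest.approx(30.0))]


def test_apportion_zero_grams():
    line = _line(mappings=(FoodCodeMapping("A", 0.5), FoodCodeMapping("B", 0.5)))
    assert all(g == 0 for _, g, _ in apportion_to_foods(0.0, line, _res()))


def test_apportion_cereal_equal_split_conserves_mass():
    line = _line(part2_tag="cereal", mappings=(FoodCodeMapping("CER", 1.0, substitutable=True),))
    out = apportion_to_foods(80.0, line, _res(cereal_codes=("C1", "C2")))
    assert [(c, g) for c, g, _ in out] == [("C1", pytest.approx(40.0)), ("C2", pytest.approx(40.0))]
    for n in (1, 3, 4):
        codes = tuple(f"C{i}" for i in range(n))
        out = apportion_to_foods(80.0, line, _res(cereal_codes=codes))
        assert math.isclose(sum(g for _, g, _ in out), 80.0, rel_tol=1e-9)


def test_apportion_milk_substitution():
    line = _line(part2_tag="milk", mappings=(FoodCodeMapping("MILK0", 1.0, substitutable=True),))
    out = apportion_to_foods(50.0, line, _res(milk_code="M9"))
    assert out == [("M9", 50.0, 0.0)]


def _fat_dm():
    dm = build_data_model(FixtureSpec(seed=3))
    return dm


@pytest.mark.parametrize(
    "fat_code, uptake, expect_fat_grams",
    [
        ("F001", 10.0, 5.0),  # 50 g x 10/100
        (NO_FAT, 10.0, None),  # None/No box: no fat entry
        ("F001", 0.0, None),  # unmodified food: no fat entry
    ],
)
def test_fat_substitution(fat_code, uptake, expect_fat_grams):
    dm = _fat_dm()
    line = _line(part2_tag="frying_fat", mappings=(FoodCodeMapping("F002", 1.0, fat_uptake_g_per_100g=uptake),))
    log = RunLog()
    entries = apply_fat_substitution(("F002", 50.0), uptake, line, _res(frying_fat_code=fat_code), dm, log, "P1")
    if expect_fat_grams is None:
        assert len(entries) == 1
    else:
        assert len(entries) == 2
        assert entries[1].food_code == fat_code
        assert entries[1].grams_per_day == pytest.approx(expect_fat_grams)
        assert sum(e.grams_per_day for e in entries) == pytest.approx(50.0 + expect_fat_grams)


def test_fat_code_without_composition_logs_error():
    dm = _fat_dm()
    line = _line(part2_tag="baking_fat", mappings=(FoodCodeMapping("F002", 1.0, fat_uptake_g_per_100g=8.0),))
    log = RunLog()
    entries = apply_fat_substitution(("F002", 100.0), 8.0, line, _res(baking_fat_code="GHOST"), dm, log, "P1")
    assert entries[1].grams_per_day == pytest.approx(8.0)
    assert all(v == 0 for v in entries[1].nutrients.values())
    assert log.count("ERROR") == 1


# ---------------------------------------------------------------------------
# whole-participant computation


def _single_line_dm():
    """One line, once-a-day, 60 g, one food with 250 kcal/100 g."""
    dm = build_data_model(FixtureSpec(seed=5))
    food = dataclasses.replace(
        dm.composition["F001"],
        nutrients={**{n: 0.0 for n in dm.nutrient_ids}, "energy_kcal": 250.0},
    )
    line = _line(meal_id=1, portion_g=60.0, mappings=(FoodCodeMapping("F001", 1.0),))
    return dataclasses.replace(dm, lines=[line], composition={**dm.composition, "F001": food})


def _record(part1, part2=Part2Answers(), pid="P1", sex="male", age=50.0, weight=80.0):
    return ParticipantRecord(pid, sex, age, weight, tuple(part1), part2)


def test_single_line_hand_arithmetic():
    dm = _single_line_dm()
    rec = _record([FrequencyValue("answered", 6)])
    intake, _ = compute_participant(rec, dm)
    assert intake.nutrient_totals["energy_kcal"] == pytest.approx(150.0)  # 60 g x 250/100
    assert intake.missing_line_count == 0


def test_all_never_participant_is_all_zero(dm):
    rec = _record([FrequencyValue("answered", 1)] * len(dm.lines))
    intake, _ = compute_participant(rec, dm)
    assert all(v == 0 for v in intake.nutrient_totals.values())
    assert all(v == 0 for v in intake.group_totals.values())


def test_missing_equals_zero_contribution_but_counts(dm):
    base = [FrequencyValue("answered", 1)] * len(dm.lines)
    with_missing = [FrequencyValue("missing")] + base[1:]
    i1, _ = compute_participant(_record(base), dm)
    i2, _ = compute_participant(_record(with_missing), dm)
    assert i1.nutrient_totals == i2.nutrient_totals
    assert i2.missing_line_count - i1.missing_line_count == 1


def test_unknown_code_zero_contribution_and_error_logged(dm):
    line = _line(meal_id=dm.lines[-1].meal_id + 1, mappings=(FoodCodeMapping("GHOST", 1.0),))
    dm2 = dataclasses.replace(dm, lines=dm.lines + [line])
    rec = _record([FrequencyValue("answered", 6)] * len(dm2.lines))
    intake, log = compute_participant(rec, dm2)
    assert log.count("ERROR") >= 1
    ghost = [f for f in intake.foods if f.food_code == "GHOST"]
    assert ghost and all(v == 0 for v in ghost[0].nutrients.values())


def test_strict_mode_raises_on_unknown_code(dm):
    line = _line(meal_id=999, mappings=(FoodCodeMapping("GHOST", 1.0),))
    dm2 = dataclasses.replace(dm, lines=dm.lines + [line])
    rec = _record([FrequencyValue("answered", 6)] * len(dm2.lines))
    with pytest.raises(KeyError):
        compute_participant(rec, dm2, EngineOptions(strict=True))


def test_aggregation_identity(intakes):
    """Totals = sum of lines = sum of foods, componentwise."""
    for intake in intakes:
        for n, total in intake.nutrient_totals.items():
            assert math.isclose(total, sum(l.nutrients[n] for l in intake.lines), rel_tol=1e-9, abs_tol=1e-12)
            assert math.isclose(total, sum(f.nutrients[n] for f in intake.foods), rel_tol=1e-9, abs_tol=1e-12)
        for g, total in intake.group_totals.items():
            assert math.isclose(total, sum(l.group_grams.get(g, 0) for l in intake.lines), rel_tol=1e-9, abs_tol=1e-12)


def test_mass_conservation(cohort, dm, intakes):
    """Sum of food grams equals sum over answered lines of multiplier x portion
    (+ fat uptake and milk scaling, which the per-line totals absorb)."""
    for rec, intake in zip(cohort, intakes):
        line_total = sum(l.grams_per_day for l in intake.lines)
        food_total = sum(f.grams_per_day for f in intake.foods)
        assert math.isclose(line_total, food_total, rel_tol=1e-9, abs_tol=1e-12)


def test_linearity_in_composition(cohort, dm):
    """Scaling every composition value by c scales every nutrient total by c."""
    c = 3.0
    scaled = {
        code: dataclasses.replace(rec, nutrients={n: c * v for n, v in rec.nutrients.items()})
        for code, rec in dm.composition.items()
    }
    dm2 = dataclasses.replace(dm, composition=scaled)
    for rec in cohort[:5]:
        i1, _ = compute_participant(rec, dm)
        i2, _ = compute_participant(rec, dm2)
        for n in dm.nutrient_ids:
            assert math.isclose(i2.nutrient_totals[n], c * i1.nutrient_totals[n], rel_tol=1e-9, abs_tol=1e-12)
        assert i1.group_totals == pytest.approx(i2.group_totals)


def test_order_equivariance(cohort, dm):
    fwd, _ = compute_cohort(cohort, dm)
    rev, _ = compute_cohort(list(reversed(cohort)), dm)
    assert [i.participant_id for i in rev] == [i.participant_id for i in reversed(fwd)]
    assert rev[0].nutrient_totals == fwd[-1].nutrient_totals


def test_cohort_run_never_aborts(dm, cohort):
    intakes, log = compute_cohort(cohort, dm)
    assert len(intakes) == len(cohort)
    assert log.count("NOTE") >= len(cohort)


@pytest.mark.parametrize("seed", range(12))
def test_engine_matches_naive_oracle(seed, tmp_path):
    """Triple-loop reference implementation agrees to 1e-9 relative."""
    spec = FixtureSpec(seed=seed, n_participants=4, text_typo_rate=0.3,
                       missing_cell_rate=0.05, dual_frequency_rate=0.05)
    dm = build_data_model(spec)
    path = tmp_path / "c.csv"
    generate_cohort(dm, spec, path)
    records, _ = read_cohort(path, dm)
    intakes, _ = compute_cohort(records, dm)
    for rec, intake in zip(records, intakes):
        nutrients, groups = naive_totals(rec, dm)
        for n in dm.nutrient_ids:
            assert math.isclose(intake.nutrient_totals[n], nutrients[n], rel_tol=1e-9, abs_tol=1e-12)
        for g in dm.group_scheme:
            assert math.isclose(intake.group_totals[g], groups[g], rel_tol=1e-9, abs_tol=1e-12)


def test_text_toggle_changes_only_part2_affected_participants(dm, cohort):
    """Disabling text matching may only change participants whose part-2
    answers resolved to something other than the defaults."""
    from ffqkit.part2_resolution import resolve_part2

    on, _ = compute_cohort(cohort, dm, EngineOptions(text_matching=True))
    off, _ = compute_cohort(cohort, dm, EngineOptions(text_matching=False))
    for rec, a, b in zip(cohort, on, off):
        res_on, _ = resolve_part2(rec.part2, dm, text_matching=True)
        res_off, _ = resolve_part2(rec.part2, dm, text_matching=False)
        if res_on == res_off:
            assert a.nutrient_totals == b.nutrient_totals
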