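"""Deliberately naive reference implementation of the intake computation.

A plain triple loop over (participant, line, mapping) with its own copies of
the frequency-to-grams rule, part-2 code substitution, equal cereal split,
fat uptake and composition join — no shared code paths with the engine
beyond the data containers. Used only as an independent oracle in tests.
"""

from ffqkit.data_model import NO_FAT, DataModel
from ffqkit.part2_resolution import normalize_name
from ffqkit.questionnaire_io import ParticipantRecord


def naive_totals(rec: ParticipantRecord, dm: DataModel) -> tuple[dict, dict]:
    """(nutrient totals/day, group grams/day) for one participant."""

    def resolve(kind: str, text: str) -> str:
        ref = dm.reference_lists[kind]
        pre = rec.part2.preassigned_codes.get(kind)
        if pre and pre in dm.composition:
            return pre
        if kind in rec.part2.none_boxes:
            return NO_FAT if ref.none_allowed else ref.default_code
        code = ref.entries.get(normalize_name(text))
        return code if code is not None else ref.default_code

    milk = resolve("milk", rec.part2.milk_text)
    frying = resolve("frying_fat", rec.part2.frying_fat_text)
    baking = resolve("baking_fat", rec.part2.baking_fat_text)

    cereals: list[str] = []
    pre = rec.part2.preassigned_codes.get("cereal")
    if pre and pre in dm.composition:
        cereals = [pre]
    elif "cereal" in rec.part2.none_boxes:
        cereals = [dm.reference_lists["cereal"].default_code]
    else:
        for t in rec.part2.cereal_texts:
            c = dm.reference_lists["cereal"].entries.get(normalize_name(t))
            if c is not None and c not in cereals:
                cereals.append(c)
        cereals = cereals[:4] or [dm.reference_lists["cereal"].default_code]

    scale = 1.0
    if rec.part2.milk_amount_code is not None and dm.milk_amounts:
        scale = dm.milk_amounts.get(rec.part2.milk_amount_code, 1.0)

    nutrients = {n: 0.0 for n in dm.nutrient_dictionary}
    groups = {g: 0.0 for g in dm.group_scheme}

    def add(code: str, grams: float) -> None:
        comp = dm.composition.get(code)
        if comp is None:
            return
        for n in nutrients:
            nutrients[n] += grams * comp.nutrients.get(n, 0.0) / 100.0
        groups[comp.food_group] += grams

    for fv, line in zip(rec.part1, dm.lines):
        if fv.status != "answered":
            continue
        mult = dict((c, m) for c, _l, m in dm.frequency_scheme.categories)[fv.code]
        line_grams = mult * line.portion_g
        if line.part2_tag == "milk":
            line_grams *= scale
        for m in line.mappings:
            slot = line_grams * m.proportion
            if m.substitutable and line.part2_tag == "milk":
                targets = [(milk, slot)]
            elif m.substitutable and line.part2_tag == "cereal":
                targets = [(c, slot / len(cereals)) for c in cereals]
            else:
                targets = [(m.food_code, slot)]
            for code, grams in targets:
                add(code, grams)
                if m.fat_uptake_g_per_100g > 0 and line.part2_tag in ("frying_fat", "baking_fat"):
                    fat = frying if line.part2_tag == "frying_fat" else baking
                    if fat != NO_FAT:
                        add(fat, grams * m.fat_uptake_g_per_100g / 100.0)
    return nutrients, groups
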