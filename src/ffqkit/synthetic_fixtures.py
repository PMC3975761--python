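"""Synthetic data-model bundles and cohorts.

Everything here is generated, toy-scale stand-in data with the *structural*
properties the engine assumes — tagged milk/cereal/fat lines, modified
without-fat foods with a nonzero fat uptake, reference lists with defaults,
a full adult BMR coefficient table — so every module is testable without any
external download. The food names, portion weights and nutrient values are
invented; no claim of dietary realism is made.

All randomness flows from the single integer seed in :class:`FixtureSpec`;
the same spec always produces byte-identical files.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_FREQUENCIES,
    CompositionRecord,
    DataModel,
    FoodCodeMapping,
    FrequencyScheme,
    QuestionnaireLine,
    ReferenceList,
    SchofieldRow,
    SchofieldTable,
    load_data_model,
    write_data_model,
)
from .part2_resolution import normalize_name
from .questionnaire_io import cohort_columns

__all__ = ["FixtureSpec", "TOY", "FULLSCALE", "build_data_model", "generate_data_model", "generate_cohort"]


@dataclass(frozen=True)
class FixtureSpec:
    n_lines: int = 10
    n_foods: int = 12
    n_nutrients: int = 8
    n_groups: int = 4
    n_participants: int = 20
    missing_cell_rate: float = 0.02
    dual_frequency_rate: float = 0.01
    text_typo_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("missing_cell_rate", "dual_frequency_rate", "text_typo_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_lines", "n_foods", "n_nutrients", "n_groups", "n_participants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


TOY = FixtureSpec()
#: Full-scale *shape*: 130 questionnaire lines, 46 nutrients, 14 food groups.
FULLSCALE = FixtureSpec(
    n_lines=130, n_foods=60, n_nutrients=46, n_groups=14, n_participants=200
)

GROUP_NAMES = (
    "alcoholic_beverages",
    "cereals_and_cereal_products",
    "eggs_and_egg_dishes",
    "fats_and_oils",
    "fish_and_fish_products",
    "fruit",
    "meat_and_meat_products",
    "milk_and_milk_products",
    "non_alcoholic_beverages",
    "nuts_and_seeds",
    "potatoes",
    "soups_and_sauces",
    "sugars",
    "vegetables",
)

_BASE_NUTRIENTS = (
    ("energy_kcal", "Energy", "kcal"),
    ("energy_kj", "Energy", "kJ"),
    ("protein_g", "Protein", "g"),
    ("fat_g", "Fat", "g"),
    ("carbohydrate_g", "Carbohydrate", "g"),
    ("fibre_g", "Fibre", "g"),
    ("vitamin_c_mg", "Vitamin C", "mg"),
    ("iron_mg", "Iron", "mg"),
)

_MILK_NAMES = ("skimmed milk", "semi skimmed milk", "whole milk", "soya milk")
_CEREAL_NAMES = ("cornflakes", "muesli", "bran flakes", "crunchy oat cereal", "porridge oats")
_FRYING_NAMES = ("vegetable oil", "sunflower oil", "lard", "olive oil")
_BAKING_NAMES = ("butter", "margarine", "solid vegetable oil")

#: Adult BMR prediction bands (MJ/day = slope x weight_kg + intercept).
SCHOFIELD_ROWS = (
    SchofieldRow("male", 18.0, 30.0, 0.063, 2.896),
    SchofieldRow("male", 30.0, 60.0, 0.048, 3.653),
    SchofieldRow("male", 60.0, 120.0, 0.049, 2.459),
    SchofieldRow("female", 18.0, 30.0, 0.062, 2.036),
    SchofieldRow("female", 30.0, 60.0, 0.034, 3.538),
    SchofieldRow("female", 60.0, 120.0, 0.038, 2.755),
)

PORTION_KIND_CYCLE = ("medium serving", "standard unit", "household measure")


def build_data_model(spec: FixtureSpec = TOY) -> DataModel:
    """Construct an in-memory toy data model (deterministic in spec.seed)."""
    rng = np.random.default_rng(spec.seed)

    nutrient_dictionary: dict[str, tuple[str, str]] = {}
    for nid, name, unit in _BASE_NUTRIENTS[: max(2, min(spec.n_nutrients, len(_BASE_NUTRIENTS)))]:
        nutrient_dictionary[nid] = (name, unit)
    for i in range(len(nutrient_dictionary), spec.n_nutrients):
        nutrient_dictionary[f"nutrient_{i + 1:02d}"] = (f"Nutrient {i + 1}", "mg")

    groups = GROUP_NAMES[: min(spec.n_groups, len(GROUP_NAMES))]
    if "milk_and_milk_products" not in groups:
        groups = groups[:-1] + ("milk_and_milk_products",)

    codes = [f"F{i + 1:03d}" for i in range(spec.n_foods)]
    composition: dict[str, CompositionRecord] = {}
    for i, code in enumerate(codes):
        nutrients = {}
        for nid in nutrient_dictionary:
            if nid == "energy_kcal":
                nutrients[nid] = float(np.round(rng.uniform(20, 500), 1))
            elif nid == "energy_kj":
                nutrients[nid] = float(np.round(nutrients.get("energy_kcal", 100.0) * 4.184, 1))
            else:
                nutrients[nid] = float(np.round(rng.uniform(0, 50), 2))
        composition[code] = CompositionRecord(code, groups[i % len(groups)], nutrients)

    n_ref = len(_MILK_NAMES) + len(_CEREAL_NAMES) + len(_FRYING_NAMES) + len(_BAKING_NAMES)
    ref_codes = [codes[i % len(codes)] for i in range(n_ref)]
    it = iter(ref_codes)
    milk_entries = {normalize_name(n): next(it) for n in _MILK_NAMES}
    cereal_entries = {normalize_name(n): next(it) for n in _CEREAL_NAMES}
    frying_entries = {normalize_name(n): next(it) for n in _FRYING_NAMES}
    baking_entries = {normalize_name(n): next(it) for n in _BAKING_NAMES}
    reference_lists = {
        "milk": ReferenceList("milk", milk_entries, milk_entries[normalize_name(_MILK_NAMES[0])], False),
        "cereal": ReferenceList("cereal", cereal_entries, cereal_entries[normalize_name(_CEREAL_NAMES[0])], False),
        "frying_fat": ReferenceList("frying_fat", frying_entries, frying_entries[normalize_name(_FRYING_NAMES[0])], True),
        "baking_fat": ReferenceList("baking_fat", baking_entries, baking_entries[normalize_name(_BAKING_NAMES[0])], True),
    }

    lines: list[QuestionnaireLine] = []
    for i in range(spec.n_lines):
        meal_id = i + 1
        portion = float(np.round(rng.uniform(20, 250), 0))
        kind = PORTION_KIND_CYCLE[i % 3]
        if i == 0:
            lines.append(
                QuestionnaireLine(meal_id, "milk on its own", portion, kind, "milk",
                                  (FoodCodeMapping(reference_lists["milk"].default_code, 1.0, substitutable=True),))
            )
        elif i == 1:
            lines.append(
                QuestionnaireLine(meal_id, "breakfast cereal", portion, kind, "cereal",
                                  (FoodCodeMapping(reference_lists["cereal"].default_code, 1.0, substitutable=True),))
            )
        elif i == 2:
            food = codes[rng.integers(0, len(codes))]
            lines.append(
                QuestionnaireLine(meal_id, "fried food without fat", portion, kind, "frying_fat",
                                  (FoodCodeMapping(food, 1.0, fat_uptake_g_per_100g=10.0),))
            )
        elif i == 3:
            food = codes[rng.integers(0, len(codes))]
            lines.append(
                QuestionnaireLine(meal_id, "home baked food without fat", portion, kind, "baking_fat",
                                  (FoodCodeMapping(food, 1.0, fat_uptake_g_per_100g=6.0),))
            )
        else:
            k = int(rng.integers(1, 4))
            picked = list(rng.choice(codes, size=k, replace=False))
            weights = rng.integers(1, 6, size=k).astype(float)
            props = weights / weights.sum()
            props[-1] = 1.0 - float(props[:-1].sum())  # float-exact sum to 1
            lines.append(
                QuestionnaireLine(meal_id, f"food line {meal_id}", portion, kind, "none",
                                  tuple(FoodCodeMapping(c, float(p)) for c, p in zip(picked, props)))
            )

    return DataModel(
        frequency_scheme=FrequencyScheme(DEFAULT_FREQUENCIES),
        lines=lines,
        composition=composition,
        reference_lists=reference_lists,
        schofield=SchofieldTable(SCHOFIELD_ROWS),
        nutrient_dictionary=nutrient_dictionary,
        group_scheme=tuple(groups),
        energy_kj_nutrient_id="energy_kj",
        milk_amounts={1: 0.5, 2: 1.0, 3: 1.5, 4: 2.0},
    )


def generate_data_model(spec: FixtureSpec, bundle_path: str | Path) -> DataModel:
    """Write a bundle to disk and return it re-loaded (round-trip checked)."""
    dm = build_data_model(spec)
    write_data_model(dm, bundle_path)
    return load_data_model(bundle_path)


def _typo(name: str, rng: np.random.Generator, known: set[str]) -> str:
    """One-character edit guaranteed to miss the reference list."""
    letters = [i for i, ch in enumerate(name) if ch in string.ascii_lowercase]
    for _ in range(10):
        i = letters[rng.integers(0, len(letters))]
        sub = chr(ord("a") + int(rng.integers(0, 26)))
        cand = name[:i] + sub + name[i + 1 :]
        if normalize_name(cand) not in known:
            return cand
    return name + "zz"


def generate_cohort(
    dm: DataModel, spec: FixtureSpec, path: str | Path
) -> pd.DataFrame:
    """Write a synthetic cohort CSV for ``dm`` and return the frame.

    Participants are aged 40-79 with sex-specific body weights; frequency
    cells are drawn per line with missing (``-9``/``-4``/empty) and dual
    (``a;b``) sentinels injected at the spec's rates; part-2 texts are drawn
    from the reference lists, corrupted by a single-character typo at
    ``text_typo_rate`` (so exact matching fails and the default code is
    assigned), with occasional None/No fat boxes.
    """
    rng = np.random.default_rng(spec.seed + 1)
    cols = cohort_columns(dm)
    ref = dm.reference_lists
    known = {k: set(r.entries) for k, r in ref.items()}
    rows = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:04d}"
        sex = "male" if rng.random() < 0.5 else "female"
        age = float(np.round(rng.uniform(40, 79), 1))
        weight = float(np.round(rng.normal(78 if sex == "male" else 68, 10), 1))
        weight = max(weight, 40.0)
        row = {"id": pid, "sex": sex, "age": f"{age}", "weight": f"{weight}"}
        for ln in dm.lines:
            u = rng.random()
            if u < spec.missing_cell_rate:
                row[f"q{ln.meal_id}"] = ["-9", "-4", ""][rng.integers(0, 3)]
            elif u < spec.missing_cell_rate + spec.dual_frequency_rate:
                a, b = rng.integers(1, 10, size=2)
                row[f"q{ln.meal_id}"] = f"{a};{b}"
            else:
                # skewed toward the low-frequency categories, as in real FFQs
                code = int(min(9, rng.geometric(0.45)))
                row[f"q{ln.meal_id}"] = str(code)

        def pick(kind: str) -> str:
            names = sorted(known[kind])
            name = names[rng.integers(0, len(names))]
            if rng.random() < spec.text_typo_rate:
                name = _typo(name, rng, known[kind])
            return name

        row["milk_text"] = pick("milk")
        row["milk_amount"] = str(int(rng.integers(1, 5)))
        n_cereal = int(rng.integers(1, 4))
        for i in range(1, 5):
            row[f"cereal{i}"] = pick("cereal") if i <= n_cereal else ""
        none_flags = []
        if rng.random() < 0.1:
            none_flags.append("frying_fat")
            row["frying_fat"] = ""
        else:
            row["frying_fat"] = pick("frying_fat")
        if rng.random() < 0.1:
            none_flags.append("baking_fat")
            row["baking_fat"] = ""
        else:
            row["baking_fat"] = pick("baking_fat")
        row["none_flags"] = "|".join(none_flags)
        for kind in ("milk", "cereal", "frying_fat", "baking_fat"):
            row[f"code_{kind}"] = ""
        rows.append(row)

    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False)
    return df
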