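"""Configurable data model for food-frequency-questionnaire processing.

The processing algorithm is kept separate from the data it consumes: every
lookup the engine needs — questionnaire lines and their portion weights,
frequency-category multipliers, line-to-food-code mappings, the food
composition table, food-group assignments, part-2 reference lists with
default codes, and the BMR coefficient table — lives in a directory of
delimited text files ("the bundle") loaded into a :class:`DataModel`.
Editing the bundle customises the tool for a different questionnaire or
study population without touching code.

Bundle layout (UTF-8, comma-delimited, one header row, decimal point)::

    lines.csv            one row per (meal_id, food_code) mapping; line
                         attributes (label, portion_g, portion_kind,
                         part2_tag) repeated on every row of the line
    frequencies.csv      code (1-9), label, multiplier (occurrences/day)
    composition.csv      food_code, food_group, one column per nutrient id
                         (amount per 100 g edible food)
    nutrients.csv        nutrient_id, name, unit
    groups.csv           ordered food-group names
    reference_<kind>.csv normalized name -> food_code, for kind in
                         {milk, cereal, frying_fat, baking_fat}
    defaults.csv         kind, default_code, none_allowed
    schofield.csv        sex, age_lo, age_hi, slope (MJ/day/kg),
                         intercept (MJ/day)
    milk_amounts.csv     milk amount category -> scale factor (optional)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "NO_FAT",
    "PART2_KINDS",
    "PORTION_KINDS",
    "FrequencyScheme",
    "FoodCodeMapping",
    "QuestionnaireLine",
    "CompositionRecord",
    "ReferenceList",
    "SchofieldRow",
    "SchofieldTable",
    "DataModel",
    "ConfigError",
    "ValidationReport",
    "load_data_model",
    "write_data_model",
    "validate_data_model",
]

#: Sentinel food code meaning "no cooking fat" (the ticked None/No box).
NO_FAT = "NO_FAT"

PART2_KINDS = ("milk", "cereal", "frying_fat", "baking_fat")
PORTION_KINDS = ("medium serving", "standard unit", "household measure")

PROPORTION_TOL = 1e-9


class ConfigError(ValueError):
    """Fatal problem in the data-model bundle (missing table, bad invariant)."""


@dataclass(frozen=True)
class FrequencyScheme:
    """The nine ordered consumption-frequency categories.

    Code 1 is "never or less than once a month" and must carry multiplier 0;
    code 9 is "6+ times per day". ``multiplier`` is average occurrences per
    day for the category.
    """

    categories: tuple[tuple[int, str, float], ...]

    def multiplier(self, code: int) -> float:
        for c, _label, m in self.categories:
            if c == code:
                return m
        raise KeyError(f"unknown frequency code {code}")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(c for c, _l, _m in self.categories)


#: Default frequency multipliers (occurrences/day). The nine category labels
#: constrain but do not fix the midpoints; this table is an editable
#: convention shipped with the tool, not part of the algorithm.
DEFAULT_FREQUENCIES: tuple[tuple[int, str, float], ...] = (
    (1, "never or less than once a month", 0.0),
    (2, "1-3 per month", 2.0 / 30.44),
    (3, "once a week", 1.0 / 7.0),
    (4, "2-4 per week", 3.0 / 7.0),
    (5, "5-6 per week", 5.5 / 7.0),
    (6, "once a day", 1.0),
    (7, "2-3 per day", 2.5),
    (8, "4-5 per day", 4.5),
    (9, "6+ per day", 6.0),
)


@dataclass(frozen=True)
class FoodCodeMapping:
    food_code: str
    proportion: float
    substitutable: bool = False
    fat_uptake_g_per_100g: float = 0.0


@dataclass(frozen=True)
class QuestionnaireLine:
    meal_id: int
    label: str
    portion_g: float
    portion_kind: str
    part2_tag: str  # "none" or one of PART2_KINDS
    mappings: tuple[FoodCodeMapping, ...]


@dataclass(frozen=True)
class CompositionRecord:
    food_code: str
    food_group: str
    nutrients: dict[str, float]


@dataclass(frozen=True)
class ReferenceList:
    kind: str
    entries: dict[str, str]  # normalized name -> food code
    default_code: str
    none_allowed: bool


@dataclass(frozen=True)
class SchofieldRow:
    sex: str
    age_lo: float
    age_hi: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class SchofieldTable:
    rows: tuple[SchofieldRow, ...]

    def lookup(self, sex: str, age: float) -> SchofieldRow:
        for row in self.rows:
            if row.sex == sex and row.age_lo <= age < row.age_hi:
                return row
        raise ValueError(f"no BMR coefficient band for sex={sex!r}, age={age}")


@dataclass
class DataModel:
    frequency_scheme: FrequencyScheme
    lines: list[QuestionnaireLine]
    composition: dict[str, CompositionRecord]
    reference_lists: dict[str, ReferenceList]
    schofield: SchofieldTable
    nutrient_dictionary: dict[str, tuple[str, str]]  # id -> (name, unit)
    group_scheme: tuple[str, ...]
    energy_kj_nutrient_id: str
    milk_amounts: dict[int, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def nutrient_ids(self) -> tuple[str, ...]:
        return tuple(self.nutrient_dictionary)

    def line_index(self) -> dict[int, QuestionnaireLine]:
        return {ln.meal_id: ln for ln in self.lines}

    def known_codes(self) -> set[str]:
        return set(self.composition)

    def milk_scale(self, amount_code: int | None) -> float:
        """Scale factor for milk-tagged lines from the part-2 amount answer."""
        if amount_code is None or not self.milk_amounts:
            return 1.0
        return self.milk_amounts.get(amount_code, 1.0)


# ---------------------------------------------------------------------------
# loading

_REQUIRED_TABLES = (
    "lines.csv",
    "frequencies.csv",
    "composition.csv",
    "nutrients.csv",
    "groups.csv",
    "defaults.csv",
    "schofield.csv",
)


def _read(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def load_data_model(bundle_path: str | Path) -> DataModel:
    """Load and check a data-model bundle directory.

    Structural invariant violations (missing table, duplicate meal_id or
    frequency code, mapping proportions not summing to 1) raise
    :class:`ConfigError`. Food codes referenced by a line or reference list
    but absent from the composition table are *warnings*, collected on the
    returned model: such codes are processed as zero nutrients and logged at
    run time rather than rejected here.
    """
    bundle = Path(bundle_path)
    if not bundle.is_dir():
        raise ConfigError(f"data-model bundle not found: {bundle}")
    for name in _REQUIRED_TABLES:
        if not (bundle / name).is_file():
            raise ConfigError(f"missing data-model table: {name}")

    freq_df = _read(bundle / "frequencies.csv")
    codes = [int(c) for c in freq_df["code"]]
    if len(codes) != len(set(codes)):
        raise ConfigError("duplicate frequency code in frequencies.csv")
    categories = tuple(
        (int(r["code"]), r["label"], float(r["multiplier"]))
        for _, r in freq_df.iterrows()
    )
    scheme = FrequencyScheme(tuple(sorted(categories)))

    nutr_df = _read(bundle / "nutrients.csv")
    nutrient_dictionary = {
        r["nutrient_id"]: (r["name"], r["unit"]) for _, r in nutr_df.iterrows()
    }

    groups = tuple(_read(bundle / "groups.csv")["group"])

    comp_df = _read(bundle / "composition.csv")
    nutrient_cols = [c for c in comp_df.columns if c not in ("food_code", "food_group")]
    composition: dict[str, CompositionRecord] = {}
    for _, r in comp_df.iterrows():
        composition[r["food_code"]] = CompositionRecord(
            food_code=r["food_code"],
            food_group=r["food_group"],
            nutrients={c: float(r[c]) for c in nutrient_cols},
        )

    lines_df = _read(bundle / "lines.csv")
    lines: list[QuestionnaireLine] = []
    warnings: list[str] = []
    for meal_id, grp in lines_df.groupby(lines_df["meal_id"].astype(int), sort=True):
        first = grp.iloc[0]
        mappings = tuple(
            FoodCodeMapping(
                food_code=r["food_code"],
                proportion=float(r["proportion"]),
                substitutable=r["substitutable"].strip().lower() in ("1", "true", "yes"),
                fat_uptake_g_per_100g=float(r.get("fat_uptake_g_per_100g", "0") or 0),
            )
            for _, r in grp.iterrows()
        )
        if not 1 <= len(mappings) <= 6:
            raise ConfigError(f"meal_id {meal_id}: lines map to 1-6 food codes, got {len(mappings)}")
        total = sum(m.proportion for m in mappings)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=PROPORTION_TOL):
            raise ConfigError(
                f"meal_id {meal_id}: mapping proportions sum to {total!r}, expected 1"
            )
        lines.append(
            QuestionnaireLine(
                meal_id=int(meal_id),
                label=first["label"],
                portion_g=float(first["portion_g"]),
                portion_kind=first["portion_kind"],
                part2_tag=first["part2_tag"] or "none",
                mappings=mappings,
            )
        )
    ids = [ln.meal_id for ln in lines]
    if len(ids) != len(set(ids)):  # pragma: no cover - groupby already dedupes
        raise ConfigError("duplicate meal_id in lines.csv")

    defaults_df = _read(bundle / "defaults.csv")
    defaults = {
        r["kind"]: (r["default_code"], r["none_allowed"].strip().lower() in ("1", "true", "yes"))
        for _, r in defaults_df.iterrows()
    }
    reference_lists: dict[str, ReferenceList] = {}
    for kind in PART2_KINDS:
        ref_path = bundle / f"reference_{kind}.csv"
        if not ref_path.is_file():
            continue
        ref_df = _read(ref_path)
        entries = {r["name"]: r["food_code"] for _, r in ref_df.iterrows()}
        if len(entries) != len(ref_df):
            raise ConfigError(f"duplicate normalized name in reference_{kind}.csv")
        if kind not in defaults:
            raise ConfigError(f"reference list {kind!r} has no row in defaults.csv")
        default_code, none_allowed = defaults[kind]
        reference_lists[kind] = ReferenceList(kind, entries, default_code, none_allowed)

    scho_df = _read(bundle / "schofield.csv")
    schofield = SchofieldTable(
        tuple(
            SchofieldRow(
                sex=r["sex"],
                age_lo=float(r["age_lo"]),
                age_hi=float(r["age_hi"]),
                slope=float(r["slope"]),
                intercept=float(r["intercept"]),
            )
            for _, r in scho_df.iterrows()
        )
    )

    milk_amounts: dict[int, float] = {}
    ma_path = bundle / "milk_amounts.csv"
    if ma_path.is_file():
        ma_df = _read(ma_path)
        milk_amounts = {int(r["code"]): float(r["scale"]) for _, r in ma_df.iterrows()}

    energy_id = "energy_kj"
    if energy_id not in nutrient_dictionary:
        raise ConfigError("nutrient dictionary must declare an 'energy_kj' nutrient")

    dm = DataModel(
        frequency_scheme=scheme,
        lines=lines,
        composition=composition,
        reference_lists=reference_lists,
        schofield=schofield,
        nutrient_dictionary=nutrient_dictionary,
        group_scheme=groups,
        energy_kj_nutrient_id=energy_id,
        milk_amounts=milk_amounts,
        warnings=warnings,
    )
    for code in _referenced_codes(dm):
        if code not in composition and code != NO_FAT:
            warnings.append(f"food code {code} has no composition record")
    return dm


def _referenced_codes(dm: DataModel) -> Iterable[str]:
    seen: set[str] = set()
    for ln in dm.lines:
        for m in ln.mappings:
            seen.add(m.food_code)
    for ref in dm.reference_lists.values():
        seen.update(ref.entries.values())
        seen.add(ref.default_code)
    return sorted(seen)


# ---------------------------------------------------------------------------
# writing (round-trip support)


def write_data_model(dm: DataModel, bundle_path: str | Path) -> None:
    """Serialize a model back to a bundle directory (inverse of load)."""
    bundle = Path(bundle_path)
    bundle.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [{"code": c, "label": l, "multiplier": repr(m)} for c, l, m in dm.frequency_scheme.categories]
    ).to_csv(bundle / "frequencies.csv", index=False)

    pd.DataFrame(
        [{"nutrient_id": nid, "name": n, "unit": u} for nid, (n, u) in dm.nutrient_dictionary.items()]
    ).to_csv(bundle / "nutrients.csv", index=False)

    pd.DataFrame({"group": list(dm.group_scheme)}).to_csv(bundle / "groups.csv", index=False)

    comp_rows = []
    for rec in dm.composition.values():
        row = {"food_code": rec.food_code, "food_group": rec.food_group}
        row.update({k: repr(v) for k, v in rec.nutrients.items()})
        comp_rows.append(row)
    pd.DataFrame(comp_rows).to_csv(bundle / "composition.csv", index=False)

    line_rows = []
    for ln in dm.lines:
        for m in ln.mappings:
            line_rows.append(
                {
                    "meal_id": ln.meal_id,
                    "label": ln.label,
                    "portion_g": repr(ln.portion_g),
                    "portion_kind": ln.portion_kind,
                    "part2_tag": ln.part2_tag,
                    "food_code": m.food_code,
                    "proportion": repr(m.proportion),
                    "substitutable": int(m.substitutable),
                    "fat_uptake_g_per_100g": repr(m.fat_uptake_g_per_100g),
                }
            )
    pd.DataFrame(line_rows).to_csv(bundle / "lines.csv", index=False)

    pd.DataFrame(
        [
            {"kind": ref.kind, "default_code": ref.default_code, "none_allowed": int(ref.none_allowed)}
            for ref in dm.reference_lists.values()
        ]
    ).to_csv(bundle / "defaults.csv", index=False)
    for ref in dm.reference_lists.values():
        pd.DataFrame(
            [{"name": n, "food_code": c} for n, c in ref.entries.items()]
        ).to_csv(bundle / f"reference_{ref.kind}.csv", index=False)

    pd.DataFrame(
        [
            {
                "sex": r.sex,
                "age_lo": repr(r.age_lo),
                "age_hi": repr(r.age_hi),
                "slope": repr(r.slope),
                "intercept": repr(r.intercept),
            }
            for r in dm.schofield.rows
        ]
    ).to_csv(bundle / "schofield.csv", index=False)

    if dm.milk_amounts:
        pd.DataFrame(
            [{"code": c, "scale": repr(s)} for c, s in dm.milk_amounts.items()]
        ).to_csv(bundle / "milk_amounts.csv", index=False)


# ---------------------------------------------------------------------------
# validation

ValidationReport = list[tuple[str, str]]  # (severity, message)


def validate_data_model(dm: DataModel) -> ValidationReport:
    """Cross-check every declared invariant; report, never raise.

    Returns an empty list iff the model is fully consistent. Severities are
    ``"error"`` (invariant broken) and ``"warning"`` (processable but logged,
    e.g. a referenced food code with no composition record).
    """
    report: ValidationReport = []

    codes = dm.frequency_scheme.codes
    if sorted(codes) != list(range(1, 10)):
        report.append(("error", f"frequency codes must be exactly 1..9, got {sorted(codes)}"))
    else:
        mults = [dm.frequency_scheme.multiplier(c) for c in range(1, 10)]
        if mults[0] != 0:
            report.append(("error", "frequency code 1 (never) must have multiplier 0"))
        if any(b < a for a, b in zip(mults, mults[1:])):
            report.append(("error", "frequency multipliers must be non-decreasing in code"))
        if any(m < 0 for m in mults):
            report.append(("error", "frequency multipliers must be >= 0"))

    seen_ids: set[int] = set()
    for ln in dm.lines:
        if ln.meal_id in seen_ids:
            report.append(("error", f"duplicate meal_id {ln.meal_id}"))
        seen_ids.add(ln.meal_id)
        if ln.portion_g <= 0:
            report.append(("error", f"meal_id {ln.meal_id}: portion_g must be > 0"))
        if ln.portion_kind not in PORTION_KINDS:
            report.append(("error", f"meal_id {ln.meal_id}: unknown portion_kind {ln.portion_kind!r}"))
        if ln.part2_tag not in ("none",) + PART2_KINDS:
            report.append(("error", f"meal_id {ln.meal_id}: unknown part2_tag {ln.part2_tag!r}"))
        if not 1 <= len(ln.mappings) <= 6:
            report.append(("error", f"meal_id {ln.meal_id}: {len(ln.mappings)} mappings (1-6 allowed)"))
        total = sum(m.proportion for m in ln.mappings)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=PROPORTION_TOL):
            report.append(("error", f"meal_id {ln.meal_id}: proportions sum to {total}"))
        for m in ln.mappings:
            if not 0 <= m.proportion <= 1:
                report.append(("error", f"meal_id {ln.meal_id}: proportion {m.proportion} outside [0,1]"))
            if m.fat_uptake_g_per_100g < 0:
                report.append(("error", f"meal_id {ln.meal_id}: negative fat uptake for {m.food_code}"))
            if m.substitutable and ln.part2_tag not in dm.reference_lists:
                report.append(
                    (
                        "error",
                        f"meal_id {ln.meal_id}: substitutable slot tagged {ln.part2_tag!r} "
                        "has no matching reference list",
                    )
                )

    group_set = set(dm.group_scheme)
    for rec in dm.composition.values():
        if rec.food_group not in group_set:
            report.append(("error", f"food code {rec.food_code}: unknown group {rec.food_group!r}"))
        for nid, amount in rec.nutrients.items():
            if nid not in dm.nutrient_dictionary:
                report.append(("error", f"food code {rec.food_code}: undeclared nutrient {nid!r}"))
            if amount < 0:
                report.append(("error", f"food code {rec.food_code}: negative amount for nutrient {nid}"))

    for ref in dm.reference_lists.values():
        if ref.default_code not in dm.composition:
            report.append(("error", f"reference list {ref.kind}: default code {ref.default_code} not in composition"))

    by_sex: dict[str, list[SchofieldRow]] = {}
    for r in dm.schofield.rows:
        by_sex.setdefault(r.sex, []).append(r)
        if r.slope < 0:
            report.append(("error", f"BMR table: negative slope for {r.sex} {r.age_lo}-{r.age_hi}"))
    for sex, rows in by_sex.items():
        rows = sorted(rows, key=lambda r: r.age_lo)
        for a, b in zip(rows, rows[1:]):
            if not math.isclose(a.age_hi, b.age_lo):
                report.append(("error", f"BMR table: {sex} age bands not contiguous at {a.age_hi}"))
        if rows and (rows[0].age_lo > 18 or rows[-1].age_hi < 120):
            report.append(("error", f"BMR table: {sex} bands do not cover [18, 120)"))

    if dm.energy_kj_nutrient_id not in dm.nutrient_dictionary:
        report.append(("error", f"energy nutrient {dm.energy_kj_nutrient_id!r} not in dictionary"))

    for code in _referenced_codes(dm):
        if code not in dm.composition and code != NO_FAT:
            report.append(("warning", f"food code {code} has no composition record"))

    return report
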