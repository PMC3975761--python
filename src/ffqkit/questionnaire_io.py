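"""Cohort file parsing.

One row per participant: identifier, sex, age, body weight, one frequency
cell per questionnaire line, then the part-2 detail answers (milk variety
text, milk amount category, up to four breakfast-cereal texts, frying- and
baking-fat texts, None/No tick boxes, and optional pre-assigned food codes).

Frequency-cell conventions:

* ``'1'``..``'9'`` — the nine consumption-frequency categories;
* empty or ``'-9'`` — frequency not recorded (missing);
* ``'-4'`` — legacy marker for "two frequencies ticked", treated as missing;
* ``'a;b'`` — both frequencies entered; the *first* value is processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .data_model import DataModel, PART2_KINDS

__all__ = [
    "FrequencyValue",
    "Part2Answers",
    "ParticipantRecord",
    "CohortFormatError",
    "parse_frequency_cell",
    "read_cohort",
    "cohort_columns",
]

#: Unicode minus occasionally produced by hand-keyed spreadsheets.
_MINUS = "−"


class CohortFormatError(ValueError):
    """Fatal cohort-file problem (duplicate id, column-count mismatch)."""


@dataclass(frozen=True)
class FrequencyValue:
    status: str  # "answered" | "missing" | "legacy_missing"
    code: int | None = None
    raw: str = ""

    @property
    def answered(self) -> bool:
        return self.status == "answered"


@dataclass(frozen=True)
class Part2Answers:
    milk_text: str = ""
    milk_amount_code: int | None = None
    cereal_texts: tuple[str, ...] = ()
    frying_fat_text: str = ""
    baking_fat_text: str = ""
    none_boxes: frozenset[str] = frozenset()
    preassigned_codes: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    sex: str  # "male" | "female"
    age: float | None
    weight: float | None
    part1: tuple[FrequencyValue, ...]
    part2: Part2Answers


def parse_frequency_cell(cell: str, where: str = "") -> FrequencyValue:
    """Map one part-1 cell to a :class:`FrequencyValue`.

    Deterministic and total over the documented token set; anything else
    raises ``ValueError`` naming the offending location.
    """
    raw = cell
    token = cell.strip().replace(_MINUS, "-")
    if token == "":
        return FrequencyValue("missing", raw=raw)
    if token == "-9":
        return FrequencyValue("missing", raw=raw)
    if token == "-4":
        return FrequencyValue("legacy_missing", raw=raw)
    if ";" in token:
        first = token.split(";", 1)[0]
        inner = parse_frequency_cell(first, where)
        return FrequencyValue(inner.status, inner.code, raw=raw)
    try:
        code = int(token)
    except ValueError:
        raise ValueError(f"unparseable frequency cell {cell!r}{' at ' + where if where else ''}")
    if not 1 <= code <= 9:
        raise ValueError(f"frequency code {code} outside 1..9{' at ' + where if where else ''}")
    return FrequencyValue("answered", code, raw=raw)


def cohort_columns(dm: DataModel) -> list[str]:
    """Header of a cohort file for this data model (the documented layout)."""
    cols = ["id", "sex", "age", "weight"]
    cols += [f"q{ln.meal_id}" for ln in dm.lines]
    cols += ["milk_text", "milk_amount"]
    cols += [f"cereal{i}" for i in range(1, 5)]
    cols += ["frying_fat", "baking_fat", "none_flags"]
    cols += [f"code_{k}" for k in PART2_KINDS]
    return cols


def _parse_part2(row: pd.Series) -> Part2Answers:
    none_flags = str(row.get("none_flags", "")).strip()
    none_boxes = frozenset(
        tok for tok in (t.strip() for t in none_flags.split("|")) if tok in PART2_KINDS
    )
    preassigned = {
        kind: str(row.get(f"code_{kind}", "")).strip()
        for kind in PART2_KINDS
        if str(row.get(f"code_{kind}", "")).strip()
    }
    amount_raw = str(row.get("milk_amount", "")).strip()
    amount = int(amount_raw) if amount_raw else None
    cereals = tuple(
        str(row.get(f"cereal{i}", "")).strip()
        for i in range(1, 5)
        if str(row.get(f"cereal{i}", "")).strip()
    )
    return Part2Answers(
        milk_text=str(row.get("milk_text", "")).strip(),
        milk_amount_code=amount,
        cereal_texts=cereals,
        frying_fat_text=str(row.get("frying_fat", "")).strip(),
        baking_fat_text=str(row.get("baking_fat", "")).strip(),
        none_boxes=none_boxes,
        preassigned_codes=preassigned,
    )


def read_cohort(
    path: str | Path, dm: DataModel
) -> tuple[list[ParticipantRecord], list[str]]:
    """Parse a cohort CSV into participant records.

    Row order is preserved. Malformed rows (bad frequency token, non-numeric
    age/weight) are skipped with a message in ``issues``, never silently
    dropped. A duplicate participant id or a frequency-column count that does
    not match the data model is fatal.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    q_cols = [c for c in df.columns if c.startswith("q") and c[1:].isdigit()]
    if len(q_cols) != len(dm.lines):
        raise CohortFormatError(
            f"cohort has {len(q_cols)} frequency columns, data model defines {len(dm.lines)} lines"
        )
    ids = df["id"].tolist()
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CohortFormatError(f"duplicate participant id(s): {', '.join(dupes)}")

    expected_q = [f"q{ln.meal_id}" for ln in dm.lines]
    records: list[ParticipantRecord] = []
    issues: list[str] = []
    for idx, row in df.iterrows():
        pid = row["id"]
        try:
            part1 = []
            for col in expected_q:
                fv = parse_frequency_cell(row[col], where=f"row {pid}, column {col}")
                if ";" in fv.raw:
                    issues.append(
                        f"participant {pid}: dual frequency {fv.raw!r} in {col}; first value used"
                    )
                part1.append(fv)
            sex = row["sex"].strip().lower()
            if sex not in ("male", "female"):
                raise ValueError(f"unknown sex {row['sex']!r}")
            age = float(row["age"]) if row["age"].strip() else None
            weight = float(row["weight"]) if row["weight"].strip() else None
            if age is not None and age <= 0:
                raise ValueError(f"age must be > 0, got {age}")
            if weight is not None and weight <= 0:
                raise ValueError(f"weight must be > 0, got {weight}")
        except ValueError as exc:
            issues.append(f"row {idx + 1} (participant {pid}) skipped: {exc}")
            continue
        records.append(
            ParticipantRecord(
                participant_id=pid,
                sex=sex,
                age=age,
                weight=weight,
                part1=tuple(part1),
                part2=_parse_part2(row),
            )
        )
    return records, issues
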