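"""Serialize intake results as the four documented output formats.

* Format 1 — one row per participant, wide: id + one column per nutrient and
  per food group (average daily intake). For import into stats packages.
* Format 2 — the same data in long format: one row per (participant,
  variable).
* Format 3 — one row per (participant, meal_id): grams of food consumed and
  daily nutrient / group intakes for each questionnaire line.
* Format 4 — the most detailed: one row per (participant, meal_id,
  food_code) with grams and nutrients.

A log file accompanies each output file (same basename + ``.log``). Column
order is nutrient-dictionary order then group-scheme order, stable across
runs. Values are rounded only here, at serialization.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import pandas as pd

from .data_model import DataModel
from .intake_engine import ParticipantIntake
from .runlog import RunLog

__all__ = ["emit", "output_frame", "missing_counts_from_log", "write_outputs"]

_MISSING_RE = re.compile(r"^missing frequency for meal_id ")


def _columns(dm: DataModel) -> list[str]:
    return list(dm.nutrient_ids) + [f"group_{g}" for g in dm.group_scheme]


def _round(x: float, digits: int | None) -> float:
    if digits is None:
        return x
    if x == 0:
        return 0.0
    return float(f"{x:.{digits}g}")


def output_frame(
    results: Sequence[ParticipantIntake],
    fmt: int,
    dm: DataModel,
    round_digits: int | None = 6,
) -> pd.DataFrame:
    """Build the DataFrame for one output format (1-4)."""
    cols = _columns(dm)

    def values(nutrients: dict[str, float], groups: dict[str, float]) -> list[float]:
        return [_round(nutrients[n], round_digits) for n in dm.nutrient_ids] + [
            _round(groups.get(g, 0.0), round_digits) for g in dm.group_scheme
        ]

    if fmt == 1:
        rows = [
            [r.participant_id] + values(r.nutrient_totals, r.group_totals)
            for r in results
        ]
        return pd.DataFrame(rows, columns=["id"] + cols)
    if fmt == 2:
        rows = []
        for r in results:
            for name, v in zip(cols, values(r.nutrient_totals, r.group_totals)):
                rows.append([r.participant_id, name, v])
        return pd.DataFrame(rows, columns=["id", "variable", "value"])
    if fmt == 3:
        rows = []
        for r in results:
            for ln in r.lines:
                rows.append(
                    [r.participant_id, ln.meal_id, _round(ln.grams_per_day, round_digits)]
                    + values(ln.nutrients, ln.group_grams)
                )
        return pd.DataFrame(rows, columns=["id", "meal_id", "grams_per_day"] + cols)
    if fmt == 4:
        rows = []
        for r in results:
            for fi in r.foods:
                group_grams = {fi.group: fi.grams_per_day} if fi.group else {}
                rows.append(
                    [
                        r.participant_id,
                        fi.meal_id,
                        fi.food_code,
                        _round(fi.grams_per_day, round_digits),
                    ]
                    + values(fi.nutrients, group_grams)
                )
        return pd.DataFrame(
            rows, columns=["id", "meal_id", "food_code", "grams_per_day"] + cols
        )
    raise ValueError(f"unknown output format {fmt}; expected 1, 2, 3 or 4")


def emit(
    results: Sequence[ParticipantIntake],
    fmt: int,
    sink: str | Path,
    dm: DataModel,
    round_digits: int | None = 6,
) -> int:
    """Write one output format to ``sink``; returns the row count written."""
    df = output_frame(results, fmt, dm, round_digits)
    df.to_csv(sink, index=False)
    return len(df)


def write_outputs(
    results: Sequence[ParticipantIntake],
    formats: Sequence[int],
    out_dir: str | Path,
    dm: DataModel,
    log: RunLog,
    round_digits: int | None = 6,
) -> dict[int, Path]:
    """Write each requested format plus its companion ``.log`` file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[int, Path] = {}
    for fmt in formats:
        path = out / f"output{fmt}.csv"
        emit(results, fmt, path, dm, round_digits)
        log.write(path.with_suffix(".log"))
        written[fmt] = path
    return written


def missing_counts_from_log(log: RunLog) -> dict[str, int]:
    """Per-participant missing-frequency counts recomputed from log entries.

    Counts the per-line "missing frequency" NOTEs, so the 10-or-more-missing
    exclusion can be replayed from a log file alone.
    """
    counts: dict[str, int] = {}
    for e in log.entries:
        if e.level == "NOTE" and _MISSING_RE.match(e.message):
            counts[e.participant_id] = counts.get(e.participant_id, 0) + 1
    return counts
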