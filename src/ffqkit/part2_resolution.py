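"""Resolve part-2 answers (free text, tick boxes, defaults) into food codes.

The milk, breakfast-cereal, frying-fat and baking-fat varieties a participant
writes in part 2 are matched against reference lists of food codes; the
resolved codes are substituted into the tagged part-1 lines by the intake
engine. Matching is exact after name normalization — no fuzzy assignment, so
a run is exactly reproducible. Where nothing matches, the list's default code
is assigned and noted; a ticked None/No box on a fat question yields the
NO_FAT sentinel (no cooking fat consumed).

Precedence per kind: pre-assigned code > None/No box > exact normalized
match > default code. Up to four cereal codes are kept (deduplicated, order
preserved); extra matches are truncated with a note.
"""

from __future__ import annotations

import difflib
import re
import unicodedata
from dataclasses import dataclass

from .data_model import NO_FAT, DataModel, PART2_KINDS
from .questionnaire_io import Part2Answers

__all__ = ["Part2Resolution", "normalize_name", "resolve_part2"]

_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")

MAX_CEREALS = 4


def normalize_name(text: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace. Idempotent."""
    text = unicodedata.normalize("NFKC", text).casefold()
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


@dataclass(frozen=True)
class Part2Resolution:
    milk_code: str
    cereal_codes: tuple[str, ...]
    frying_fat_code: str  # food code or NO_FAT
    baking_fat_code: str
    provenance: dict[str, str]  # kind -> matched_text|preassigned|default|none_box


def _match_text(text: str, kind: str, dm: DataModel, notes: list[str]) -> str | None:
    ref = dm.reference_lists[kind]
    norm = normalize_name(text)
    if not norm:
        return None
    code = ref.entries.get(norm)
    if code is not None:
        return code
    suggestions = difflib.get_close_matches(norm, list(ref.entries), n=3, cutoff=0.75)
    if suggestions:
        notes.append(
            f"{kind} text {text!r} has no exact match; close reference entries: "
            + ", ".join(suggestions)
        )
    return None


def _resolve_single(
    kind: str,
    text: str,
    answers: Part2Answers,
    dm: DataModel,
    notes: list[str],
) -> tuple[str, str]:
    """Resolve one non-cereal kind; returns (code, provenance)."""
    ref = dm.reference_lists[kind]
    pre = answers.preassigned_codes.get(kind)
    if pre:
        if pre in dm.composition:
            return pre, "preassigned"
        notes.append(f"{kind}: pre-assigned code {pre} not in composition table; falling back")
    if kind in answers.none_boxes:
        if text:
            notes.append(f"{kind}: both None/No box and text {text!r} present; box honoured")
        if ref.none_allowed:
            return NO_FAT, "none_box"
        notes.append(f"{kind}: None/No box ticked but not allowed for this list; default used")
        return ref.default_code, "default"
    code = _match_text(text, kind, dm, notes)
    if code is not None:
        return code, "matched_text"
    notes.append(f"{kind}: default code {ref.default_code} assigned")
    return ref.default_code, "default"


def resolve_part2(
    answers: Part2Answers,
    dm: DataModel,
    *,
    text_matching: bool = True,
) -> tuple[Part2Resolution, list[str]]:
    """Resolve all four kinds for one participant.

    With ``text_matching=False`` the free-text step is skipped entirely, so
    every kind falls to its pre-assigned code, None/No box, or default —
    the condition used to measure the effect of text matching on intakes.
    """
    notes: list[str] = []
    if not text_matching:
        answers = Part2Answers(
            milk_text="",
            milk_amount_code=answers.milk_amount_code,
            cereal_texts=(),
            frying_fat_text="",
            baking_fat_text="",
            none_boxes=answers.none_boxes,
            preassigned_codes=answers.preassigned_codes,
        )

    milk_code, milk_prov = _resolve_single("milk", answers.milk_text, answers, dm, notes)
    frying_code, frying_prov = _resolve_single(
        "frying_fat", answers.frying_fat_text, answers, dm, notes
    )
    baking_code, baking_prov = _resolve_single(
        "baking_fat", answers.baking_fat_text, answers, dm, notes
    )

    ref = dm.reference_lists["cereal"]
    cereal_codes: list[str] = []
    cereal_prov = None
    pre = answers.preassigned_codes.get("cereal")
    if pre:
        if pre in dm.composition:
            cereal_codes, cereal_prov = [pre], "preassigned"
        else:
            notes.append(f"cereal: pre-assigned code {pre} not in composition table; falling back")
    if cereal_prov is None and "cereal" in answers.none_boxes:
        cereal_codes, cereal_prov = [ref.default_code], "none_box"
        notes.append("cereal: None/No box ticked; default cereal retained for tagged lines")
    if cereal_prov is None:
        for text in answers.cereal_texts:
            code = _match_text(text, "cereal", dm, notes)
            if code is not None and code not in cereal_codes:
                cereal_codes.append(code)
        if cereal_codes:
            cereal_prov = "matched_text"
            if len(cereal_codes) > MAX_CEREALS:
                notes.append(
                    f"cereal: {len(cereal_codes)} matches truncated to {MAX_CEREALS}"
                )
                cereal_codes = cereal_codes[:MAX_CEREALS]
        else:
            cereal_codes, cereal_prov = [ref.default_code], "default"
            notes.append(f"cereal: default code {ref.default_code} assigned")

    resolution = Part2Resolution(
        milk_code=milk_code,
        cereal_codes=tuple(cereal_codes),
        frying_fat_code=frying_code,
        baking_fat_code=baking_code,
        provenance={
            "milk": milk_prov,
            "cereal": cereal_prov,
            "frying_fat": frying_prov,
            "baking_fat": baking_prov,
        },
    )
    return resolution, notes
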