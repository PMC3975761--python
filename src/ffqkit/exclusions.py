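"""Outlier identification and stage-wise exclusion accounting.

Two stages, applied in a fixed order:

1. Questionnaires with 10 or more missing part-1 lines are excluded.
2. Among the remainder, each participant's reported energy intake (EI,
   kJ/day, converted to MJ/day) is divided by basal metabolic rate (BMR,
   MJ/day) predicted from sex- and age-band-specific linear coefficients
   (slope x body weight + intercept). The lowest and highest 0.5% of the
   EI:BMR ratio — implausible under- and over-reporters — are excluded.

Per tail, floor(tail x n) participants are flagged (n = the stage-2
eligible count), pooled across sexes, with ties broken by participant id
for determinism. Participants lacking the weight or age needed for BMR are
never silently imputed: they are flagged ineligible and bypass stage 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .data_model import DataModel, SchofieldTable
from .intake_engine import ParticipantIntake
from .questionnaire_io import ParticipantRecord

__all__ = [
    "ParticipantEnergy",
    "ExclusionReport",
    "ExclusionConfig",
    "schofield_bmr",
    "flag_missing_lines",
    "flag_ratio_tails",
    "apply_exclusions",
    "accounting_identity",
]

KJ_PER_MJ = 1000.0  # exact


@dataclass(frozen=True)
class ParticipantEnergy:
    participant_id: str
    ei_kj: float  # energy intake, kJ/day
    bmr_mj: float  # basal metabolic rate, MJ/day

    @property
    def ratio(self) -> float:
        """EI:BMR, dimensionless (EI converted kJ -> MJ)."""
        return (self.ei_kj / KJ_PER_MJ) / self.bmr_mj


@dataclass
class ExclusionReport:
    stage1_missing_lines: list[str] = field(default_factory=list)
    stage2_ei_bmr: list[str] = field(default_factory=list)
    ineligible_bmr: list[str] = field(default_factory=list)
    remaining: list[str] = field(default_factory=list)
    stage1_by_sex: dict[str, int] = field(default_factory=dict)
    stage2_by_sex: dict[str, int] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)
    missing_counts: dict[str, int] = field(default_factory=dict)

    @property
    def accounting(self) -> tuple[int, int, int, int]:
        """(returned_n, stage1_n, stage2_n, final_n); final = returned - s1 - s2."""
        returned = (
            len(self.stage1_missing_lines) + len(self.stage2_ei_bmr) + len(self.remaining)
        )
        return accounting_identity(
            returned, len(self.stage1_missing_lines), len(self.stage2_ei_bmr)
        )


def accounting_identity(returned_n: int, stage1_n: int, stage2_n: int) -> tuple[int, int, int, int]:
    """Stage-wise bookkeeping: the final analytical N is what the two
    exclusion stages leave of the returned questionnaires."""
    return (returned_n, stage1_n, stage2_n, returned_n - stage1_n - stage2_n)


@dataclass(frozen=True)
class ExclusionConfig:
    missing_threshold: int = 10
    tail_fraction: float = 0.005
    skip: bool = False


def schofield_bmr(sex: str, age: float, weight: float, table: SchofieldTable) -> float:
    """Predicted BMR in MJ/day: slope x weight + intercept for the sex/age band.

    No extrapolation: an age outside the table's bands is an error.
    """
    if weight <= 0:
        raise ValueError(f"weight must be > 0, got {weight}")
    row = table.lookup(sex, age)
    return row.slope * weight + row.intercept


def flag_missing_lines(intake: ParticipantIntake, threshold: int = 10) -> bool:
    """True iff the participant has >= threshold missing part-1 lines."""
    return intake.missing_line_count >= threshold


def flag_ratio_tails(
    energies: Sequence[ParticipantEnergy], tail: float = 0.005
) -> set[str]:
    """Ids in the bottom and top ``tail`` fraction of EI:BMR.

    floor(tail x n) per tail; ties broken by participant id so the flagged
    set is a deterministic function of the input.
    """
    if not energies:
        raise ValueError("no participants eligible for EI:BMR screening")
    if not 0 < tail < 0.5:
        raise ValueError(f"tail fraction must be in (0, 0.5), got {tail}")
    k = math.floor(tail * len(energies))
    if k == 0:
        return set()
    ordered = sorted(energies, key=lambda e: (e.ratio, e.participant_id))
    return {e.participant_id for e in ordered[:k]} | {
        e.participant_id for e in ordered[-k:]
    }


def apply_exclusions(
    intakes: Sequence[ParticipantIntake],
    records: Mapping[str, ParticipantRecord] | Sequence[ParticipantRecord],
    dm: DataModel,
    config: ExclusionConfig = ExclusionConfig(),
) -> ExclusionReport:
    """Run both stages in order and account for every participant.

    Stage 1 (missing lines) first; stage 2 percentile tails are computed on
    the participants stage 1 leaves, restricted to those with the age and
    weight BMR needs (the rest are reported ineligible and retained).
    """
    if not isinstance(records, Mapping):
        records = {r.participant_id: r for r in records}
    report = ExclusionReport()
    for i in intakes:
        report.missing_counts[i.participant_id] = i.missing_line_count

    if config.skip:
        report.remaining = [i.participant_id for i in intakes]
        return report

    survivors: list[ParticipantIntake] = []
    for intake in intakes:
        if flag_missing_lines(intake, config.missing_threshold):
            report.stage1_missing_lines.append(intake.participant_id)
            sex = records[intake.participant_id].sex
            report.stage1_by_sex[sex] = report.stage1_by_sex.get(sex, 0) + 1
        else:
            survivors.append(intake)

    energies: list[ParticipantEnergy] = []
    for intake in survivors:
        rec = records[intake.participant_id]
        if rec.age is None or rec.weight is None:
            report.ineligible_bmr.append(intake.participant_id)
            continue
        bmr = schofield_bmr(rec.sex, rec.age, rec.weight, dm.schofield)
        e = ParticipantEnergy(
            intake.participant_id,
            intake.nutrient_totals[dm.energy_kj_nutrient_id],
            bmr,
        )
        energies.append(e)
        report.ratios[e.participant_id] = e.ratio

    flagged = flag_ratio_tails(energies, config.tail_fraction) if energies else set()
    for intake in survivors:
        if intake.participant_id in flagged:
            report.stage2_ei_bmr.append(intake.participant_id)
            sex = records[intake.participant_id].sex
            report.stage2_by_sex[sex] = report.stage2_by_sex.get(sex, 0) + 1
        else:
            report.remaining.append(intake.participant_id)
    return report
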