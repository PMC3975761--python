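import math

import numpy as np
import pytest

from ffqkit.data_model import SchofieldTable
from ffqkit.exclusions import (
    ExclusionConfig,
    ParticipantEnergy,
    accounting_identity,
    apply_exclusions,
    flag_missing_lines,
    flag_ratio_tails,
    schofield_bmr,
)
from ffqkit.intake_engine import ParticipantIntake
from ffqkit.synthetic_fixtures import SCHOFIELD_ROWS

TABLE = SchofieldTable(SCHOFIELD_ROWS)


@pytest.mark.parametrize(
    "sex, age, weight, expected",
    [
        ("female", 45, 65, 5.748),  # 0.034*65 + 3.538
        ("male", 70, 80, 6.379),  # 0.049*80 + 2.459
        ("male", 25, 70, 0.063 * 70 + 2.896),
        ("female", 60, 60, 0.038 * 60 + 2.755),  # band boundary: 60 in [60,120)
    ],
)
def test_schofield_bmr_hand_arithmetic(sex, age, weight, expected):
    assert schofield_bmr(sex, age, weight, TABLE) == pytest.approx(expected)


def test_schofield_rejects_zero_weight():
    with pytest.raises(ValueError, match="weight"):
        schofield_bmr("male", 50, 0, TABLE)


def test_schofield_no_extrapolation_outside_bands():
    with pytest.raises(ValueError, match="band"):
        schofield_bmr("male", 15, 70, TABLE)


def _intake(pid, missing):
    return ParticipantIntake(pid, {}, {}, missing_line_count=missing)


@pytest.mark.parametrize("missing, excluded", [(10, True), (9, False), (0, False), (130, True)])
def test_missing_line_threshold_boundary(missing, excluded):
    assert flag_missing_lines(_intake("P", missing)) is excluded


def test_ratio_tails_match_full_sort_oracle():
    rng = np.random.default_rng(11)
    for n in (100, 1000, 25102):
        ratios = rng.normal(1.5, 0.4, size=n)
        energies = [ParticipantEnergy(f"P{i:05d}", float(r) * 1000 * 6.0, 6.0) for i, r in enumerate(ratios)]
        flagged = flag_ratio_tails(energies, 0.005)
        k = math.floor(0.005 * n)
        order = sorted(range(n), key=lambda i: (energies[i].ratio, energies[i].participant_id))
        expected = {energies[i].participant_id for i in order[:k]} | {
            energies[i].participant_id for i in order[n - k:]
        }
        assert flagged == expected
        assert len(flagged) == 2 * k


def test_tail_count_floor_semantics():
    energies = [ParticipantEnergy(f"P{i}", (i + 1) * 100.0, 1.0) for i in range(100)]
    assert flag_ratio_tails(energies, 0.005) == set()  # floor(0.5) = 0 per tail


def test_tied_ratios_break_by_id_deterministically():
    energies = [ParticipantEnergy(f"P{i:04d}", 9000.0, 6.0) for i in range(1000)]
    flagged = flag_ratio_tails(energies, 0.005)
    assert flagged == {f"P{i:04d}" for i in range(5)} | {f"P{i:04d}" for i in range(995, 1000)}
    assert flagged == flag_ratio_tails(list(reversed(energies)), 0.005)


def test_tails_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    ratios = rng.uniform(0.5, 3.0, size=400)
    base = [ParticipantEnergy(f"P{i}", float(r) * 1000 * 5.0, 5.0) for i, r in enumerate(ratios)]
    # exp is strictly increasing: ranks (hence flags) unchanged
    warped = [ParticipantEnergy(e.participant_id, math.exp(e.ratio) * 1000 * 5.0, 5.0) for e in base]
    assert flag_ratio_tails(base) == flag_ratio_tails(warped)


def test_accounting_identity_paper_scale_bookkeeping():
    assert accounting_identity(25351, 249, 250) == (25351, 249, 250, 24852)


def _staged_cohort(dm, n=200, n_missing=12, seed=0):
    """Records + intakes where exactly n_missing participants have >= 10
    missing lines; energy drawn so ratio tails are nontrivial."""
    from ffqkit.questionnaire_io import ParticipantRecord, FrequencyValue, Part2Answers

    rng = np.random.default_rng(seed)
    records, intakes = {}, []
    for i in range(n):
        pid = f"P{i:04d}"
        sex = "male" if i % 2 else "female"
        rec = ParticipantRecord(pid, sex, 50.0, 70.0, (), Part2Answers())
        records[pid] = rec
        missing = 10 if i < n_missing else int(rng.integers(0, 9))
        ei = float(rng.normal(9000, 2500))
        intakes.append(
            ParticipantIntake(pid, {dm.energy_kj_nutrient_id: ei}, {}, missing_line_count=missing)
        )
    return records, intakes


def test_staged_exclusions(dm):
    records, intakes = _staged_cohort(dm)
    report = apply_exclusions(intakes, records, dm, ExclusionConfig(tail_fraction=0.02))
    assert len(report.stage1_missing_lines) == 12
    # stage 2 computed on the 188 survivors: floor(0.02*188)=3 per tail
    assert len(report.stage2_ei_bmr) == 6
    r, s1, s2, final = report.accounting
    assert (r, s1, s2) == (200, 12, 6)
    assert final == r - s1 - s2 == len(report.remaining)
    assert not set(report.stage1_missing_lines) & set(report.stage2_ei_bmr)


def test_no_exclusions_leaves_everyone(dm):
    records, intakes = _staged_cohort(dm, n=50, n_missing=0)
    report = apply_exclusions(intakes, records, dm, ExclusionConfig(tail_fraction=0.005))
    # floor(0.005*50) = 0 per tail
    assert report.accounting == (50, 0, 0, 50)
    assert len(report.remaining) == 50


def test_missing_weight_makes_participant_bmr_ineligible(dm):
    from ffqkit.questionnaire_io import ParticipantRecord, Part2Answers

    records, intakes = _staged_cohort(dm, n=20, n_missing=0)
    records["P0000"] = ParticipantRecord("P0000", "male", 50.0, None, (), Part2Answers())
    report = apply_exclusions(intakes, records, dm)
    assert report.ineligible_bmr == ["P0000"]


def test_removing_unflagged_participant_changes_flags_only_via_n(dm):
    records, intakes = _staged_cohort(dm, n=400, n_missing=0, seed=9)
    report = apply_exclusions(intakes, records, dm, ExclusionConfig(tail_fraction=0.01))
    unflagged = [i for i in intakes if i.participant_id in set(report.remaining)]
    victim = unflagged[len(unflagged) // 2].participant_id
    intakes2 = [i for i in intakes if i.participant_id != victim]
    report2 = apply_exclusions(intakes2, records, dm, ExclusionConfig(tail_fraction=0.01))
    # oracle: recompute expected flags on the reduced set
    energies = [
        ParticipantEnergy(i.participant_id, i.nutrient_totals[dm.energy_kj_nutrient_id],
                          schofield_bmr(records[i.participant_id].sex, 50.0, 70.0, dm.schofield))
        for i in intakes2
    ]
    assert set(report2.stage2_ei_bmr) == flag_ratio_tails(energies, 0.01)
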