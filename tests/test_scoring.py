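"""Score engine: clipping, both overlap modes, endpoint and validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutriscore.scoring import (
    InterventionEpisode,
    PatientRecord,
    ScoreWindow,
    SupportLevel,
    ValidationError,
    WeightScheme,
    clip_episode,
    compute_patient_auc,
    daily_level_profile,
    filter_complete_followup,
    pn_outcome_at,
    validate_record,
)

from conftest import brute_force_auc, make_record, random_record


@pytest.mark.parametrize(
    "episode_days, window_days, expected",
    [
        ((90, 120), (0, 99), (90, 99)),  # boundary clip
        ((0, 10), (0, 99), (0, 10)),  # identity
        ((100, 120), (0, 99), None),  # disjoint
        ((0, 200), (50, 59), (50, 59)),  # episode spans window
    ],
)
def test_clip_episode(episode_days, window_days, expected):
    ep = InterventionEpisode("p1", SupportLevel.PN, *episode_days)
    clipped = clip_episode(ep, ScoreWindow(*window_days))
    if expected is None:
        assert clipped is None
    else:
        assert (clipped.start_day, clipped.end_day) == expected
        assert clipped.level is ep.level


@pytest.mark.parametrize("mode", ["additive", "max_per_day"])
def test_worked_score_disjoint_modalities(mode, weights, window):
    """10 d routine + 20 d enteral + 5 d PN = 10*1 + 20*4 + 5*6 = 120."""
    rec = make_record(
        [
            (SupportLevel.ROUTINE, 0, 9),
            (SupportLevel.ENTERAL, 10, 29),
            (SupportLevel.PN, 30, 34),
        ]
    )
    result = compute_patient_auc(rec, weights, window, mode)
    assert result.auc == 120.0
    assert result.days_by_level[SupportLevel.ENTERAL] == 20
    assert result.level_at_last_day is SupportLevel.NONE


def test_full_window_bespoke_gives_max_score(weights, window):
    rec = make_record([(SupportLevel.BESPOKE_PN, 0, 99)])
    assert compute_patient_auc(rec, weights, window).auc == 700.0


def test_empty_record_scores_zero(weights, window):
    result = compute_patient_auc(make_record([]), weights, window)
    assert result.auc == 0.0
    assert result.level_at_last_day is SupportLevel.NONE


def test_same_level_overlap_merged_not_double_billed(weights, window):
    rec = make_record([(SupportLevel.PN, 0, 9), (SupportLevel.PN, 5, 14)])
    result = compute_patient_auc(rec, weights, window, "additive")
    assert result.days_by_level[SupportLevel.PN] == 15
    assert result.auc == 90.0


def test_cross_level_overlap_modes_differ(weights, window):
    rec = make_record([(SupportLevel.ENTERAL, 0, 9), (SupportLevel.PN, 0, 9)])
    additive = compute_patient_auc(rec, weights, window, "additive")
    maxmode = compute_patient_auc(rec, weights, window, "max_per_day")
    assert additive.auc == 100.0  # (4 + 6) * 10
    assert maxmode.auc == 60.0  # 6 * 10


def test_daily_profile_max_of_overlap():
    rec = make_record([(SupportLevel.ENTERAL, 0, 1), (SupportLevel.PN, 1, 2)])
    profile = daily_level_profile(rec, ScoreWindow(0, 3))
    assert profile == [
        SupportLevel.ENTERAL,
        SupportLevel.PN,
        SupportLevel.PN,
        SupportLevel.NONE,
    ]


def test_oracle_equivalence_on_random_records(rng, weights, window):
    """Interval-based scoring equals the day-by-day oracle, both modes."""
    for i in range(300):
        rec = random_record(rng)
        for mode in ("additive", "max_per_day"):
            got = compute_patient_auc(rec, weights, window, mode).auc
            assert got == brute_force_auc(rec, weights, window, mode)


def test_profile_rescoring_equals_max_per_day(rng, weights, window):
    for _ in range(50):
        rec = random_record(rng)
        profile = daily_level_profile(rec, window)
        rescored = sum(weights[lvl] for lvl in profile)
        assert rescored == compute_patient_auc(rec, weights, window, "max_per_day").auc


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    start=st.integers(0, 90),
    length=st.integers(2, 30),
    split=st.data(),
    level=st.sampled_from([l for l in SupportLevel if l is not SupportLevel.NONE]),
)
def test_splitting_episode_preserves_score(start, length, split, level):
    """A contiguous episode split in two scores identically (additivity)."""
    end = start + length - 1
    cut = split.draw(st.integers(start, end - 1))
    whole = make_record([(level, start, end)], followup=end + 1)
    parts = make_record(
        [(level, start, cut), (level, cut + 1, end)], followup=end + 1
    )
    for mode in ("additive", "max_per_day"):
        assert (
            compute_patient_auc(whole, overlap_mode=mode).auc
            == compute_patient_auc(parts, overlap_mode=mode).auc
        )


def test_score_bounds_and_mode_ordering(rng, weights, window):
    for _ in range(100):
        rec = random_record(rng)
        add = compute_patient_auc(rec, weights, window, "additive").auc
        mx = compute_patient_auc(rec, weights, window, "max_per_day").auc
        assert 0.0 <= mx <= 7.0 * window.length
        assert add >= mx


def test_raising_a_days_level_never_decreases_score(rng, weights, window):
    for _ in range(50):
        rec = random_record(rng)
        base = compute_patient_auc(rec, weights, window, "max_per_day").auc
        day = int(rng.integers(0, 100))
        boosted = PatientRecord(
            patient_id=rec.patient_id,
            episodes=rec.episodes
            + [
                InterventionEpisode(
                    rec.patient_id, SupportLevel.BESPOKE_PN, day, day
                )
            ],
            followup_days=rec.followup_days,
        )
        assert (
            compute_patient_auc(boosted, weights, window, "max_per_day").auc >= base
        )


def test_episodes_entirely_after_window_contribute_zero(weights):
    rec = make_record([(SupportLevel.BESPOKE_PN, 100, 180)], followup=200)
    assert compute_patient_auc(rec, weights, ScoreWindow(0, 99)).auc == 0.0


class TestPnOutcome:
    def test_bespoke_on_last_day_true(self):
        rec = make_record([(SupportLevel.BESPOKE_PN, 90, 99)])
        assert pn_outcome_at(rec) is True

    def test_enteral_on_last_day_false(self):
        rec = make_record([(SupportLevel.ENTERAL, 90, 99)])
        assert pn_outcome_at(rec) is False

    def test_uncovered_day_false(self):
        rec = make_record([(SupportLevel.PN, 0, 50)])
        assert pn_outcome_at(rec) is False

    def test_day_beyond_followup_raises(self):
        rec = make_record([(SupportLevel.PN, 0, 40)], followup=50)
        with pytest.raises(ValidationError, match="censored"):
            pn_outcome_at(rec, day=99)

    def test_override_wins(self):
        rec = make_record([(SupportLevel.BESPOKE_PN, 0, 99)])
        rec.pn_day100_override = False
        assert pn_outcome_at(rec) is False


class TestValidation:
    def test_reversed_days_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="end_day"):
            InterventionEpisode("p1", SupportLevel.PN, 10, 5)

    def test_mixed_patient_id_flagged(self):
        rec = make_record([(SupportLevel.PN, 0, 5)])
        rec.episodes.append(InterventionEpisode("other", SupportLevel.PN, 6, 9))
        assert any("patient_id" in v for v in validate_record(rec))

    def test_well_formed_record_clean(self):
        rec = make_record([(SupportLevel.ORAL, 0, 10), (SupportLevel.PN, 11, 30)])
        assert validate_record(rec) == []

    def test_level_none_unstorable(self):
        with pytest.raises(ValidationError):
            InterventionEpisode("p1", SupportLevel.NONE, 0, 5)

    @pytest.mark.parametrize(
        "pts",
        [
            {SupportLevel.NONE: 1.0},  # NONE must be 0
            {SupportLevel.ROUTINE: 5.0},  # breaks monotonicity vs ORAL=2
        ],
    )
    def test_bad_weight_schemes_rejected(self, pts):
        bad = {
            SupportLevel.NONE: 0.0,
            SupportLevel.ROUTINE: 1.0,
            SupportLevel.ORAL: 2.0,
            SupportLevel.ENTERAL: 4.0,
            SupportLevel.PN: 6.0,
            SupportLevel.BESPOKE_PN: 7.0,
            **pts,
        }
        with pytest.raises(ValidationError):
            WeightScheme(bad)


def test_censoring_filter_excludes_short_followup(window):
    complete = make_record([(SupportLevel.PN, 0, 99)], patient_id="a")
    short = make_record([(SupportLevel.PN, 0, 40)], patient_id="b", followup=50)
    kept, excluded = filter_complete_followup([complete, short], window)
    assert [r.patient_id for r in kept] == ["a"]
    assert [r.patient_id for r in excluded] == ["b"]
    with pytest.warns(UserWarning, match="truncated"):
        kept2, excluded2 = filter_complete_followup(
            [complete, short], window, allow_truncated=True
        )
    assert len(kept2) == 2 and not excluded2
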