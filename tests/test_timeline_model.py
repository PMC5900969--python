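"""Interval algebra and record validation."""

import pytest
from hypothesis import given, settings, strategies as st

from ssc_audit.timeline_model import (
    OPEN,
    Actor,
    CareEvent,
    ContactEpisode,
    DyadRecord,
    EventKind,
    EventReason,
    LabourOnset,
    ObstetricProfile,
    Plurality,
    Presentation,
    StageAnnotation,
    canonicalized,
    contact_gap_before,
    first_ssc_onset,
    validate_record,
)

PROFILE = ObstetricProfile(0, False, Plurality.SINGLETON, Presentation.CEPHALIC,
                           39, LabourOnset.SPONTANEOUS)


def make_record(episodes=(), events=(), stages=(), obs=3600, did="D1"):
    return DyadRecord(did, PROFILE, obs, tuple(episodes), tuple(events),
                      tuple(stages))


class TestFirstOnset:
    @pytest.mark.parametrize(
        "episodes, expected",
        [
            ([(194, OPEN)], 194),       # 3:14-min repositioning delay
            ([], None),                 # never reached skin-to-skin
            ([(0, OPEN)], 0),           # placed at the moment of birth
            ([(60, 300), (400, OPEN)], 60),
        ],
    )
    def test_earliest_episode_start(self, episodes, expected):
        rec = make_record([ContactEpisode(s, e) for s, e in episodes])
        assert first_ssc_onset(rec) == expected

    def test_overlapping_episodes_raise_with_dyad_name(self):
        rec = make_record([ContactEpisode(0, 1000), ContactEpisode(500, 2000)])
        with pytest.raises(ValueError, match="D1"):
            first_ssc_onset(rec)


def brute_force_gaps(episodes, horizon, obs_end):
    """Second-by-second coverage scan; the independent oracle."""
    starts = [e.start_s for e in episodes]
    if not starts or min(starts) >= horizon:
        return []
    onset = min(starts)
    covered = [False] * horizon
    for e in episodes:
        end = horizon if e.is_open else min(e.end_s, horizon)
        for t in range(max(0, e.start_s), end):
            covered[t] = True
    gaps, start = [], None
    for t in range(onset, horizon):
        if not covered[t] and start is None:
            start = t
        elif covered[t] and start is not None:
            gaps.append((start, t))
            start = None
    if start is not None:
        gaps.append((start, horizon))
    return gaps


class TestContactGaps:
    @pytest.mark.parametrize(
        "episodes, horizon, expected",
        [
            ([(0, 3000)], 3600, [(3000, 3600)]),
            ([(0, 1200), (1500, 3600)], 3600, [(1200, 1500)]),
            ([(0, OPEN)], 3600, []),
            ([], 3600, []),
            ([(100, 200), (400, 500)], 3600, [(200, 400), (500, 3600)]),
        ],
    )
    def test_interval_complement(self, episodes, horizon, expected):
        rec = make_record([ContactEpisode(s, e) for s, e in episodes], obs=7200)
        assert contact_gap_before(rec, horizon) == expected

    @given(
        boundaries=st.lists(st.integers(0, 7200), min_size=0, max_size=20),
        open_last=st.booleans(),
        horizon=st.integers(1, 7200),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_brute_force_scan(self, boundaries, open_last, horizon):
        pts = sorted(set(boundaries))
        episodes = [ContactEpisode(pts[i], pts[i + 1])
                    for i in range(0, len(pts) - 1, 2)]
        if episodes and open_last:
            episodes[-1] = ContactEpisode(episodes[-1].start_s, OPEN)
        rec = make_record(episodes, obs=7200)
        assert contact_gap_before(rec, horizon) == \
            brute_force_gaps(episodes, horizon, 7200)


class TestValidateRecord:
    def test_well_formed_fixture_dyads_are_clean(self, japan_records):
        assert all(validate_record(r) == [] for r in japan_records)

    def test_end_before_start(self):
        rec = make_record([ContactEpisode(100, 50)])
        codes = [v.code for v in validate_record(rec)]
        assert "episode_end_before_start" in codes

    def test_unmatched_removal(self):
        rec = make_record(
            [ContactEpisode(0, OPEN)],
            [CareEvent(3000, EventKind.REMOVAL, Actor.STAFF, EventReason.ROUTINE)],
        )
        codes = [v.code for v in validate_record(rec)]
        assert codes == ["unmatched_removal"]

    def test_removal_matches_episode_end_within_tolerance(self):
        rec = make_record(
            [ContactEpisode(0, 3000)],
            [CareEvent(3003, EventKind.REMOVAL, Actor.STAFF, EventReason.ROUTINE)],
        )
        assert validate_record(rec) == []

    def test_policy_hold_after_contact_flagged(self):
        rec = make_record(
            [ContactEpisode(10, OPEN)],
            [CareEvent(500, EventKind.POLICY_HOLD)],
        )
        assert [v.code for v in validate_record(rec)] == ["policy_hold_after_contact"]

    def test_times_beyond_window_and_stage_range(self):
        rec = make_record(
            [ContactEpisode(0, 4000)],
            stages=[StageAnnotation(11, 100)],
        )
        codes = {v.code for v in validate_record(rec)}
        assert codes == {"episode_beyond_window", "stage_out_of_range"}

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_idempotent_and_order_insensitive(self, seed):
        import random

        rng = random.Random(seed)
        events = [
            CareEvent(rng.randrange(0, 3600), kind, actor, reason)
            for kind, actor, reason in [
                (EventKind.IN_PLACE_INTERFERENCE, Actor.STAFF, EventReason.ROUTINE),
                (EventKind.IN_PLACE_INTERFERENCE, Actor.FAMILY, EventReason.UNKNOWN),
                (EventKind.POLICY_HOLD, Actor.STAFF, EventReason.HOSPITAL_POLICY),
            ]
        ]
        rec = make_record([ContactEpisode(500, OPEN)], events)
        baseline = validate_record(rec)
        assert validate_record(rec) == baseline  # idempotent
        shuffled = list(events)
        rng.shuffle(shuffled)
        rec2 = make_record([ContactEpisode(500, OPEN)], shuffled)
        assert validate_record(rec2) == baseline  # order-insensitive


def test_canonicalized_sorts_every_list():
    rec = make_record(
        [ContactEpisode(1000, 2000), ContactEpisode(0, 500)],
        [CareEvent(900, EventKind.POLICY_HOLD), CareEvent(100, EventKind.POLICY_HOLD)],
        [StageAnnotation(2, 300), StageAnnotation(1, 100)],
    )
    canon = canonicalized(rec)
    assert [e.start_s for e in canon.episodes] == [0, 1000]
    assert [e.time_s for e in canon.events] == [100, 900]
    assert [s.stage for s in canon.stages] == [1, 2]


def test_profile_invariants_enforced():
    with pytest.raises(ValueError):
        ObstetricProfile(0, True, Plurality.SINGLETON, Presentation.CEPHALIC,
                         39, LabourOnset.SPONTANEOUS)
    with pytest.raises(ValueError):
        ObstetricProfile(1, False, Plurality.SINGLETON, Presentation.CEPHALIC,
                         50, LabourOnset.SPONTANEOUS)
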