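"""Pathway engine: step classification, composition, funnel invariants."""

import pytest

from ssc_audit.cohorts import CohortSimConfig, simulate_cohort
from ssc_audit.pathway import (
    Colour,
    ContinuousStatus,
    ExitStep,
    ImmediateStatus,
    ON_PATH_IMMEDIATE,
    PathwayConfig,
    PathwayError,
    UninterruptedStatus,
    classify_continuous,
    classify_immediate,
    classify_uninterrupted,
    run_pathway,
)
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
)

PROFILE = ObstetricProfile(0, False, Plurality.SINGLETON, Presentation.CEPHALIC,
                           39, LabourOnset.SPONTANEOUS)


def record(episodes=(), events=(), stages=(), obs=3600, did="D1"):
    return DyadRecord(did, PROFILE, obs, tuple(episodes), tuple(events),
                      tuple(stages))


class TestImmediate:
    def test_birth_moment_placement(self, config):
        rec = record([ContactEpisode(0, OPEN)])
        assert classify_immediate(rec, config) is ImmediateStatus.IMMEDIATE

    def test_under_threshold_after_delay_event_is_caution(self, config):
        rec = record([ContactEpisode(194, OPEN)],
                     [CareEvent(10, EventKind.POLICY_HOLD)])
        assert classify_immediate(rec, config) is \
            ImmediateStatus.DELAYED_UNDER_THRESHOLD_CAUTION

    def test_under_threshold_with_no_event_is_immediate(self, config):
        rec = record([ContactEpisode(194, OPEN)])
        assert classify_immediate(rec, config) is ImmediateStatus.IMMEDIATE

    def test_caution_disabled_reverts_to_immediate(self):
        cfg = PathwayConfig(delay_caution_enabled=False)
        rec = record([ContactEpisode(194, OPEN)],
                     [CareEvent(10, EventKind.POLICY_HOLD)])
        assert classify_immediate(rec, cfg) is ImmediateStatus.IMMEDIATE

    def test_no_ssc_with_policy_hold(self, config):
        rec = record([], [CareEvent(0, EventKind.POLICY_HOLD)], obs=7200)
        assert classify_immediate(rec, config) is \
            ImmediateStatus.NOT_IMMEDIATE_POLICY

    def test_late_onset_emergent_attribution(self, config):
        rec = record([ContactEpisode(900, OPEN)],
                     [CareEvent(0, EventKind.IN_PLACE_INTERFERENCE, Actor.STAFF,
                                EventReason.EMERGENT)])
        assert classify_immediate(rec, config) is \
            ImmediateStatus.NOT_IMMEDIATE_EMERGENT

    def test_uncaused_late_onset_defaults_to_policy(self, config):
        rec = record([ContactEpisode(900, OPEN)])
        assert classify_immediate(rec, config) is \
            ImmediateStatus.NOT_IMMEDIATE_POLICY

    def test_uncaused_late_onset_errors_under_strict_attribution(self):
        cfg = PathwayConfig(strict_attribution=True)
        rec = record([ContactEpisode(900, OPEN)])
        with pytest.raises(PathwayError, match="D1"):
            classify_immediate(rec, cfg)


class TestContinuous:
    def test_routine_removal_at_50_min(self, config):
        rec = record(
            [ContactEpisode(0, 3000)],
            [CareEvent(3000, EventKind.REMOVAL, Actor.STAFF, EventReason.ROUTINE)],
        )
        assert classify_continuous(rec, config) is ContinuousStatus.REMOVED_ROUTINE

    def test_unbroken_open_episode(self, config):
        rec = record([ContactEpisode(0, OPEN)])
        assert classify_continuous(rec, config) is ContinuousStatus.CONTINUOUS

    def test_maternal_request_defers_to_uninterrupted(self, config):
        rec = record(
            [ContactEpisode(0, 2400)],
            [CareEvent(2400, EventKind.REMOVAL, Actor.MOTHER,
                       EventReason.MATERNAL_REQUEST)],
        )
        assert classify_continuous(rec, config) is ContinuousStatus.CONTINUOUS
        assert classify_uninterrupted(rec, config) is \
            UninterruptedStatus.FAMILY_INTERFERED

    def test_emergent_removal(self, config):
        rec = record(
            [ContactEpisode(0, 1200)],
            [CareEvent(1200, EventKind.REMOVAL, Actor.STAFF, EventReason.EMERGENT)],
        )
        assert classify_continuous(rec, config) is ContinuousStatus.REMOVED_EMERGENT

    def test_bare_gap_breaks_continuity(self, config):
        rec = record([ContactEpisode(0, 1200), ContactEpisode(1500, OPEN)])
        assert classify_continuous(rec, config) is ContinuousStatus.REMOVED_ROUTINE

    def test_removal_at_horizon_does_not_break(self, config):
        rec = record(
            [ContactEpisode(0, 3600)],
            [CareEvent(3600, EventKind.REMOVAL, Actor.STAFF, EventReason.ROUTINE)],
        )
        assert classify_continuous(rec, config) is ContinuousStatus.CONTINUOUS

    def test_gap_within_tolerance_forgiven(self):
        cfg = PathwayConfig(gap_tolerance_s=120)
        rec = record([ContactEpisode(0, 1200), ContactEpisode(1290, OPEN)])
        assert classify_continuous(rec, cfg) is ContinuousStatus.CONTINUOUS


class TestUninterrupted:
    def test_staff_latching_is_interference(self, config):
        rec = record([ContactEpisode(0, OPEN)],
                     [CareEvent(1500, EventKind.IN_PLACE_INTERFERENCE,
                                Actor.STAFF, EventReason.ROUTINE)])
        assert classify_uninterrupted(rec, config) is \
            UninterruptedStatus.STAFF_INTERFERED

    def test_no_events_is_uninterrupted(self, config):
        rec = record([ContactEpisode(0, OPEN)])
        assert classify_uninterrupted(rec, config) is \
            UninterruptedStatus.UNINTERRUPTED

    def test_earliest_event_wins(self, config):
        rec = record(
            [ContactEpisode(0, 2400)],
            [CareEvent(1800, EventKind.IN_PLACE_INTERFERENCE, Actor.STAFF,
                       EventReason.ROUTINE),
             CareEvent(2400, EventKind.REMOVAL, Actor.MOTHER,
                       EventReason.MATERNAL_REQUEST)],
        )
        assert classify_uninterrupted(rec, config) is \
            UninterruptedStatus.STAFF_INTERFERED
        # and the reverse ordering attributes to the family
        rec2 = record(
            [ContactEpisode(0, 1200)],
            [CareEvent(1200, EventKind.REMOVAL, Actor.MOTHER,
                       EventReason.MATERNAL_REQUEST),
             CareEvent(1800, EventKind.IN_PLACE_INTERFERENCE, Actor.STAFF,
                       EventReason.ROUTINE)],
        )
        assert classify_uninterrupted(rec2, config) is \
            UninterruptedStatus.FAMILY_INTERFERED

    def test_equal_timestamp_tie_breaks(self, config):
        # removal outranks in-place interference; staff outranks family
        rec = record(
            [ContactEpisode(0, 1800)],
            [CareEvent(1800, EventKind.IN_PLACE_INTERFERENCE, Actor.STAFF,
                       EventReason.ROUTINE),
             CareEvent(1800, EventKind.REMOVAL, Actor.MOTHER,
                       EventReason.MATERNAL_REQUEST)],
        )
        assert classify_uninterrupted(rec, config) is \
            UninterruptedStatus.FAMILY_INTERFERED  # the removal, by mother

    def test_unknown_actor_is_an_error(self, config):
        rec = record([ContactEpisode(0, OPEN)],
                     [CareEvent(1500, EventKind.IN_PLACE_INTERFERENCE,
                                Actor.UNKNOWN, EventReason.ROUTINE)])
        with pytest.raises(PathwayError, match="D1"):
            classify_uninterrupted(rec, config)


class TestRunPathway:
    def test_green_full_standard(self):
        rec = record(
            [ContactEpisode(0, OPEN)],
            stages=[StageAnnotation(s, 100 + 300 * s) for s in range(1, 9)],
        )
        res = run_pathway(rec)
        assert res.met_standard
        assert res.colour is Colour.GREEN
        assert res.exit_step is ExitStep.NONE

    def test_red_stalled_at_stage_four(self):
        rec = record(
            [ContactEpisode(0, OPEN)],
            stages=[StageAnnotation(s, 100 + 300 * s) for s in range(1, 5)],
        )
        res = run_pathway(rec)
        assert not res.met_standard
        assert res.exit_step is ExitStep.NINE_STAGES
        assert res.colour is Colour.RED
        assert res.stage_outcome.highest_stage == 4

    def test_policy_exit_marks_downstream_not_reached(self):
        rec = record([ContactEpisode(4000, OPEN)],
                     [CareEvent(0, EventKind.POLICY_HOLD)], obs=7200)
        res = run_pathway(rec)
        assert res.immediate_status is ImmediateStatus.NOT_IMMEDIATE_POLICY
        assert res.continuous_status is ContinuousStatus.NOT_REACHED
        assert res.uninterrupted_status is UninterruptedStatus.NOT_REACHED
        assert res.stage_outcome is None
        assert res.exit_step is ExitStep.IMMEDIATE

    def test_yellow_delayed_dyad_meeting_standard(self):
        rec = record(
            [ContactEpisode(200, OPEN)],
            [CareEvent(10, EventKind.POLICY_HOLD)],
            stages=[StageAnnotation(s, 300 + 300 * s) for s in range(1, 9)],
        )
        res = run_pathway(rec)
        assert res.met_standard
        assert res.colour is Colour.YELLOW

    def test_invalid_record_raises_with_dyad_id(self):
        rec = record([ContactEpisode(100, 50)], did="BAD1")
        with pytest.raises(PathwayError, match="BAD1"):
            run_pathway(rec)

    def test_deterministic(self, japan_records):
        first = [run_pathway(r) for r in japan_records]
        second = [run_pathway(r) for r in reversed(japan_records)]
        assert sorted(first, key=lambda r: r.dyad_id) == \
            sorted(second, key=lambda r: r.dyad_id)


def funnel_counts(results):
    on_imm = sum(1 for r in results if r.immediate_status in ON_PATH_IMMEDIATE)
    on_cont = sum(1 for r in results
                  if r.continuous_status is ContinuousStatus.CONTINUOUS)
    on_unin = sum(1 for r in results
                  if r.uninterrupted_status is UninterruptedStatus.UNINTERRUPTED)
    met = sum(1 for r in results if r.met_standard)
    return on_imm, on_cont, on_unin, met


@pytest.mark.parametrize("seed", [1, 7, 42])
def test_funnel_monotone_and_conserved_on_simulated_cohorts(seed):
    records = simulate_cohort(CohortSimConfig(n_dyads=300, seed=seed))
    results = [run_pathway(r) for r in records]
    on_imm, on_cont, on_unin, met = funnel_counts(results)
    assert len(results) >= on_imm >= on_cont >= on_unin >= met
    exits = [r for r in results if r.exit_step is not ExitStep.NONE]
    assert len(exits) + met == len(results)  # conservation
    for r in results:
        assert r.met_standard == (r.exit_step is ExitStep.NONE)
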