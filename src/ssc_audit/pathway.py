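"""Skin-to-skin implementation pathway engine.

Routes each mother–baby dyad through the four-step best-practice funnel —
*immediate* (contact within 5 minutes of birth), *continuous* (no removal or
contact gap through the first hour), *uninterrupted* (no staff or family
interference with the newborn's instinctive behaviour) and *nine stages*
(progression to self-attached suckling) — recording where the dyad leaves the
path, the colour code of its trajectory, and whether the full standard was
met.

Colour semantics: blue is the best-practice trail itself; a dyad that stays
on it to suckling is green (or yellow when it carried a sub-5-minute delay
caution), and a dyad that leaves it is red, labelled with the step and cause
of exit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .robson import RobsonGroup, RobsonMode, classify_robson
from .timeline_model import (
    Actor,
    CareEvent,
    DyadRecord,
    EventKind,
    EventReason,
    REMOVAL_MATCH_TOLERANCE_S,
    contact_gap_before,
    first_ssc_onset,
    validate_record,
)
from .widstrom import StageOutcome, assess_stages

__all__ = [
    "PathwayError",
    "PathwayConfig",
    "ImmediateStatus",
    "ContinuousStatus",
    "UninterruptedStatus",
    "ExitStep",
    "Colour",
    "PathwayResult",
    "classify_immediate",
    "classify_continuous",
    "classify_uninterrupted",
    "run_pathway",
]


class PathwayError(ValueError):
    """Raised when a record cannot be classified; carries the dyad id."""


@dataclass(frozen=True)
class PathwayConfig:
    """Tunable audit thresholds.

    ``immediate_threshold_s``: latest skin-to-skin onset still counted as
    immediate (default 300 s = the 5-minute standard).
    ``continuity_horizon_s``: end of the continuity window, measured from
    birth (default 3600 s = "the first hour or so"; the standard names 60
    minutes and the knob exists because practice varies).
    ``delay_caution_enabled``: whether a sub-threshold onset preceded by a
    separation/delay event is flagged yellow rather than plain immediate.
    ``strict_attribution``: when true, a late or absent onset with no
    recorded cause event is an error instead of defaulting to hospital
    policy.
    ``gap_tolerance_s``: contact gaps no longer than this do not break
    continuity (default 0: any separation restarts the stage progression).
    """

    immediate_threshold_s: int = 300
    continuity_horizon_s: int = 3600
    delay_caution_enabled: bool = True
    strict_attribution: bool = False
    gap_tolerance_s: int = 0

    def __post_init__(self) -> None:
        if self.immediate_threshold_s >= self.continuity_horizon_s:
            raise ValueError("immediate threshold must precede continuity horizon")
        if self.immediate_threshold_s <= 0 or self.gap_tolerance_s < 0:
            raise ValueError("invalid threshold/tolerance")


class ImmediateStatus(str, enum.Enum):
    IMMEDIATE = "immediate"
    DELAYED_UNDER_THRESHOLD_CAUTION = "delayed_under_threshold_caution"
    NOT_IMMEDIATE_POLICY = "not_immediate_policy"
    NOT_IMMEDIATE_EMERGENT = "not_immediate_emergent"


ON_PATH_IMMEDIATE = frozenset(
    {ImmediateStatus.IMMEDIATE, ImmediateStatus.DELAYED_UNDER_THRESHOLD_CAUTION}
)


class ContinuousStatus(str, enum.Enum):
    CONTINUOUS = "continuous"
    REMOVED_ROUTINE = "removed_routine"
    REMOVED_EMERGENT = "removed_emergent"
    NOT_REACHED = "not_reached"


class UninterruptedStatus(str, enum.Enum):
    UNINTERRUPTED = "uninterrupted"
    STAFF_INTERFERED = "staff_interfered"
    FAMILY_INTERFERED = "family_interfered"
    NOT_REACHED = "not_reached"


class ExitStep(str, enum.Enum):
    IMMEDIATE = "immediate"
    CONTINUOUS = "continuous"
    UNINTERRUPTED = "uninterrupted"
    NINE_STAGES = "nine_stages"
    NONE = "none"


class Colour(str, enum.Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"


@dataclass(frozen=True)
class PathwayResult:
    """Per-dyad audit outcome: status at each step, exit point, colour."""

    dyad_id: str
    robson: RobsonGroup
    immediate_status: ImmediateStatus
    continuous_status: ContinuousStatus
    uninterrupted_status: UninterruptedStatus
    stage_outcome: StageOutcome | None
    met_standard: bool
    exit_step: ExitStep
    colour: Colour


def classify_immediate(record: DyadRecord, config: PathwayConfig) -> ImmediateStatus:
    """Was the newborn placed on the mother's chest within the threshold?

    A sub-threshold onset with no preceding care event is immediate; with a
    preceding separation/delay event it is a yellow caution that stays on
    the path.  A late or absent onset exits as hospital-policy or emergent,
    attributed from the recorded cause events.
    """
    onset = first_ssc_onset(record)
    if onset is not None and onset <= config.immediate_threshold_s:
        preceded = any(
            ev.time_s <= onset and ev.kind is not EventKind.REMOVAL
            for ev in record.events
        )
        if preceded and config.delay_caution_enabled:
            return ImmediateStatus.DELAYED_UNDER_THRESHOLD_CAUTION
        return ImmediateStatus.IMMEDIATE

    # late or absent onset: attribute the cause
    scope = [
        ev for ev in record.events
        if ev.kind is not EventKind.REMOVAL and (onset is None or ev.time_s <= onset)
    ]
    if any(ev.reason is EventReason.EMERGENT for ev in scope):
        return ImmediateStatus.NOT_IMMEDIATE_EMERGENT
    if any(
        ev.kind is EventKind.POLICY_HOLD
        or ev.reason in (EventReason.HOSPITAL_POLICY, EventReason.ROUTINE)
        for ev in scope
    ):
        return ImmediateStatus.NOT_IMMEDIATE_POLICY
    if config.strict_attribution:
        raise PathwayError(
            f"dyad {record.dyad_id}: skin-to-skin onset beyond "
            f"{config.immediate_threshold_s}s with no recorded cause event"
        )
    # institutional delay is the default reading of uncaused late starts
    return ImmediateStatus.NOT_IMMEDIATE_POLICY


def _removal_events(record: DyadRecord) -> list[CareEvent]:
    return [ev for ev in record.events if ev.kind is EventKind.REMOVAL]


def classify_continuous(record: DyadRecord, config: PathwayConfig) -> ContinuousStatus:
    """Did contact persist unbroken from onset through the continuity horizon?

    The first removal event or unexplained contact gap before the horizon
    breaks continuity, attributed emergent or routine by the removal reason.
    A maternal-request removal does not exit here — it is bookkept as an
    interruption and defers to the uninterrupted step.
    """
    horizon = config.continuity_horizon_s
    onset = first_ssc_onset(record)
    if onset is None:
        raise PathwayError(f"dyad {record.dyad_id}: continuity assessed with no contact")

    removals = _removal_events(record)
    breaks: list[tuple[int, EventReason]] = [
        (ev.time_s, ev.reason)
        for ev in removals
        if onset <= ev.time_s < horizon and ev.reason is not EventReason.MATERNAL_REQUEST
    ]
    for gap_start, gap_end in contact_gap_before(record, horizon):
        if gap_end - gap_start <= config.gap_tolerance_s:
            continue
        matched = [
            ev for ev in removals
            if abs(ev.time_s - gap_start) <= REMOVAL_MATCH_TOLERANCE_S
        ]
        if any(ev.reason is EventReason.MATERNAL_REQUEST for ev in matched):
            continue  # deferred to the uninterrupted step
        if not matched:  # bare gap with no event: routine by convention
            breaks.append((gap_start, EventReason.ROUTINE))

    if not breaks:
        return ContinuousStatus.CONTINUOUS
    _, reason = min(breaks, key=lambda b: b[0])
    if reason is EventReason.EMERGENT:
        return ContinuousStatus.REMOVED_EMERGENT
    return ContinuousStatus.REMOVED_ROUTINE


def classify_uninterrupted(
    record: DyadRecord, config: PathwayConfig
) -> UninterruptedStatus:
    """Did anyone interfere with the newborn's instinctive behaviour?

    Qualifying events are in-place interferences (e.g. staff latching the
    baby, which forecloses self-attachment) and maternal-request removals.
    The earliest qualifying event attributes the exit; at equal timestamps a
    removal outranks an in-place interference, and staff outranks family.
    """
    horizon = config.continuity_horizon_s
    qualifying = [
        ev for ev in record.events
        if ev.time_s <= horizon
        and (
            ev.kind is EventKind.IN_PLACE_INTERFERENCE
            or (ev.kind is EventKind.REMOVAL
                and ev.reason is EventReason.MATERNAL_REQUEST)
        )
    ]
    if not qualifying:
        return UninterruptedStatus.UNINTERRUPTED

    def rank(ev: CareEvent) -> tuple[int, int, int]:
        kind_rank = 0 if ev.kind is EventKind.REMOVAL else 1
        actor_rank = 0 if ev.actor is Actor.STAFF else 1
        return (ev.time_s, kind_rank, actor_rank)

    first = min(qualifying, key=rank)
    if first.actor is Actor.STAFF:
        return UninterruptedStatus.STAFF_INTERFERED
    if first.actor in (Actor.MOTHER, Actor.FAMILY):
        return UninterruptedStatus.FAMILY_INTERFERED
    raise PathwayError(
        f"dyad {record.dyad_id}: interference at {first.time_s}s has unknown actor"
    )


def run_pathway(
    record: DyadRecord,
    config: PathwayConfig | None = None,
    robson_mode: RobsonMode | str = RobsonMode.STRICT,
) -> PathwayResult:
    """Route one dyad through the full funnel and summarise the outcome.

    Classification stops at the first off-path status; downstream statuses
    are reported as not-reached and the stage outcome is absent unless the
    dyad survives to the nine-stages step.  Deterministic: identical records
    and config yield identical results.
    """
    config = config or PathwayConfig()
    violations = validate_record(record)
    if violations:
        raise PathwayError(
            f"dyad {record.dyad_id}: invalid record: "
            + "; ".join(str(v) for v in violations)
        )

    robson = classify_robson(record.profile, robson_mode)
    immediate = classify_immediate(record, config)
    delayed = immediate is ImmediateStatus.DELAYED_UNDER_THRESHOLD_CAUTION

    if immediate not in ON_PATH_IMMEDIATE:
        return PathwayResult(
            record.dyad_id, robson, immediate,
            ContinuousStatus.NOT_REACHED, UninterruptedStatus.NOT_REACHED,
            None, False, ExitStep.IMMEDIATE, Colour.RED,
        )

    continuous = classify_continuous(record, config)
    if continuous is not ContinuousStatus.CONTINUOUS:
        return PathwayResult(
            record.dyad_id, robson, immediate, continuous,
            UninterruptedStatus.NOT_REACHED,
            None, False, ExitStep.CONTINUOUS, Colour.RED,
        )

    uninterrupted = classify_uninterrupted(record, config)
    if uninterrupted is not UninterruptedStatus.UNINTERRUPTED:
        return PathwayResult(
            record.dyad_id, robson, immediate, continuous, uninterrupted,
            None, False, ExitStep.UNINTERRUPTED, Colour.RED,
        )

    outcome = assess_stages(record.stages, config.continuity_horizon_s)
    if not outcome.achieved_suckling:
        return PathwayResult(
            record.dyad_id, robson, immediate, continuous, uninterrupted,
            outcome, False, ExitStep.NINE_STAGES, Colour.RED,
        )

    colour = Colour.YELLOW if delayed else Colour.GREEN
    return PathwayResult(
        record.dyad_id, robson, immediate, continuous, uninterrupted,
        outcome, True, ExitStep.NONE, colour,
    )
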