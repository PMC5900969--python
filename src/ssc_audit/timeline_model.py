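"""Domain types and interval algebra for first-hour mother–newborn event timelines.

All times are integer seconds since birth (birth = 0).  Skin-to-skin (SSC)
contact episodes, care events (removals, in-place interferences, policy
holds) and Widström-stage annotations hang off a :class:`DyadRecord`, the
audit unit shared by every other module.

An episode or stage that continues past the observation window carries the
:data:`OPEN` sentinel as its end, never a magic number.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "OPEN",
    "OpenEnd",
    "Plurality",
    "Presentation",
    "LabourOnset",
    "EventKind",
    "Actor",
    "EventReason",
    "ObstetricProfile",
    "ContactEpisode",
    "CareEvent",
    "StageAnnotation",
    "DyadRecord",
    "Violation",
    "REMOVAL_MATCH_TOLERANCE_S",
    "first_ssc_onset",
    "contact_gap_before",
    "validate_record",
    "canonicalized",
]

#: Matching slack, in seconds, between a removal event and the episode end it
#: closes.  Hand-coded video timestamps jitter; exact equality would reject
#: real data.
REMOVAL_MATCH_TOLERANCE_S = 5


class OpenEnd:
    """Sentinel for a censored (still-ongoing) episode or stage end."""

    _instance = None

    def __new__(cls) -> "OpenEnd":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "OPEN"


OPEN = OpenEnd()


class Plurality(str, enum.Enum):
    SINGLETON = "singleton"
    MULTIPLE = "multiple"


class Presentation(str, enum.Enum):
    CEPHALIC = "cephalic"
    BREECH = "breech"
    TRANSVERSE_OBLIQUE = "transverse_oblique"


class LabourOnset(str, enum.Enum):
    SPONTANEOUS = "spontaneous"
    INDUCED = "induced"
    CAESAREAN_BEFORE_LABOUR = "caesarean_before_labour"


class EventKind(str, enum.Enum):
    REMOVAL = "removal"
    IN_PLACE_INTERFERENCE = "in_place_interference"
    POLICY_HOLD = "policy_hold"


class Actor(str, enum.Enum):
    STAFF = "staff"
    MOTHER = "mother"
    FAMILY = "family"
    UNKNOWN = "unknown"


class EventReason(str, enum.Enum):
    ROUTINE = "routine"
    EMERGENT = "emergent"
    MATERNAL_REQUEST = "maternal_request"
    HOSPITAL_POLICY = "hospital_policy"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class ObstetricProfile:
    """Prebirth obstetric parameters driving the Robson classification.

    ``parity_prior_births`` counts previous births: 0 = nullipara,
    >= 1 = multipara.  ``gestation_weeks`` is completed weeks.
    """

    parity_prior_births: int
    previous_caesarean: bool
    plurality: Plurality
    presentation: Presentation
    gestation_weeks: int
    labour_onset: LabourOnset

    def __post_init__(self) -> None:
        if self.parity_prior_births < 0:
            raise ValueError("parity_prior_births must be non-negative")
        if self.previous_caesarean and self.parity_prior_births < 1:
            raise ValueError("previous caesarean implies at least one prior birth")
        if not 20 <= self.gestation_weeks <= 45:
            raise ValueError(
                f"gestation_weeks {self.gestation_weeks} outside sanity bound [20, 45]"
            )


@dataclass(frozen=True)
class ContactEpisode:
    """One uninterrupted stretch of skin-to-skin contact.

    ``end_s`` is :data:`OPEN` when contact continues past the observation
    window (right-censored).  Shape constraints (start >= 0, end > start) are
    reported by :func:`validate_record` rather than enforced on construction,
    so malformed input can be loaded and diagnosed.
    """

    start_s: int
    end_s: int | OpenEnd

    @property
    def is_open(self) -> bool:
        return isinstance(self.end_s, OpenEnd)

    def end_or(self, default: int) -> int:
        return default if self.is_open else int(self.end_s)  # type: ignore[arg-type]


@dataclass(frozen=True)
class CareEvent:
    """A timed care action that can divert a dyad off the best-practice path."""

    time_s: int
    kind: EventKind
    actor: Actor = Actor.UNKNOWN
    reason: EventReason = EventReason.UNKNOWN


@dataclass(frozen=True)
class StageAnnotation:
    """A coded Widström-stage interval (stage 1–9)."""

    stage: int
    onset_s: int
    offset_s: int | OpenEnd = OPEN


@dataclass(frozen=True)
class DyadRecord:
    """One mother–baby pair: profile, observation window and coded timeline."""

    dyad_id: str
    profile: ObstetricProfile
    observation_end_s: int
    episodes: tuple[ContactEpisode, ...] = ()
    events: tuple[CareEvent, ...] = ()
    stages: tuple[StageAnnotation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "episodes", tuple(self.episodes))
        object.__setattr__(self, "events", tuple(self.events))
        object.__setattr__(self, "stages", tuple(self.stages))
        if self.observation_end_s <= 0:
            raise ValueError("observation window must be positive")


@dataclass(frozen=True)
class Violation:
    """One invariant violation found in a record; data, not an exception."""

    dyad_id: str
    code: str
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.dyad_id}] {self.code}: {self.detail}"


def canonicalized(record: DyadRecord) -> DyadRecord:
    """Return the record with episodes, events and stages in canonical time order."""
    return replace(
        record,
        episodes=tuple(sorted(record.episodes, key=lambda e: e.start_s)),
        events=tuple(
            sorted(record.events, key=lambda e: (e.time_s, e.kind.value, e.actor.value))
        ),
        stages=tuple(sorted(record.stages, key=lambda s: (s.onset_s, s.stage))),
    )


def first_ssc_onset(record: DyadRecord) -> int | None:
    """Start time of the earliest contact episode, or ``None`` when the dyad
    never reaches skin-to-skin within the observation window."""
    violations = _episode_order_violations(record)
    if violations:
        raise ValueError(
            f"dyad {record.dyad_id}: episodes unsorted or overlapping: "
            + "; ".join(v.detail for v in violations)
        )
    if not record.episodes:
        return None
    return min(e.start_s for e in record.episodes)


def contact_gap_before(
    record: DyadRecord, horizon_s: int
) -> list[tuple[int, int]]:
    """Maximal uncovered intervals in [first SSC onset, ``horizon_s``].

    Returns the complement of episode coverage between the first onset and the
    horizon; an empty list means coverage is unbroken (or the dyad has no
    episode at all, in which case continuity is moot).
    """
    if horizon_s <= 0:
        raise ValueError("horizon_s must be positive")
    onset = first_ssc_onset(record)
    if onset is None or onset >= horizon_s:
        return []
    gaps: list[tuple[int, int]] = []
    cursor = onset
    for ep in sorted(record.episodes, key=lambda e: e.start_s):
        start = ep.start_s
        end = ep.end_or(horizon_s)
        if start >= horizon_s:
            break
        if start > cursor:
            gaps.append((cursor, min(start, horizon_s)))
        cursor = max(cursor, min(end, horizon_s))
        if cursor >= horizon_s:
            break
    if cursor < horizon_s:
        gaps.append((cursor, horizon_s))
    return gaps


def _episode_order_violations(record: DyadRecord) -> list[Violation]:
    out: list[Violation] = []
    eps = record.episodes
    for i in range(1, len(eps)):
        prev, cur = eps[i - 1], eps[i]
        if cur.start_s < prev.start_s:
            out.append(
                Violation(record.dyad_id, "episodes_unsorted",
                          f"episode at {cur.start_s}s listed after {prev.start_s}s")
            )
        prev_end = prev.end_or(record.observation_end_s)
        if prev.is_open or cur.start_s < prev_end:
            out.append(
                Violation(record.dyad_id, "episodes_overlap",
                          f"episode at {cur.start_s}s overlaps previous ending at "
                          f"{'OPEN' if prev.is_open else prev_end}s")
            )
    return out


def validate_record(record: DyadRecord) -> list[Violation]:
    """Collect every structural invariant violation in a record.

    Violations are returned as data so a cohort loader can report them all at
    once; an empty list means the record is well-formed.  The check is
    idempotent and insensitive to input ordering (lists are canonically
    sorted first).
    """
    rec = canonicalized(record)
    out: list[Violation] = []
    vid = rec.dyad_id

    out.extend(_episode_order_violations(rec))

    for ep in rec.episodes:
        if ep.start_s < 0:
            out.append(Violation(vid, "episode_before_birth",
                                 f"episode starts at {ep.start_s}s"))
        if not ep.is_open and ep.end_s <= ep.start_s:
            out.append(Violation(vid, "episode_end_before_start",
                                 f"episode end {ep.end_s}s not after start "
                                 f"{ep.start_s}s"))
        if ep.start_s > rec.observation_end_s:
            out.append(Violation(vid, "episode_beyond_window",
                                 f"episode starts at {ep.start_s}s, window ends "
                                 f"{rec.observation_end_s}s"))
        if not ep.is_open and ep.end_s > rec.observation_end_s:
            out.append(Violation(vid, "episode_beyond_window",
                                 f"episode ends at {ep.end_s}s, window ends "
                                 f"{rec.observation_end_s}s"))

    episode_ends = [ep.end_s for ep in rec.episodes if not ep.is_open]
    first_onset = min((e.start_s for e in rec.episodes), default=None)
    for ev in rec.events:
        if ev.time_s < 0:
            out.append(Violation(vid, "event_before_birth",
                                 f"event at {ev.time_s}s"))
        if ev.time_s > rec.observation_end_s:
            out.append(Violation(vid, "event_beyond_window",
                                 f"event at {ev.time_s}s, window ends "
                                 f"{rec.observation_end_s}s"))
        if ev.kind is EventKind.REMOVAL:
            if not any(abs(ev.time_s - end) <= REMOVAL_MATCH_TOLERANCE_S
                       for end in episode_ends):
                out.append(Violation(vid, "unmatched_removal",
                                     f"removal at {ev.time_s}s matches no episode "
                                     f"end within {REMOVAL_MATCH_TOLERANCE_S}s"))
        if ev.kind is EventKind.POLICY_HOLD and first_onset is not None \
                and ev.time_s > first_onset:
            out.append(Violation(vid, "policy_hold_after_contact",
                                 f"policy hold at {ev.time_s}s after first contact "
                                 f"at {first_onset}s"))

    for st in rec.stages:
        if not 1 <= st.stage <= 9:
            out.append(Violation(vid, "stage_out_of_range",
                                 f"stage {st.stage} outside 1..9"))
        if st.onset_s < 0:
            out.append(Violation(vid, "stage_before_birth",
                                 f"stage {st.stage} onset {st.onset_s}s"))
        if not isinstance(st.offset_s, OpenEnd) and st.offset_s <= st.onset_s:
            out.append(Violation(vid, "stage_offset_before_onset",
                                 f"stage {st.stage} offset {st.offset_s}s not "
                                 f"after onset {st.onset_s}s"))
        if st.onset_s > rec.observation_end_s:
            out.append(Violation(vid, "stage_beyond_window",
                                 f"stage {st.stage} onset {st.onset_s}s beyond "
                                 f"window end {rec.observation_end_s}s"))

    return out
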