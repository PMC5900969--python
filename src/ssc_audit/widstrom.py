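"""Widström nine-stage newborn behaviour sequence logic.

In immediate, continuous, uninterrupted skin-to-skin contact, term newborns
progress through nine observable instinctive stages in the first hour or so:
birth cry (1), relaxation (2), awakening (3), activity (4), rest (5),
crawling (6), familiarization (7), suckling (8) and sleep (9).  Rest is
special — it can occur at any point, interspersed between stages — so it
never counts toward progression order or the progression ceiling.

The practice standard assessed here is *suckling achieved*: a stage-8
annotation (self-attachment and suckling) inside the audit window.  Sleep
(stage 9) typically occurs 1.5–2 h after birth, beyond a 60-minute window,
and is not required.
"""

from __future__ import annotations

from dataclasses import dataclass

from .timeline_model import StageAnnotation

__all__ = ["REST_STAGE", "SUCKLING_STAGE", "StageOutcome", "assess_stages"]

REST_STAGE = 5
SUCKLING_STAGE = 8


@dataclass(frozen=True)
class StageOutcome:
    """Summary of a dyad's stage progression within an audit window.

    ``highest_stage`` is 0 when no (non-rest) stage was observed.
    """

    highest_stage: int
    achieved_suckling: bool
    sequence_violations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.achieved_suckling and self.highest_stage < SUCKLING_STAGE:
            raise ValueError("suckling achieved implies highest stage >= 8")


def assess_stages(
    stages: list[StageAnnotation] | tuple[StageAnnotation, ...],
    window_end_s: int,
) -> StageOutcome:
    """Assess stage progression from coded annotations up to ``window_end_s``.

    Only annotations with onset at or before the window end count.  The
    highest stage excludes rest (stage 5): rest never raises the progression
    ceiling.  Suckling is achieved iff a stage-8 onset falls inside the
    window.  Sequence violations are pairs of non-rest stages whose first
    onsets occur in decreasing stage order; missing intermediate stages are
    tolerated (coders may miss brief stages).
    """
    in_window = [s for s in stages if s.onset_s <= window_end_s]
    non_rest = [s for s in in_window if s.stage != REST_STAGE]

    highest = max((s.stage for s in non_rest), default=0)
    suckled = any(s.stage == SUCKLING_STAGE for s in non_rest)

    first_onset: dict[int, int] = {}
    for s in non_rest:
        if s.stage not in first_onset or s.onset_s < first_onset[s.stage]:
            first_onset[s.stage] = s.onset_s
    by_onset = sorted(first_onset.items(), key=lambda kv: (kv[1], kv[0]))
    violations: list[str] = []
    for i, (stage_i, onset_i) in enumerate(by_onset):
        for stage_j, onset_j in by_onset[i + 1:]:
            if onset_j > onset_i and stage_j < stage_i:
                violations.append(
                    f"stage {stage_i} (onset {onset_i}s) precedes "
                    f"stage {stage_j} (onset {onset_j}s)"
                )
    return StageOutcome(
        highest_stage=highest,
        achieved_suckling=suckled,
        sequence_violations=tuple(violations),
    )
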