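"""Canadian-modified Robson ten-group obstetric classification.

The Robson system partitions every birth into exactly one of ten groups using
parity, previous caesarean, plurality, presentation, gestational age and
labour onset; the Canadian modification adds A/B/C onset subgroups.  The
classifier here is total and single-valued over valid profiles.

Two modes are offered.  ``strict`` applies the standard precedence in which a
previous caesarean in a term singleton cephalic pregnancy lands in group 5.
``paper_compat`` reproduces a published audit's bookkeeping that filed
elective repeat caesareans under group 4B instead; the discrepancy is
surfaced, not resolved, and strict is the default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .timeline_model import LabourOnset, ObstetricProfile, Plurality, Presentation

__all__ = ["RobsonMode", "Subgroup", "RobsonGroup", "classify_robson", "parse_robson"]

TERM_WEEKS = 37


class RobsonMode(str, enum.Enum):
    STRICT = "strict"
    PAPER_COMPAT = "paper_compat"


class Subgroup(str, enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    NONE = ""


@dataclass(frozen=True, order=True)
class RobsonGroup:
    """A Robson group 1–10 with optional onset subgroup.

    Groups 1 and 3 carry no subgroup; 2 and 4 use A (induced) / B (caesarean
    before labour); 5–10 use A (spontaneous) / B (induced) / C (caesarean
    before labour).
    """

    group: int
    subgroup: Subgroup = Subgroup.NONE

    def __post_init__(self) -> None:
        if not 1 <= self.group <= 10:
            raise ValueError(f"Robson group {self.group} outside 1..10")
        if self.group in (1, 3):
            allowed = {Subgroup.NONE}
        elif self.group in (2, 4):
            allowed = {Subgroup.A, Subgroup.B}
        else:
            allowed = {Subgroup.A, Subgroup.B, Subgroup.C}
        if self.subgroup not in allowed:
            raise ValueError(
                f"subgroup {self.subgroup.value or 'none'} invalid for group {self.group}"
            )

    def __str__(self) -> str:
        return f"{self.group}{self.subgroup.value}"


def parse_robson(text: str) -> RobsonGroup:
    """Parse strings like ``"1"``, ``"4a"``, ``"5C"`` (case-insensitive)."""
    token = text.strip().upper()
    if token and token[-1] in "ABC":
        group_part, sub = token[:-1], Subgroup(token[-1])
    else:
        group_part, sub = token, Subgroup.NONE
    try:
        group = int(group_part)
    except ValueError:
        raise ValueError(f"unparseable Robson group {text!r}") from None
    return RobsonGroup(group, sub)


def _abc(onset: LabourOnset) -> Subgroup:
    return {
        LabourOnset.SPONTANEOUS: Subgroup.A,
        LabourOnset.INDUCED: Subgroup.B,
        LabourOnset.CAESAREAN_BEFORE_LABOUR: Subgroup.C,
    }[onset]


def classify_robson(
    profile: ObstetricProfile, mode: RobsonMode | str = RobsonMode.STRICT
) -> RobsonGroup:
    """Assign exactly one Robson group to a validated obstetric profile.

    Precedence: multiple pregnancy (8) > transverse/oblique lie (9) > breech
    (6 nullipara / 7 multipara) > preterm singleton cephalic (10) > previous
    caesarean (5) > term singleton cephalic by parity and onset (1/2, 3/4).
    Groups 7–10 absorb previous-caesarean cases per their definitions.
    """
    mode = RobsonMode(mode)
    nullipara = profile.parity_prior_births == 0
    onset = profile.labour_onset

    if profile.plurality is Plurality.MULTIPLE:
        return RobsonGroup(8, _abc(onset))
    if profile.presentation is Presentation.TRANSVERSE_OBLIQUE:
        return RobsonGroup(9, _abc(onset))
    if profile.presentation is Presentation.BREECH:
        return RobsonGroup(6 if nullipara else 7, _abc(onset))
    if profile.gestation_weeks < TERM_WEEKS:
        return RobsonGroup(10, _abc(onset))
    if profile.previous_caesarean:
        if (
            mode is RobsonMode.PAPER_COMPAT
            and onset is LabourOnset.CAESAREAN_BEFORE_LABOUR
        ):
            # compatibility quirk: elective repeat caesareans filed under 4B
            return RobsonGroup(4, Subgroup.B)
        return RobsonGroup(5, _abc(onset))
    if onset is LabourOnset.SPONTANEOUS:
        return RobsonGroup(1 if nullipara else 3)
    sub = Subgroup.A if onset is LabourOnset.INDUCED else Subgroup.B
    return RobsonGroup(2 if nullipara else 4, sub)
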