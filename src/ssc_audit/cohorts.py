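"""Packaged study cohorts and a configurable random-cohort simulator.

Two deterministic fixture cohorts reconstruct published first-hour audits at
the per-dyad level: 14 vaginal births at a Japanese Baby-Friendly hospital
(60-minute observation) and 21 elective repeat caesareans at an Australian
metropolitan hospital (2-hour observation).  Only the aggregate funnel counts
and a handful of narrated details (a 3:14-minute repositioning onset, a
removal at 50 minutes, a maternal-request removal, onsets up to 65 minutes)
are fixed by the source material; every other timestamp is an arbitrary
documented constant, synthetic by construction.

The simulator draws cohorts with configurable policy-exclusion probability,
onset-delay distribution, removal hazard, interference probabilities and a
per-stage progression process, from a single owned random stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeline_model import (
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

__all__ = [
    "build_japan_cohort",
    "build_australia_cohort",
    "CohortSimConfig",
    "PROFILE_TEMPLATES",
    "simulate_cohort",
]

_NULLIPARA_SPONT = ObstetricProfile(0, False, Plurality.SINGLETON,
                                    Presentation.CEPHALIC, 39,
                                    LabourOnset.SPONTANEOUS)
_MULTIPARA_SPONT = ObstetricProfile(1, False, Plurality.SINGLETON,
                                    Presentation.CEPHALIC, 39,
                                    LabourOnset.SPONTANEOUS)
_MULTIPARA_INDUCED = ObstetricProfile(2, False, Plurality.SINGLETON,
                                      Presentation.CEPHALIC, 38,
                                      LabourOnset.INDUCED)
_REPEAT_CS_ELECTIVE = ObstetricProfile(1, True, Plurality.SINGLETON,
                                       Presentation.CEPHALIC, 39,
                                       LabourOnset.CAESAREAN_BEFORE_LABOUR)


def _stages_1_to(n: int, onset: int, *, step: int = 350) -> tuple[StageAnnotation, ...]:
    """Evenly spaced stage onsets from SSC onset; arbitrary synthetic spacing."""
    return tuple(
        StageAnnotation(stage=k, onset_s=onset + 60 + (k - 1) * step)
        for k in range(1, n + 1)
    )


def build_japan_cohort() -> list[DyadRecord]:
    """The 14-dyad Japanese vaginal-birth cohort, 60-minute windows.

    Funnel: all 14 immediate (one onset at 194 s after the mother moved off
    hands-and-knees); one removed for routine care at 50 min; 7 of the
    remaining 13 interrupted by staff "helping" the baby to latch; of the 6
    uninterrupted, one progressed to self-attached suckling (stage 8) and
    five stalled at the activity stage (stage 4).  Robson mix: 5 nulliparas
    in spontaneous labour (group 1), 8 multiparas in spontaneous labour
    (group 3), 1 induced multipara (group 4A).
    """
    obs = 3600
    records: list[DyadRecord] = []

    def dyad(did, profile, onset, *, removed_at=None, staff_at=None, top_stage=4,
             stage_step=350):
        episodes = (ContactEpisode(onset, removed_at if removed_at else OPEN),)
        events = []
        if removed_at:
            events.append(CareEvent(removed_at, EventKind.REMOVAL,
                                    Actor.STAFF, EventReason.ROUTINE))
        if staff_at:
            events.append(CareEvent(staff_at, EventKind.IN_PLACE_INTERFERENCE,
                                    Actor.STAFF, EventReason.ROUTINE))
        return DyadRecord(did, profile, obs, episodes, tuple(events),
                          _stages_1_to(top_stage, onset, step=stage_step))

    # group 1: two staff-interfered, three uninterrupted (stalled at stage 4)
    records.append(dyad("YJ01", _NULLIPARA_SPONT, 30, staff_at=1450))
    records.append(dyad("YJ02", _NULLIPARA_SPONT, 55, staff_at=1720))
    records.append(dyad("YJ03", _NULLIPARA_SPONT, 40))
    records.append(dyad("YJ04", _NULLIPARA_SPONT, 70))
    # hands-and-knees birth: repositioning took 3:14 min before contact began
    records.append(dyad("YJ11", _NULLIPARA_SPONT, 194))

    # group 3: one removed at 50 min, five staff-interfered, two uninterrupted
    records.append(dyad("YJ05", _MULTIPARA_SPONT, 25, removed_at=3000,
                        top_stage=3))
    records.append(dyad("YJ06", _MULTIPARA_SPONT, 45, staff_at=1500))
    records.append(dyad("YJ07", _MULTIPARA_SPONT, 60, staff_at=1600))
    records.append(dyad("YJ08", _MULTIPARA_SPONT, 35, staff_at=1800))
    records.append(dyad("YJ09", _MULTIPARA_SPONT, 50, staff_at=2050))
    records.append(dyad("YJ10", _MULTIPARA_SPONT, 90, staff_at=2200))
    records.append(dyad("YJ12", _MULTIPARA_SPONT, 20, top_stage=8, stage_step=380))
    records.append(dyad("YJ13", _MULTIPARA_SPONT, 65))

    # group 4A: one induced multipara, uninterrupted, stalled at stage 4
    records.append(dyad("YJ14", _MULTIPARA_INDUCED, 80))
    return records


def build_australia_cohort() -> list[DyadRecord]:
    """The 21-dyad Australian elective repeat-caesarean cohort, 2-hour windows.

    Funnel: one dyad in contact immediately, seven within 5 minutes after a
    brief hold in theatre, twelve reaching contact between 5 and about 65
    minutes (institutional practice, coded as hospital policy) and one never
    in contact within 2 hours.  Of the eight on-path dyads, seven were
    removed for routine care inside the first hour and the eighth was removed
    at the mother's request (recorded as an interruption).  No newborn
    reached suckling.  All profiles are term singleton cephalic repeat
    caesareans before labour.
    """
    obs = 7200
    prof = _REPEAT_CS_ELECTIVE
    records: list[DyadRecord] = []

    def hold(t: int = 0) -> CareEvent:
        return CareEvent(t, EventKind.POLICY_HOLD, Actor.STAFF,
                         EventReason.HOSPITAL_POLICY)

    # immediate contact, removed for routine care at 30 min
    records.append(DyadRecord(
        "AU01", prof, obs,
        (ContactEpisode(120, 1800),),
        (CareEvent(1800, EventKind.REMOVAL, Actor.STAFF, EventReason.ROUTINE),),
        _stages_1_to(3, 120),
    ))
    # brief theatre delay, then contact within 5 min; removed for routine care
    delayed = [("AU02", 185, 900), ("AU03", 200, 1200), ("AU04", 220, 1500),
               ("AU05", 240, 2100), ("AU06", 260, 2700), ("AU07", 280, 3300)]
    for did, onset, removed_at in delayed:
        records.append(DyadRecord(
            did, prof, obs,
            (ContactEpisode(onset, removed_at),),
            (hold(30),
             CareEvent(removed_at, EventKind.REMOVAL, Actor.STAFF,
                       EventReason.ROUTINE)),
            _stages_1_to(2, onset),
        ))
    # delayed under 5 min; mother asked for the baby to be removed (nausea)
    records.append(DyadRecord(
        "AU08", prof, obs,
        (ContactEpisode(295, 2400),),
        (hold(30),
         CareEvent(2400, EventKind.REMOVAL, Actor.MOTHER,
                   EventReason.MATERNAL_REQUEST)),
        _stages_1_to(4, 295),
    ))
    # contact first established between 5 and ~65 min: institutional practice
    late_onsets = [420, 600, 780, 960, 1200, 1500, 1800, 2100, 2400,
                   2700, 3300, 3903]
    for i, onset in enumerate(late_onsets, start=9):
        records.append(DyadRecord(
            f"AU{i:02d}", prof, obs,
            (ContactEpisode(onset, OPEN),),
            (hold(0),),
            (),
        ))
    # no skin-to-skin at all within the 2-hour window
    records.append(DyadRecord("AU21", prof, obs, (), (hold(0),), ()))
    return records


PROFILE_TEMPLATES: dict[str, ObstetricProfile] = {
    "nullipara_spontaneous": _NULLIPARA_SPONT,
    "nullipara_induced": ObstetricProfile(0, False, Plurality.SINGLETON,
                                          Presentation.CEPHALIC, 40,
                                          LabourOnset.INDUCED),
    "multipara_spontaneous": _MULTIPARA_SPONT,
    "multipara_induced": _MULTIPARA_INDUCED,
    "repeat_cs_elective": _REPEAT_CS_ELECTIVE,
    "preterm_cephalic": ObstetricProfile(0, False, Plurality.SINGLETON,
                                         Presentation.CEPHALIC, 34,
                                         LabourOnset.SPONTANEOUS),
    "breech_nullipara": ObstetricProfile(0, False, Plurality.SINGLETON,
                                         Presentation.BREECH, 39,
                                         LabourOnset.CAESAREAN_BEFORE_LABOUR),
}

_DEFAULT_MIX: tuple[tuple[str, float], ...] = (
    ("nullipara_spontaneous", 0.32),
    ("nullipara_induced", 0.10),
    ("multipara_spontaneous", 0.30),
    ("multipara_induced", 0.08),
    ("repeat_cs_elective", 0.12),
    ("preterm_cephalic", 0.05),
    ("breech_nullipara", 0.03),
)


@dataclass(frozen=True)
class CohortSimConfig:
    """Parameters of the random-cohort generator.

    ``robson_mix`` weights the obstetric profile templates (normalised
    internally).  ``p_policy_exclusion`` is the probability that hospital
    practice withholds immediate contact (a policy hold at birth plus a late
    or absent onset); policy exclusion is the sole source of late starts —
    non-excluded onset delays are exponential with mean
    ``onset_delay_mean_s`` capped at the 5-minute threshold.
    ``removal_hazard_per_min`` drives an exponential time-to-removal clock;
    removals before 60 min end the contact episode.  ``stage_gap_means_s``
    are mean exponential onset gaps between successive stages 1..8 (a zero
    mean makes that transition instantaneous), from which the probability of
    reaching suckling by any time is derivable as a hypoexponential tail.
    """

    n_dyads: int = 100
    robson_mix: tuple[tuple[str, float], ...] = _DEFAULT_MIX
    p_policy_exclusion: float = 0.15
    p_no_ssc_given_excluded: float = 0.10
    onset_delay_mean_s: float = 60.0
    removal_hazard_per_min: float = 0.004
    p_staff_interference: float = 0.30
    p_family_interference: float = 0.05
    stage_gap_means_s: tuple[float, ...] = (30, 120, 300, 600, 400, 700, 600, 600)
    observation_end_s: int = 3600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dyads < 1:
            raise ValueError("n_dyads must be positive")
        for name, p in [("p_policy_exclusion", self.p_policy_exclusion),
                        ("p_no_ssc_given_excluded", self.p_no_ssc_given_excluded),
                        ("p_staff_interference", self.p_staff_interference),
                        ("p_family_interference", self.p_family_interference)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.onset_delay_mean_s < 0 or self.removal_hazard_per_min < 0:
            raise ValueError("rates and delays must be non-negative")
        if len(self.stage_gap_means_s) != 8 or any(m < 0 for m in self.stage_gap_means_s):
            raise ValueError("stage_gap_means_s needs 8 non-negative means")
        unknown = [n for n, _ in self.robson_mix if n not in PROFILE_TEMPLATES]
        if unknown:
            raise ValueError(f"unknown profile templates {unknown}")
        if not self.robson_mix or sum(w for _, w in self.robson_mix) <= 0:
            raise ValueError("robson_mix weights must sum to a positive value")


def simulate_cohort(config: CohortSimConfig) -> list[DyadRecord]:
    """Draw a reproducible random cohort; same config and seed, same cohort.

    Every generated record passes structural validation: removals coincide
    with episode ends, policy holds precede first contact, and all times fall
    inside the observation window.
    """
    rng = np.random.default_rng(config.seed)
    horizon = 3600  # the audited first hour
    names = [n for n, _ in config.robson_mix]
    weights = np.array([w for _, w in config.robson_mix], dtype=float)
    weights /= weights.sum()

    records: list[DyadRecord] = []
    for i in range(config.n_dyads):
        did = f"SIM{i:05d}"
        profile = PROFILE_TEMPLATES[rng.choice(names, p=weights)]
        events: list[CareEvent] = []
        episodes: list[ContactEpisode] = []
        onset: int | None

        if rng.random() < config.p_policy_exclusion:
            events.append(CareEvent(0, EventKind.POLICY_HOLD, Actor.STAFF,
                                    EventReason.HOSPITAL_POLICY))
            if rng.random() < config.p_no_ssc_given_excluded:
                onset = None
            else:
                onset = int(rng.integers(301, config.observation_end_s))
                episodes.append(ContactEpisode(onset, OPEN))
        else:
            delay = rng.exponential(config.onset_delay_mean_s) \
                if config.onset_delay_mean_s > 0 else 0.0
            onset = min(int(delay), 300)
            removal_at: int | None = None
            if config.removal_hazard_per_min > 0:
                t_removal = onset + rng.exponential(
                    1.0 / config.removal_hazard_per_min) * 60.0
                if t_removal < horizon:
                    removal_at = max(onset + 1, int(t_removal))
            if removal_at is not None:
                episodes.append(ContactEpisode(onset, removal_at))
                events.append(CareEvent(removal_at, EventKind.REMOVAL,
                                        Actor.STAFF, EventReason.ROUTINE))
            else:
                episodes.append(ContactEpisode(onset, OPEN))
            if rng.random() < config.p_staff_interference:
                t = int(rng.integers(onset + 60, horizon - 60))
                events.append(CareEvent(t, EventKind.IN_PLACE_INTERFERENCE,
                                        Actor.STAFF, EventReason.ROUTINE))
            if rng.random() < config.p_family_interference:
                t = int(rng.integers(onset + 60, horizon - 60))
                events.append(CareEvent(t, EventKind.IN_PLACE_INTERFERENCE,
                                        Actor.FAMILY, EventReason.UNKNOWN))

        stages: list[StageAnnotation] = []
        if onset is not None:
            cap = config.observation_end_s
            if any(ev.kind is EventKind.REMOVAL for ev in events):
                cap = min(cap, next(ev.time_s for ev in events
                                    if ev.kind is EventKind.REMOVAL))
            t = float(onset)
            for stage, mean in enumerate(config.stage_gap_means_s, start=1):
                t += (rng.exponential(mean) if mean > 0 else 0.0) + 1.0
                if t > cap:
                    break
                stages.append(StageAnnotation(stage=stage, onset_s=int(t)))

        records.append(DyadRecord(
            did, profile, config.observation_end_s,
            tuple(episodes),
            tuple(sorted(events, key=lambda e: e.time_s)),
            tuple(stages),
        ))
    return records
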