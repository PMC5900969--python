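"""CSV input/output for cohorts, results and the audit matrix.

Three input tables describe a cohort, all UTF-8 comma-delimited with a
mandatory header row ("NA" or an empty cell means missing):

``profiles.csv``
    dyad_id, parity_prior_births, previous_caesarean, plurality,
    presentation, gestation_weeks, labour_onset, observation_end
``events.csv``
    dyad_id, time, kind, actor, reason — where ``kind`` is one of
    ``ssc_start`` / ``ssc_end`` (delimiting skin-to-skin contact episodes;
    an episode still running at the window end simply has no ``ssc_end``
    row), ``removal``, ``in_place_interference`` or ``policy_hold``.
``stages.csv``
    dyad_id, stage, onset, offset — ``offset`` may be missing or ``open``
    for a censored stage interval.

Times are written in one of three declared notations (:class:`TimeDialect`):
plain seconds, decimal minutes (65.05 min = 3903 s), or mm:ss (``3:14`` =
194 s; a dotted token such as ``65.05`` reads as 65 min 05 s).  The dialect
is declared per file set, never guessed: the same token can mean different
instants under different notations.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from pathlib import Path

import pandas as pd

from .pathway import PathwayConfig, PathwayResult
from .report import AuditReport, render
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
    OpenEnd,
    Plurality,
    Presentation,
    StageAnnotation,
    canonicalized,
    validate_record,
)

__all__ = [
    "TimeDialect",
    "parse_time",
    "format_time",
    "read_cohort",
    "write_cohort",
    "write_results",
    "load_config",
]

logger = logging.getLogger(__name__)

PROFILE_COLUMNS = [
    "dyad_id", "parity_prior_births", "previous_caesarean", "plurality",
    "presentation", "gestation_weeks", "labour_onset", "observation_end",
]
EVENT_COLUMNS = ["dyad_id", "time", "kind", "actor", "reason"]
STAGE_COLUMNS = ["dyad_id", "stage", "onset", "offset"]

_EPISODE_START = "ssc_start"
_EPISODE_END = "ssc_end"
_MISSING = {"", "NA", "na", "NaN", "nan", None}


class TimeDialect(str, enum.Enum):
    SECONDS = "seconds"
    DECIMAL_MINUTES = "decimal_minutes"
    MM_SS = "mm_ss"


def parse_time(token: str, dialect: TimeDialect | str) -> int:
    """Convert one time token to integer seconds since birth."""
    dialect = TimeDialect(dialect)
    token = str(token).strip()
    if ":" in token:
        if dialect is not TimeDialect.MM_SS:
            raise ValueError(
                f"colon token {token!r} only valid under the mm_ss dialect"
            )
        mm, ss = token.split(":", 1)
        minutes, seconds = int(mm), int(ss)
        if not 0 <= seconds < 60:
            raise ValueError(f"seconds part out of range in {token!r}")
        return minutes * 60 + seconds
    if dialect is TimeDialect.SECONDS:
        value = float(token)
        if value != int(value):
            raise ValueError(f"non-integer second count {token!r}")
        return int(value)
    if dialect is TimeDialect.DECIMAL_MINUTES:
        return round(float(token) * 60)
    # mm_ss with a dotted token: mm.ss, the seconds part in base 60
    if "." in token:
        mm, ss = token.split(".", 1)
        seconds = int(ss.ljust(2, "0")[:2])
        if seconds >= 60:
            raise ValueError(f"seconds part out of range in {token!r}")
        return int(mm) * 60 + seconds
    return int(token) * 60


def format_time(seconds: int, dialect: TimeDialect | str = TimeDialect.SECONDS) -> str:
    dialect = TimeDialect(dialect)
    if dialect is TimeDialect.SECONDS:
        return str(int(seconds))
    if dialect is TimeDialect.DECIMAL_MINUTES:
        return f"{seconds / 60:.6g}"
    return f"{seconds // 60}:{seconds % 60:02d}"


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def _parse_bool(token: str, context: str) -> bool:
    low = token.strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no"}:
        return False
    raise ValueError(f"{context}: unparseable boolean {token!r}")


def _time_cell(token: str, dialect: TimeDialect, context: str) -> int:
    try:
        return parse_time(token, dialect)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{context}: bad time token {token!r}: {exc}") from None


def read_cohort(
    profiles_path: str | Path,
    events_path: str | Path,
    stages_path: str | Path,
    dialect: TimeDialect | str = TimeDialect.SECONDS,
    strict: bool = True,
) -> list[DyadRecord]:
    """Load and validate a cohort from the three CSV tables.

    All times are converted to seconds under the declared dialect.  Events
    and stages join to profiles on ``dyad_id``; unknown ids are an error
    listing the orphans.  Dyads with a profile but no events or stages get
    empty timelines.  Structural violations found by record validation are
    an error naming each dyad (logged as warnings and returned anyway when
    ``strict`` is false, so callers can report them all).
    """
    dialect = TimeDialect(dialect)
    profiles = _read_table(profiles_path, PROFILE_COLUMNS)
    events = _read_table(events_path, EVENT_COLUMNS)
    stages = _read_table(stages_path, STAGE_COLUMNS)

    known = list(dict.fromkeys(profiles["dyad_id"]))
    if len(known) != len(profiles):
        raise ValueError(f"{profiles_path}: duplicate dyad_id in profiles")
    known_set = set(known)
    for name, df in (("events", events), ("stages", stages)):
        orphans = sorted(set(df["dyad_id"]) - known_set)
        if orphans:
            raise ValueError(
                f"{name} table references unknown dyad ids: {', '.join(orphans)}"
            )

    prof_by_id: dict[str, tuple[ObstetricProfile, int]] = {}
    for i, row in profiles.iterrows():
        ctx = f"{profiles_path}:{i + 2}"
        profile = ObstetricProfile(
            parity_prior_births=int(row["parity_prior_births"]),
            previous_caesarean=_parse_bool(row["previous_caesarean"], ctx),
            plurality=Plurality(row["plurality"].strip()),
            presentation=Presentation(row["presentation"].strip()),
            gestation_weeks=int(row["gestation_weeks"]),
            labour_onset=LabourOnset(row["labour_onset"].strip()),
        )
        prof_by_id[row["dyad_id"]] = (
            profile,
            _time_cell(row["observation_end"], dialect, ctx),
        )

    parsed_events: dict[str, list[tuple[int, str, pd.Series, str]]] = {
        d: [] for d in known
    }
    for i, row in events.iterrows():
        ctx = f"{events_path}:{i + 2}"
        t = _time_cell(row["time"], dialect, ctx)
        parsed_events[row["dyad_id"]].append((t, row["kind"].strip(), row, ctx))

    episodes: dict[str, list[ContactEpisode]] = {d: [] for d in known}
    care: dict[str, list[CareEvent]] = {d: [] for d in known}
    for did, items in parsed_events.items():
        # ssc_end sorts before ssc_start at equal times so back-to-back
        # episodes pair up; other kinds keep file order via stable sort
        items.sort(key=lambda it: (it[0], 0 if it[1] == _EPISODE_END else 1))
        open_start: int | None = None
        for t, kind, row, ctx in items:
            if kind == _EPISODE_START:
                if open_start is not None:
                    raise ValueError(
                        f"{ctx}: ssc_start while an episode is already open"
                    )
                open_start = t
            elif kind == _EPISODE_END:
                if open_start is None:
                    raise ValueError(f"{ctx}: ssc_end with no open episode")
                episodes[did].append(ContactEpisode(open_start, t))
                open_start = None
            else:
                actor = row["actor"].strip()
                reason = row["reason"].strip()
                care[did].append(
                    CareEvent(
                        time_s=t,
                        kind=EventKind(kind),
                        actor=Actor(actor) if actor not in _MISSING else Actor.UNKNOWN,
                        reason=EventReason(reason) if reason not in _MISSING
                        else EventReason.UNKNOWN,
                    )
                )
        if open_start is not None:
            episodes[did].append(ContactEpisode(open_start, OPEN))

    stage_ann: dict[str, list[StageAnnotation]] = {d: [] for d in known}
    for i, row in stages.iterrows():
        ctx = f"{stages_path}:{i + 2}"
        offset_token = str(row["offset"]).strip()
        offset: int | OpenEnd
        if offset_token in _MISSING or offset_token.lower() == "open":
            offset = OPEN
        else:
            offset = _time_cell(offset_token, dialect, ctx)
        stage_ann[row["dyad_id"]].append(
            StageAnnotation(
                stage=int(row["stage"]),
                onset_s=_time_cell(row["onset"], dialect, ctx),
                offset_s=offset,
            )
        )

    records: list[DyadRecord] = []
    problems: list[str] = []
    for did in known:
        profile, obs_end = prof_by_id[did]
        record = canonicalized(
            DyadRecord(
                dyad_id=did,
                profile=profile,
                observation_end_s=obs_end,
                episodes=tuple(episodes[did]),
                events=tuple(care[did]),
                stages=tuple(stage_ann[did]),
            )
        )
        for v in validate_record(record):
            problems.append(str(v))
            logger.warning("validation: %s", v)
        records.append(record)
    if problems and strict:
        raise ValueError("cohort failed validation: " + "; ".join(problems))
    return records


def write_cohort(
    records: list[DyadRecord],
    out_dir: str | Path,
    dialect: TimeDialect | str = TimeDialect.SECONDS,
) -> list[Path]:
    """Export a cohort to the three CSV tables; inverse of :func:`read_cohort`."""
    dialect = TimeDialect(dialect)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    prof_rows, event_rows, stage_rows = [], [], []
    for rec in records:
        p = rec.profile
        prof_rows.append({
            "dyad_id": rec.dyad_id,
            "parity_prior_births": p.parity_prior_births,
            "previous_caesarean": str(p.previous_caesarean).lower(),
            "plurality": p.plurality.value,
            "presentation": p.presentation.value,
            "gestation_weeks": p.gestation_weeks,
            "labour_onset": p.labour_onset.value,
            "observation_end": format_time(rec.observation_end_s, dialect),
        })
        timeline: list[tuple[int, int, dict]] = []
        for ep in rec.episodes:
            timeline.append((ep.start_s, 0, {
                "dyad_id": rec.dyad_id, "time": format_time(ep.start_s, dialect),
                "kind": _EPISODE_START, "actor": "", "reason": "",
            }))
            if not ep.is_open:
                timeline.append((int(ep.end_s), 1, {  # type: ignore[arg-type]
                    "dyad_id": rec.dyad_id, "time": format_time(int(ep.end_s), dialect),  # type: ignore[arg-type]
                    "kind": _EPISODE_END, "actor": "", "reason": "",
                }))
        for ev in rec.events:
            timeline.append((ev.time_s, 2, {
                "dyad_id": rec.dyad_id, "time": format_time(ev.time_s, dialect),
                "kind": ev.kind.value, "actor": ev.actor.value,
                "reason": ev.reason.value,
            }))
        event_rows.extend(row for _, _, row in sorted(timeline, key=lambda t: t[:2]))
        for st in rec.stages:
            stage_rows.append({
                "dyad_id": rec.dyad_id,
                "stage": st.stage,
                "onset": format_time(st.onset_s, dialect),
                "offset": "open" if isinstance(st.offset_s, OpenEnd)
                else format_time(int(st.offset_s), dialect),
            })

    paths = [out / "profiles.csv", out / "events.csv", out / "stages.csv"]
    pd.DataFrame(prof_rows, columns=PROFILE_COLUMNS).to_csv(paths[0], index=False)
    pd.DataFrame(event_rows, columns=EVENT_COLUMNS).to_csv(paths[1], index=False)
    pd.DataFrame(stage_rows, columns=STAGE_COLUMNS).to_csv(paths[2], index=False)
    return paths


def _result_row(r: PathwayResult) -> dict:
    return {
        "dyad_id": r.dyad_id,
        "robson_group": str(r.robson),
        "immediate_status": r.immediate_status.value,
        "continuous_status": r.continuous_status.value,
        "uninterrupted_status": r.uninterrupted_status.value,
        "highest_stage": "" if r.stage_outcome is None
        else r.stage_outcome.highest_stage,
        "achieved_suckling": "" if r.stage_outcome is None
        else str(r.stage_outcome.achieved_suckling).lower(),
        "met_standard": str(r.met_standard).lower(),
        "exit_step": r.exit_step.value,
        "colour": r.colour.value,
    }


def write_results(
    results: list[PathwayResult],
    report: AuditReport,
    out_dir: str | Path,
    config: PathwayConfig | None = None,
    robson_mode: str = "strict",
    version: str = "0.1.0",
) -> list[Path]:
    """Write per-dyad results, the audit matrix in three formats, and run
    metadata; returns the manifest of files written.

    Output is deterministic: rerunning on identical inputs produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    per_dyad = out / "dyad_results.csv"
    pd.DataFrame([_result_row(r) for r in results]).to_csv(per_dyad, index=False)
    manifest.append(per_dyad)

    for fmt, suffix in (("csv", "csv"), ("markdown", "md"), ("json", "json")):
        path = out / f"audit_matrix.{suffix}"
        path.write_text(render(report, fmt), encoding="utf-8")
        manifest.append(path)

    meta = {
        "tool": "ssc-audit",
        "version": version,
        "robson_mode": robson_mode,
        "config": dataclasses.asdict(config or PathwayConfig()),
        "n_dyads": len(results),
    }
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n",
                         encoding="utf-8")
    manifest.append(meta_path)
    return manifest


def load_config(path: str | Path) -> PathwayConfig:
    """Load a :class:`PathwayConfig` from a YAML or JSON file."""
    import yaml

    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    allowed = {f.name for f in dataclasses.fields(PathwayConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PathwayConfig(**data)
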