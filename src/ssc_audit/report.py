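"""Robson-group × pathway-step audit matrix.

Aggregates per-dyad pathway results into the funnel table a facility reviews:
one row per Robson group (all ten rendered, empty or not, so facilities can
be compared side by side; groups with subgroups present get one row per
subgroup), thirteen count columns tracing the cohort through the funnel, and
a totals row.

Column semantics: ``prebirth_n`` is everyone; ``immediate_policy_n`` and
``immediate_emergent_n`` are exits at the immediate step; ``immediate_n`` is
the on-path remainder, of which ``delayed_under_5_n`` is the yellow-caution
subset (an annotation, not an exit).  Each later step splits its predecessor
the same way, ending in ``not_achieved_nine_n`` + ``met_standard_n``.
"""

from __future__ import annotations

import csv as _csv
import io
import json
from dataclasses import dataclass

from .pathway import (
    ContinuousStatus,
    ImmediateStatus,
    PathwayResult,
    UninterruptedStatus,
)
from .robson import parse_robson

__all__ = ["COLUMNS", "AuditRow", "AuditReport", "tabulate", "render", "parse_report"]

COLUMNS: tuple[str, ...] = (
    "prebirth_n",
    "immediate_policy_n",
    "immediate_emergent_n",
    "delayed_under_5_n",
    "immediate_n",
    "removed_emergent_n",
    "removed_routine_n",
    "continuous_n",
    "staff_interfered_n",
    "family_interfered_n",
    "uninterrupted_n",
    "not_achieved_nine_n",
    "met_standard_n",
)

TOTAL_LABEL = "total"


@dataclass(frozen=True)
class AuditRow:
    label: str
    counts: tuple[int, ...]  # aligned with COLUMNS

    def __post_init__(self) -> None:
        if len(self.counts) != len(COLUMNS):
            raise ValueError("count vector length mismatch")

    def as_dict(self) -> dict[str, int]:
        return dict(zip(COLUMNS, self.counts))


@dataclass(frozen=True)
class AuditReport:
    rows: tuple[AuditRow, ...]
    totals: AuditRow


def _count(result: PathwayResult) -> dict[str, int]:
    c = dict.fromkeys(COLUMNS, 0)
    c["prebirth_n"] = 1
    imm = result.immediate_status
    if imm is ImmediateStatus.NOT_IMMEDIATE_POLICY:
        c["immediate_policy_n"] = 1
        return c
    if imm is ImmediateStatus.NOT_IMMEDIATE_EMERGENT:
        c["immediate_emergent_n"] = 1
        return c
    c["immediate_n"] = 1
    if imm is ImmediateStatus.DELAYED_UNDER_THRESHOLD_CAUTION:
        c["delayed_under_5_n"] = 1
    cont = result.continuous_status
    if cont is ContinuousStatus.REMOVED_EMERGENT:
        c["removed_emergent_n"] = 1
        return c
    if cont is ContinuousStatus.REMOVED_ROUTINE:
        c["removed_routine_n"] = 1
        return c
    c["continuous_n"] = 1
    unin = result.uninterrupted_status
    if unin is UninterruptedStatus.STAFF_INTERFERED:
        c["staff_interfered_n"] = 1
        return c
    if unin is UninterruptedStatus.FAMILY_INTERFERED:
        c["family_interfered_n"] = 1
        return c
    c["uninterrupted_n"] = 1
    if result.met_standard:
        c["met_standard_n"] = 1
    else:
        c["not_achieved_nine_n"] = 1
    return c


def tabulate(results: list[PathwayResult]) -> AuditReport:
    """Aggregate results into the audit matrix.

    Each dyad contributes to exactly one exit column and to every on-path
    cumulative column it reached, so the per-row funnel identities hold by
    construction.  Duplicate dyad ids or an empty cohort are errors.
    """
    if not results:
        raise ValueError("cannot tabulate an empty cohort")
    seen: set[str] = set()
    for r in results:
        if r.dyad_id in seen:
            raise ValueError(f"duplicate dyad_id {r.dyad_id!r}")
        seen.add(r.dyad_id)

    acc: dict[str, dict[str, int]] = {}
    for r in results:
        row = acc.setdefault(str(r.robson), dict.fromkeys(COLUMNS, 0))
        for k, v in _count(r).items():
            row[k] += v

    labels: list[str] = []
    for group in range(1, 11):
        present = sorted(
            (lab for lab in acc if parse_robson(lab).group == group),
            key=lambda lab: lab,
        )
        labels.extend(present if present else [str(group)])

    zero = dict.fromkeys(COLUMNS, 0)
    rows = tuple(
        AuditRow(lab, tuple(acc.get(lab, zero)[c] for c in COLUMNS)) for lab in labels
    )
    totals = AuditRow(
        TOTAL_LABEL,
        tuple(sum(row.counts[i] for row in rows) for i in range(len(COLUMNS))),
    )
    return AuditReport(rows=rows, totals=totals)


def render(report: AuditReport, format: str = "csv") -> str:
    """Render the matrix as CSV, a GitHub-flavoured markdown table, or JSON.

    Output is deterministic (byte-identical across runs for equal inputs) and
    round-trippable via :func:`parse_report` for csv and json.
    """
    if format == "csv":
        buf = io.StringIO()
        w = _csv.writer(buf, lineterminator="\n")
        w.writerow(("robson_group",) + COLUMNS)
        for row in report.rows:
            w.writerow((row.label,) + row.counts)
        w.writerow((report.totals.label,) + report.totals.counts)
        return buf.getvalue()
    if format == "markdown":
        header = ["Robson group"] + [c[:-2].replace("_", " ") for c in COLUMNS]
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "|".join(["---"] * len(header)) + "|"]
        for row in list(report.rows) + [report.totals]:
            cells = [row.label] + [str(v) for v in row.counts]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    if format == "json":
        payload = {
            "columns": list(COLUMNS),
            "rows": [
                {"robson_group": row.label, **row.as_dict()} for row in report.rows
            ],
            "totals": {"robson_group": report.totals.label,
                       **report.totals.as_dict()},
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"
    raise ValueError(f"unknown format {format!r}")


def parse_report(text: str, format: str = "csv") -> AuditReport:
    """Inverse of :func:`render` for the csv and json formats."""
    if format == "csv":
        reader = _csv.reader(io.StringIO(text))
        header = next(reader)
        if tuple(header[1:]) != COLUMNS:
            raise ValueError("unexpected audit-matrix CSV header")
        rows = [AuditRow(r[0], tuple(int(v) for v in r[1:])) for r in reader]
        totals = rows.pop()
        if totals.label != TOTAL_LABEL:
            raise ValueError("audit-matrix CSV missing totals row")
        return AuditReport(rows=tuple(rows), totals=totals)
    if format == "json":
        payload = json.loads(text)
        rows = tuple(
            AuditRow(r["robson_group"], tuple(int(r[c]) for c in COLUMNS))
            for r in payload["rows"]
        )
        t = payload["totals"]
        totals = AuditRow(t["robson_group"], tuple(int(t[c]) for c in COLUMNS))
        return AuditReport(rows=rows, totals=totals)
    raise ValueError(f"unknown format {format!r}")
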