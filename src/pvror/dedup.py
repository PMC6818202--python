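"""Two-stage duplicate removal for spontaneous reports.

Spontaneous reporting systems receive the same physical case several times:
as updated versions under one case number, and as independent submissions of
the same event under different case numbers.  Stage 1 collapses versions by
case number, keeping the most recently submitted one.  Stage 2 collapses
reports whose age, sex, event date and reporter country all match exactly.

Recency is a total order — (case_version, receipt_date, primary_id) — so the
survivor of any duplicate group is deterministic.  Stage 2 groups only
reports with all four profile fields present: grouping on missing values
would collapse unrelated reports.
"""

from __future__ import annotations

import csv
import datetime
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .model import Report

_DATE_MIN = datetime.date.min


@dataclass(frozen=True)
class AuditRecord:
    """One duplicate group that lost at least one report."""

    stage: str  # "case" or "profile"
    group_key: str
    survivor: str  # primary_id
    removed: tuple[str, ...]  # primary_ids


def recency_key(report: Report) -> tuple[int, datetime.date, str]:
    """Total order deciding which duplicate survives (greatest wins)."""
    return (
        report.case_version if report.case_version is not None else 0,
        report.receipt_date if report.receipt_date is not None else _DATE_MIN,
        report.primary_id,
    )


def _collapse(
    groups: dict[str, list[Report]],
    stage: str,
    audit: Optional[list[AuditRecord]],
) -> list[Report]:
    survivors = []
    for key, members in groups.items():
        best = max(members, key=recency_key)
        survivors.append(best)
        if audit is not None and len(members) > 1:
            removed = tuple(
                sorted(m.primary_id for m in members if m.primary_id != best.primary_id)
            )
            audit.append(
                AuditRecord(stage=stage, group_key=key, survivor=best.primary_id, removed=removed)
            )
    survivors.sort(key=lambda r: (r.case_id, r.primary_id))
    return survivors


def dedup_by_case(
    reports: Sequence[Report], audit: Optional[list[AuditRecord]] = None
) -> list[Report]:
    """Keep one report per case_id: the most recently submitted version."""
    groups: dict[str, list[Report]] = {}
    for report in reports:
        groups.setdefault(report.case_id, []).append(report)
    return _collapse(groups, "case", audit)


def dedup_by_profile(
    reports: Sequence[Report], audit: Optional[list[AuditRecord]] = None
) -> list[Report]:
    """Collapse reports matching exactly on (age, sex, event_date, country).

    Reports with any of the four fields missing never group.  Input should
    already be case-deduplicated.
    """
    groups: dict[str, list[Report]] = {}
    for report in reports:
        fields = (report.age, report.sex, report.event_date, report.reporter_country)
        if any(f is None for f in fields):
            key = f"__singleton__{report.primary_id}"
        else:
            age_val, age_unit = report.age  # type: ignore[misc]
            key = "|".join(
                [
                    format(age_val, "g"),
                    age_unit,
                    report.sex,  # type: ignore[arg-type]
                    report.event_date.isoformat(),  # type: ignore[union-attr]
                    report.reporter_country,  # type: ignore[list-item]
                ]
            )
        groups.setdefault(key, []).append(report)
    return _collapse(groups, "profile", audit)


def deduplicate(
    reports: Sequence[Report], audit: Optional[list[AuditRecord]] = None
) -> list[Report]:
    """Both stages in the fixed order: case number first, then profile."""
    return dedup_by_profile(dedup_by_case(reports, audit), audit)


def write_audit_log(audit: Sequence[AuditRecord], path: Union[str, Path]) -> None:
    """Write the dedup audit as TSV: stage, group key, survivor, removed ids."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["stage", "group_key", "survivor", "removed"])
        for record in audit:
            writer.writerow(
                [record.stage, record.group_key, record.survivor, ",".join(record.removed)]
            )
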