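"""Independent brute-force oracles used to cross-check pipeline stages.

Deliberately naive: O(n^2) pairwise comparison with union-find for duplicate
grouping, and a direct re-scan of Report objects for contingency cells.
These never call the implementations they check.
"""

from __future__ import annotations

import datetime
from typing import Sequence

from pvror.model import Report


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def _recency(report: Report):
    return (
        report.case_version if report.case_version is not None else 0,
        report.receipt_date if report.receipt_date is not None else datetime.date.min,
        report.primary_id,
    )


def _collapse_pairwise(reports: Sequence[Report], same) -> list[Report]:
    uf = _UnionFind(len(reports))
    for i in range(len(reports)):
        for j in range(i + 1, len(reports)):
            if same(reports[i], reports[j]):
                uf.union(i, j)
    groups: dict[int, list[Report]] = {}
    for idx, report in enumerate(reports):
        groups.setdefault(uf.find(idx), []).append(report)
    return [max(members, key=_recency) for members in groups.values()]


def brute_force_case_dedup(reports: Sequence[Report]) -> set[str]:
    """Surviving primary_ids after case-number dedup, by exhaustive pairing."""
    survivors = _collapse_pairwise(reports, lambda x, y: x.case_id == y.case_id)
    return {r.primary_id for r in survivors}


def brute_force_profile_dedup(reports: Sequence[Report]) -> set[str]:
    """Surviving primary_ids after 4-field profile dedup, by exhaustive pairing."""

    def same(x: Report, y: Report) -> bool:
        fields_x = (x.age, x.sex, x.event_date, x.reporter_country)
        fields_y = (y.age, y.sex, y.event_date, y.reporter_country)
        if any(f is None for f in fields_x) or any(f is None for f in fields_y):
            return False
        return fields_x == fields_y

    survivors = _collapse_pairwise(reports, same)
    return {r.primary_id for r in survivors}


def brute_force_cells(
    reports: Sequence[Report],
    drug: str,
    event_terms: frozenset[str],
    dictionary,
) -> tuple[int, int, int, int]:
    """2x2 cells by direct scan: PS-row resolution and PT intersection inline."""
    a = b = c = d = 0
    for report in reports:
        exposed = False
        for entry in report.drugs:
            if entry.role_code != "PS":
                continue
            generic = dictionary.lookup(entry.verbatim_name)
            if generic is None and entry.active_ingredient:
                generic = dictionary.lookup(entry.active_ingredient)
            if generic == drug:
                exposed = True
        event = bool(report.reactions & event_terms)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return a, b, c, d
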