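"""Core data model shared across the pipeline.

A spontaneous adverse-event report is represented post-ingest as a
:class:`Report`: one demographic record joined with its drug rows and its
set of MedDRA Preferred Terms (PTs).  Downstream stages operate on these
objects; the 2x2 contingency machinery operates on
:class:`ContingencyTable` / :class:`SignalResult`.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Optional

#: (value, unit-code) pair, compared verbatim — no unit conversion.
Age = tuple[float, str]

ROLE_CODES = ("PS", "SS", "C", "I")


@dataclass(frozen=True)
class DrugEntry:
    """One drug row of a report.

    role_code is the reporter-assigned role: PS (primary suspect),
    SS (secondary suspect), C (concomitant), I (interacting).
    canonical_generic is filled in by the exposure stage when the verbatim
    name (or active ingredient) resolves against the drug dictionary.
    """

    role_code: str
    verbatim_name: str
    active_ingredient: Optional[str] = None
    canonical_generic: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role_code not in ROLE_CODES:
            raise ValueError(f"unknown drug role code: {self.role_code!r}")


@dataclass(frozen=True)
class Report:
    """One report version: demographics plus drug and reaction content."""

    primary_id: str
    case_id: str
    case_version: Optional[int] = None
    receipt_date: Optional[datetime.date] = None
    age: Optional[Age] = None
    sex: Optional[str] = None
    event_date: Optional[datetime.date] = None
    reporter_country: Optional[str] = None
    drugs: tuple[DrugEntry, ...] = ()
    reactions: frozenset[str] = frozenset()


@dataclass(frozen=True)
class CaseDefinition:
    """A named, non-empty set of normalized MedDRA PTs.

    Represents either a single PT (e.g. rhabdomyolysis) or a flat SMQ-style
    term list (e.g. hepatic disorders).
    """

    name: str
    terms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError(f"case definition {self.name!r} has no terms")


@dataclass(frozen=True)
class ReportFlags:
    """Event/condition flags for one report, derived from its PT set."""

    primary_id: str
    is_event: bool
    has_hepatic: bool = False
    has_aki: bool = False


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cells for one drug-event pair over a fixed report set.

    a: exposed with event, b: exposed without, c: unexposed with event,
    d: unexposed without.  a+b+c+d equals the analyzed report total.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError(f"cells must be non-negative integers: {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def zero_cells(self) -> tuple[str, ...]:
        return tuple(
            name for name in "abcd" if getattr(self, name) == 0
        )

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane-Anscombe +0.5 cells."""
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass(frozen=True)
class SignalResult:
    """ROR point estimate and Woolf CI for one drug under one analysis variant.

    variant tags: "crude", "adjusted", "subgroup:<condition>:<with|without>".
    ror / ci bounds are None when a zero cell makes the estimate undefined
    and the continuity correction is off; reason then carries a code.
    """

    drug: str
    variant: str
    table: ContingencyTable
    ror: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    z: float = 1.96
    significant: bool = False
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ror is not None and self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.ror <= self.ci_high):
                raise ValueError("CI does not bracket the point estimate")
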