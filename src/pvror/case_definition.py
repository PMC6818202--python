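"""Flag reports as event cases and condition carriers from MedDRA terms.

A case definition is a flat, non-empty set of Preferred Terms — a single PT
(rhabdomyolysis) or an SMQ-style term list (hepatic disorders, acute renal
failure).  A report matches when its reaction set intersects the term set;
matching is exact after trim/upper-case normalization, with no substring or
hierarchy logic (MedDRA's hierarchy is licensed content and term files are
supplied by the user).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

from .faers_io import read_term_list
from .model import CaseDefinition, Report, ReportFlags

#: Literal PT that supplements the acute-renal-failure SMQ list.
AKI_LITERAL_PT = "RENAL FAILURE ACUTE"


def load_case_definition(name: str, path: Union[str, Path]) -> CaseDefinition:
    """Load a case definition from a one-PT-per-line term file."""
    return CaseDefinition(name=name, terms=read_term_list(path))


def build_aki_definition(smq_path: Optional[Union[str, Path]] = None) -> CaseDefinition:
    """Acute kidney injury definition: SMQ term list union the literal PT.

    The literal "Renal failure acute" PT is always included, so the
    definition is valid even without an SMQ file.
    """
    terms: frozenset[str] = frozenset({AKI_LITERAL_PT})
    if smq_path is not None:
        terms = terms | read_term_list(smq_path)
    return CaseDefinition(name="aki", terms=terms)


def matches(report: Report, case_def: CaseDefinition) -> bool:
    """True iff the report's PT set intersects the definition's term set."""
    return not report.reactions.isdisjoint(case_def.terms)


def flag_reports(
    reports: Sequence[Report],
    event_def: CaseDefinition,
    hepatic_def: Optional[CaseDefinition] = None,
    aki_def: Optional[CaseDefinition] = None,
) -> list[ReportFlags]:
    """One ReportFlags per report, order-preserving.

    Condition flags are False when the corresponding definition is not bound.
    """
    flags = []
    for report in reports:
        flags.append(
            ReportFlags(
                primary_id=report.primary_id,
                is_event=matches(report, event_def),
                has_hepatic=matches(report, hepatic_def) if hepatic_def else False,
                has_aki=matches(report, aki_def) if aki_def else False,
            )
        )
    return flags
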