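"""Published FAERS 2004-2017 rhabdomyolysis signal estimates for closure checks.

A public disproportionality analysis of FAERS (2,334,959 deduplicated
reports, 7,685 rhabdomyolysis reports) reported RORs and 95% CIs for several
antibiotics, with the exposed-case cell `a` stated in the text for the newly
identified signals.  Those numbers let the full 2x2 table be reconstructed:
with a known, c = total event reports - a, and N known, :func:`solve_b`
recovers b from the printed point estimate, and the Woolf CI recomputed on
the reconstructed table must round back to the printed bounds.  This module
holds those published inputs and runs the closure check — it is a validation
harness for the CI math, not data the pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .disproportionality import ContingencyTable, ror_ci, ror_point, round_half_up, solve_b

#: Deduplicated report total in the published analysis.
TOTAL_REPORTS = 2_334_959
#: Rhabdomyolysis report total in the published analysis.
EVENT_REPORTS = 7_685


@dataclass(frozen=True)
class ReferenceSignal:
    """One published drug-event estimate whose 2x2 table is reconstructible."""

    drug: str
    variant: str
    a: int
    ror: float
    ci_low: float
    ci_high: float
    n_total: int = TOTAL_REPORTS
    event_total: int = EVENT_REPORTS

    @property
    def c(self) -> int:
        return self.event_total - self.a


REFERENCE_SIGNALS: tuple[ReferenceSignal, ...] = (
    ReferenceSignal("MEROPENEM", "crude", 7, 3.19, 1.51, 6.72),
    ReferenceSignal("PIPERACILLIN-TAZOBACTAM", "crude", 12, 2.61, 1.48, 4.61),
    ReferenceSignal("CEFDITOREN", "crude", 5, 8.61, 3.54, 20.94),
    ReferenceSignal("CEFACLOR", "crude", 3, 7.16, 2.28, 22.49),
    ReferenceSignal("MEROPENEM", "subgroup:hepatic:with", 4, 9.77, 3.61, 26.46),
    ReferenceSignal("MEROPENEM", "subgroup:hepatic:without", 3, 1.68, 0.54, 5.23),
    ReferenceSignal("PIPERACILLIN-TAZOBACTAM", "subgroup:aki:with", 3, 4.91, 1.57, 15.37),
    ReferenceSignal("PIPERACILLIN-TAZOBACTAM", "subgroup:aki:without", 9, 2.26, 1.17, 4.35),
)


@dataclass(frozen=True)
class ClosureResult:
    """Reconstructed table and recomputed estimates for one reference signal."""

    signal: ReferenceSignal
    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float

    @property
    def closes(self) -> bool:
        """True when all three recomputed values round to the published ones."""
        return (
            round_half_up(self.ror) == self.signal.ror
            and round_half_up(self.ci_low) == self.signal.ci_low
            and round_half_up(self.ci_high) == self.signal.ci_high
        )


def closure_check(signal: ReferenceSignal, z: float = 1.96) -> ClosureResult:
    """Reconstruct the 2x2 table from published numbers and recompute ROR/CI."""
    b = solve_b(signal.a, signal.c, signal.n_total, signal.ror)
    d = signal.n_total - signal.a - b - signal.c
    table = ContingencyTable(signal.a, b, signal.c, d)
    point = ror_point(table)
    interval = ror_ci(table, z=z)
    assert point is not None and interval is not None  # cells all positive by construction
    return ClosureResult(signal=signal, table=table, ror=point, ci_low=interval[0], ci_high=interval[1])


def run_all_closure_checks() -> list[ClosureResult]:
    return [closure_check(sig) for sig in REFERENCE_SIGNALS]


def find_reference(drug: str, variant: str) -> Optional[ReferenceSignal]:
    for sig in REFERENCE_SIGNALS:
        if sig.drug == drug.upper() and sig.variant == variant:
            return sig
    return None
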