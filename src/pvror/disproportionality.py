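"""2x2 contingency tables and reporting odds ratios (ROR).

The ROR compares the odds of the target event versus all other events among
reports of a drug with the same odds among all other reports:

    ROR = (a/b) / (c/d) = (a*d) / (b*c)

with the Woolf (log-normal) 95% confidence interval

    exp( ln ROR  +/-  z * sqrt(1/a + 1/b + 1/c + 1/d) ),   z = 1.96.

A signal is declared when the lower CI bound exceeds 1.0 (strict).  Zero
cells leave the estimate undefined by default (with a reason code); the
Haldane-Anscombe +0.5 correction is available by flag.

Variants implemented on top of the crude table: the statin-adjusted analysis
(recompute after removing every report listing any statin, any role code)
and condition-stratified subgroup analyses where exposure is
(drug is PS AND condition present/absent) and the comparator is all other
reports.
"""

from __future__ import annotations

import csv
import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .exposure import DrugDictionary, all_role_generics
from .model import ContingencyTable, Report, ReportFlags, SignalResult

#: The seven statins treated as rhabdomyolysis confounders.
STATINS = frozenset(
    {
        "ATORVASTATIN",
        "FLUVASTATIN",
        "LOVASTATIN",
        "PITAVASTATIN",
        "PRAVASTATIN",
        "ROSUVASTATIN",
        "SIMVASTATIN",
    }
)


def _cells(
    table: ContingencyTable, correction: bool
) -> Optional[tuple[float, float, float, float]]:
    if correction:
        return table.corrected()
    if table.zero_cells():
        return None
    return (float(table.a), float(table.b), float(table.c), float(table.d))


def zero_cell_reason(table: ContingencyTable) -> Optional[str]:
    zeros = table.zero_cells()
    return f"zero_cell:{','.join(zeros)}" if zeros else None


def ror_point(table: ContingencyTable, correction: bool = False) -> Optional[float]:
    """(a*d)/(b*c); None when any cell is 0 and the correction is off."""
    cells = _cells(table, correction)
    if cells is None:
        return None
    a, b, c, d = cells
    return (a * d) / (b * c)


def ror_ci(
    table: ContingencyTable, z: float = 1.96, correction: bool = False
) -> Optional[tuple[float, float]]:
    """Woolf interval on the same (possibly corrected) cells as the point estimate."""
    cells = _cells(table, correction)
    if cells is None:
        return None
    a, b, c, d = cells
    log_ror = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_ror - z * se), math.exp(log_ror + z * se))


def compute_signal(
    drug: str,
    variant: str,
    table: ContingencyTable,
    z: float = 1.96,
    correction: bool = False,
) -> SignalResult:
    """Bundle point estimate, CI and the significance call for one table."""
    point = ror_point(table, correction)
    interval = ror_ci(table, z, correction)
    if point is None or interval is None:
        return SignalResult(
            drug=drug,
            variant=variant,
            table=table,
            ror=None,
            ci_low=None,
            ci_high=None,
            z=z,
            significant=False,
            reason=zero_cell_reason(table),
        )
    low, high = interval
    return SignalResult(
        drug=drug,
        variant=variant,
        table=table,
        ror=point,
        ci_low=low,
        ci_high=high,
        z=z,
        significant=low > 1.0,
    )


def is_significant(result: SignalResult) -> bool:
    """Signal rule: defined lower CI bound strictly above 1.0."""
    return result.ci_low is not None and result.ci_low > 1.0


def build_table(
    flags: Sequence[ReportFlags],
    exposures: Sequence[frozenset[str]],
    drug: str,
) -> ContingencyTable:
    """Crude 2x2 cells for one drug over aligned per-report flags/exposures.

    Exposure unit is the report: a report with the drug among its PS
    generics counts once in a or b.
    """
    if len(flags) != len(exposures):
        raise ValueError("flags and exposures must cover the same report set")
    a = b = c = d = 0
    for flag, exposed_set in zip(flags, exposures):
        exposed = drug in exposed_set
        if exposed and flag.is_event:
            a += 1
        elif exposed:
            b += 1
        elif flag.is_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def subgroup_tables(
    flags: Sequence[ReportFlags],
    exposures: Sequence[frozenset[str]],
    drug: str,
    condition: str,
) -> tuple[ContingencyTable, ContingencyTable]:
    """Stratified tables: exposure = (drug PS and condition present/absent).

    In both tables the comparator cells c, d count all reports outside the
    exposed stratum — including the drug's other stratum.
    """
    if condition not in ("hepatic", "aki"):
        raise ValueError(f"unknown condition {condition!r}; expected hepatic|aki")
    attr = "has_hepatic" if condition == "hepatic" else "has_aki"
    if len(flags) != len(exposures):
        raise ValueError("flags and exposures must cover the same report set")

    def _count(want_condition: bool) -> ContingencyTable:
        a = b = c = d = 0
        for flag, exposed_set in zip(flags, exposures):
            stratum = (drug in exposed_set) and (getattr(flag, attr) is want_condition)
            if stratum and flag.is_event:
                a += 1
            elif stratum:
                b += 1
            elif flag.is_event:
                c += 1
            else:
                d += 1
        return ContingencyTable(a, b, c, d)

    return _count(True), _count(False)


def remove_statin_reports(
    reports: Sequence[Report],
    statins: Iterable[str],
    dictionary: DrugDictionary,
) -> list[Report]:
    """Drop every report in which ANY drug row (any role) resolves to a statin.

    Concomitant statins are the confounder of interest, so the filter is not
    limited to primary-suspect rows.
    """
    statin_set = {s.strip().upper() for s in statins}
    return [
        report
        for report in reports
        if statin_set.isdisjoint(all_role_generics(report, dictionary))
    ]


def solve_b(a: int, c: int, N: int, ror_target: float) -> int:
    """Back-solve the b cell from a printed ROR with a, c and N known.

    Closed form of ror = a*(N-a-b-c)/(b*c):  b = a*(N-a-c)/(c*ror + a),
    rounded to the nearest integer.  Used to reconstruct published 2x2
    tables for closure validation.
    """
    if a < 1 or c < 1 or ror_target <= 0 or a + c >= N:
        raise ValueError("need a >= 1, c >= 1, ror_target > 0, a + c < N")
    b = math.floor(a * (N - a - c) / (c * ror_target + a) + 0.5)
    if b < 1 or N - a - b - c < 1:
        raise ValueError(
            f"no positive b solves ROR={ror_target} with a={a}, c={c}, N={N}"
        )
    return b


def round_half_up(value: float, places: int = 2) -> float:
    """Display rounding: 2 decimal places, ties away from zero."""
    quant = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def write_signals_tsv(results: Sequence[SignalResult], path: Union[str, Path]) -> None:
    """Forest-plot-ready TSV: drug, variant, cells, ROR, CI, significance."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["drug", "variant", "a", "b", "c", "d", "ror", "ci_low", "ci_high", "significant"]
        )
        for res in results:
            fmt = lambda x: "" if x is None else f"{round_half_up(x):.2f}"
            writer.writerow(
                [
                    res.drug,
                    res.variant,
                    res.table.a,
                    res.table.b,
                    res.table.c,
                    res.table.d,
                    fmt(res.ror),
                    fmt(res.ci_low),
                    fmt(res.ci_high),
                    str(res.significant).lower(),
                ]
            )
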