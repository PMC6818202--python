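"""Readers and writers for FAERS-style quarterly ASCII tables.

FAERS distributes quarterly data as dollar-sign-delimited text files with a
header line: one demographics row per report version, multiple drug rows per
report (with role codes), multiple reaction rows per report (one MedDRA PT
each).  This module parses the three schemas into typed raw rows, reads flat
term-list files, and assembles joined :class:`~pvror.model.Report` objects.

Parsing conventions (applied uniformly so that downstream comparisons are
deterministic):

* text fields are trimmed and upper-cased;
* dates parse only as 8-digit YYYYMMDD — partial dates ("2015") are missing;
* ages are (value, unit-code) pairs, kept verbatim with no unit conversion;
* unparseable dates/ages become missing values, never errors.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .model import Age, DrugEntry, Report, ROLE_CODES

logger = logging.getLogger(__name__)

DELIMITER = "$"

#: Modern (post-2012Q3) FAERS column names per schema, in file order.
MODERN_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": (
        "primaryid",
        "caseid",
        "caseversion",
        "fda_dt",
        "age",
        "age_cod",
        "sex",
        "event_dt",
        "reporter_country",
    ),
    "drug": ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"),
    "reac": ("primaryid", "pt"),
}

VALID_SEX_CODES = frozenset({"M", "F", "UNK"})


@dataclass(frozen=True)
class RawDemoRow:
    """One demographics row: one report version."""

    primary_id: str
    case_id: str
    case_version: Optional[int]
    receipt_date: Optional[datetime.date]
    age: Optional[Age]
    sex: Optional[str]
    event_date: Optional[datetime.date]
    reporter_country: Optional[str]


@dataclass(frozen=True)
class RawDrugRow:
    """One drug row; a report has one or more."""

    primary_id: str
    drug_seq: int
    role_code: str
    verbatim_name: str
    active_ingredient: Optional[str]


@dataclass(frozen=True)
class RawReacRow:
    """One reaction row: a single MedDRA Preferred Term."""

    primary_id: str
    preferred_term: str


RawRow = Union[RawDemoRow, RawDrugRow, RawReacRow]


def _norm_text(value: str) -> Optional[str]:
    out = value.strip().upper()
    return out or None


def parse_faers_date(value: str) -> Optional[datetime.date]:
    """Parse an 8-digit YYYYMMDD date; anything else is missing."""
    value = value.strip()
    if len(value) != 8 or not value.isdigit():
        return None
    try:
        return datetime.datetime.strptime(value, "%Y%m%d").date()
    except ValueError:
        return None


def parse_age(value: str, unit: str) -> Optional[Age]:
    value = value.strip()
    if not value:
        return None
    try:
        num = float(value)
    except ValueError:
        return None
    return (num, unit.strip().upper())


def _parse_sex(value: str) -> Optional[str]:
    code = value.strip().upper()
    return code if code in VALID_SEX_CODES else None


def _read_frame(
    path: Union[str, Path],
    schema: str,
    dialect: str,
    column_map: Optional[Mapping[str, str]],
) -> pd.DataFrame:
    if schema not in MODERN_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}; expected demo|drug|reac")
    try:
        frame = pd.read_csv(
            path, sep=DELIMITER, dtype=str, keep_default_na=False, engine="c"
        )
    except pd.errors.EmptyDataError:
        logger.warning("empty %s file: %s", schema, path)
        return pd.DataFrame(columns=list(MODERN_COLUMNS[schema]))
    frame.columns = [str(col).strip().lower() for col in frame.columns]
    if dialect == "legacy":
        if column_map is None:
            raise ValueError("legacy dialect requires a column_map (modern name -> legacy name)")
        rename = {legacy.lower(): modern for modern, legacy in column_map.items()}
        frame = frame.rename(columns=rename)
    elif dialect != "modern":
        raise ValueError(f"unknown dialect {dialect!r}; expected modern|legacy")
    for col in MODERN_COLUMNS[schema]:
        if col not in frame.columns:
            raise ValueError(f"{schema} file {path} is missing required column {col!r}")
    return frame


def read_table(
    path: Union[str, Path],
    schema: str,
    dialect: str = "modern",
    column_map: Optional[Mapping[str, str]] = None,
) -> list[RawRow]:
    """Read one FAERS-style table into typed raw rows.

    Every data line yields exactly one row or one logged skip (blank
    primary_id, unknown role code, empty PT).  Missing required columns are
    a hard error naming the column.
    """
    frame = _read_frame(path, schema, dialect, column_map)
    rows: list[RawRow] = []
    if schema == "demo":
        seen: set[str] = set()
        for rec in frame.itertuples(index=False):
            primary_id = str(rec.primaryid).strip()
            if not primary_id:
                logger.warning("demo row with blank primaryid skipped")
                continue
            if primary_id in seen:
                raise ValueError(f"duplicate primaryid {primary_id!r} in demo file {path}")
            seen.add(primary_id)
            version = str(rec.caseversion).strip()
            rows.append(
                RawDemoRow(
                    primary_id=primary_id,
                    case_id=str(rec.caseid).strip(),
                    case_version=int(version) if version.isdigit() else None,
                    receipt_date=parse_faers_date(str(rec.fda_dt)),
                    age=parse_age(str(rec.age), str(rec.age_cod)),
                    sex=_parse_sex(str(rec.sex)),
                    event_date=parse_faers_date(str(rec.event_dt)),
                    reporter_country=_norm_text(str(rec.reporter_country)),
                )
            )
    elif schema == "drug":
        for rec in frame.itertuples(index=False):
            primary_id = str(rec.primaryid).strip()
            role = str(rec.role_cod).strip().upper()
            name = _norm_text(str(rec.drugname))
            if not primary_id or role not in ROLE_CODES or name is None:
                logger.warning(
                    "drug row skipped (primaryid=%r role=%r name=%r)", primary_id, role, name
                )
                continue
            seq = str(rec.drug_seq).strip()
            rows.append(
                RawDrugRow(
                    primary_id=primary_id,
                    drug_seq=int(seq) if seq.isdigit() else 1,
                    role_code=role,
                    verbatim_name=name,
                    active_ingredient=_norm_text(str(rec.prod_ai)),
                )
            )
    else:  # reac
        for rec in frame.itertuples(index=False):
            primary_id = str(rec.primaryid).strip()
            term = _norm_text(str(rec.pt))
            if not primary_id or term is None:
                logger.warning("reac row skipped (primaryid=%r pt=%r)", primary_id, term)
                continue
            rows.append(RawReacRow(primary_id=primary_id, preferred_term=term))
    return rows


def _date_str(value: Optional[datetime.date]) -> str:
    return value.strftime("%Y%m%d") if value is not None else ""


def write_table(rows: Sequence[RawRow], path: Union[str, Path], schema: str) -> None:
    """Write raw rows back out as a modern-dialect dollar-delimited file."""
    if schema not in MODERN_COLUMNS:
        raise ValueError(f"unknown schema {schema!r}")
    records: list[dict[str, str]] = []
    if schema == "demo":
        for row in rows:
            assert isinstance(row, RawDemoRow)
            records.append(
                {
                    "primaryid": row.primary_id,
                    "caseid": row.case_id,
                    "caseversion": "" if row.case_version is None else str(row.case_version),
                    "fda_dt": _date_str(row.receipt_date),
                    "age": "" if row.age is None else format(row.age[0], "g"),
                    "age_cod": "" if row.age is None else row.age[1],
                    "sex": row.sex or "",
                    "event_dt": _date_str(row.event_date),
                    "reporter_country": row.reporter_country or "",
                }
            )
    elif schema == "drug":
        for row in rows:
            assert isinstance(row, RawDrugRow)
            records.append(
                {
                    "primaryid": row.primary_id,
                    "drug_seq": str(row.drug_seq),
                    "role_cod": row.role_code,
                    "drugname": row.verbatim_name,
                    "prod_ai": row.active_ingredient or "",
                }
            )
    else:
        for row in rows:
            assert isinstance(row, RawReacRow)
            records.append({"primaryid": row.primary_id, "pt": row.preferred_term})
    frame = pd.DataFrame.from_records(records, columns=list(MODERN_COLUMNS[schema]))
    frame.to_csv(path, sep=DELIMITER, index=False, lineterminator="\n")


def read_term_list(path: Union[str, Path]) -> frozenset[str]:
    """Read a flat term-list file: one MedDRA PT per line, "#" comments.

    Terms are trimmed, upper-cased and deduplicated.  An empty result is a
    hard error — a case definition cannot be empty.
    """
    terms: set[str] = set()
    with open(path, "r", encoding="utf-8") as handle:
        for line in handle:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            terms.add(stripped.upper())
    if not terms:
        raise ValueError(f"term list {path} contains no terms")
    return frozenset(terms)


def assemble_reports(
    demo_rows: Sequence[RawDemoRow],
    drug_rows: Sequence[RawDrugRow],
    reac_rows: Sequence[RawReacRow],
) -> list[Report]:
    """Join demo/drug/reac rows on primary_id into Report objects.

    Order follows the demo file; drug rows keep drug_seq order; reactions
    collapse to a set of PTs.  Drug/reaction rows without a matching demo
    row are dropped with a warning.
    """
    demo_ids = {row.primary_id for row in demo_rows}
    drugs_by_id: dict[str, list[RawDrugRow]] = {}
    for row in drug_rows:
        if row.primary_id not in demo_ids:
            logger.warning("drug row for unknown primaryid %s dropped", row.primary_id)
            continue
        drugs_by_id.setdefault(row.primary_id, []).append(row)
    reacs_by_id: dict[str, set[str]] = {}
    for reac in reac_rows:
        if reac.primary_id not in demo_ids:
            logger.warning("reac row for unknown primaryid %s dropped", reac.primary_id)
            continue
        reacs_by_id.setdefault(reac.primary_id, set()).add(reac.preferred_term)

    reports: list[Report] = []
    for demo in demo_rows:
        entries = tuple(
            DrugEntry(
                role_code=d.role_code,
                verbatim_name=d.verbatim_name,
                active_ingredient=d.active_ingredient,
            )
            for d in sorted(drugs_by_id.get(demo.primary_id, []), key=lambda d: d.drug_seq)
        )
        reports.append(
            Report(
                primary_id=demo.primary_id,
                case_id=demo.case_id,
                case_version=demo.case_version,
                receipt_date=demo.receipt_date,
                age=demo.age,
                sex=demo.sex,
                event_date=demo.event_date,
                reporter_country=demo.reporter_country,
                drugs=entries,
                reactions=frozenset(reacs_by_id.get(demo.primary_id, set())),
            )
        )
    return reports
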