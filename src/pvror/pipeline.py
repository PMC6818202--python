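"""End-to-end orchestration: ingest -> dedup -> exposure -> flags -> signals.

Produces three signal families per run, mirroring the standard analysis plan
for a statin-confounded antibiotic-event question:

* crude — RORs on the full deduplicated, date-filtered report set;
* adjusted — RORs after removing every report listing any statin;
* subgroup — condition-stratified RORs (with/without hepatic disorders, with/
  without acute kidney injury) where bound.

The run log records counts at every stage so stage-count monotonicity
(raw >= post-case-dedup >= post-profile-dedup >= analyzed) is auditable.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import case_definition as casedef
from . import dedup as dedup_mod
from . import disproportionality as dispro
from . import exposure as expo
from .faers_io import assemble_reports, parse_faers_date, read_table
from .model import CaseDefinition, Report, ReportFlags, SignalResult

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Dates are YYYYMMDD integers-as-strings (FAERS convention) or
    datetime.date; the date-range filter applies to the receipt date and
    reports with a missing receipt date are excluded from analysis (counted
    in the log).
    """

    demo_path: Union[str, Path]
    drug_path: Union[str, Path]
    reac_path: Union[str, Path]
    out_dir: Union[str, Path]
    dictionary_path: Optional[Union[str, Path]] = None
    event_terms_path: Optional[Union[str, Path]] = None
    hepatic_terms_path: Optional[Union[str, Path]] = None
    aki_terms_path: Optional[Union[str, Path]] = None
    dialect: str = "modern"
    column_map: Optional[dict[str, str]] = None
    statins: tuple[str, ...] = tuple(sorted(dispro.STATINS))
    min_report_threshold: int = 3
    z: float = 1.96
    zero_cell_correction: bool = False
    date_start: Optional[datetime.date] = None
    date_end: Optional[datetime.date] = None

    def __post_init__(self) -> None:
        if self.min_report_threshold < 1:
            raise ValueError("min_report_threshold must be >= 1")
        for attr in ("date_start", "date_end"):
            value = getattr(self, attr)
            if isinstance(value, str):
                parsed = parse_faers_date(value)
                if parsed is None:
                    raise ValueError(f"{attr} must be YYYYMMDD, got {value!r}")
                setattr(self, attr, parsed)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "RunConfig":
        """Flat key = value text config; keys match the field names."""
        values: dict[str, object] = {}
        with open(path, "r", encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                if "=" not in stripped:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, raw = stripped.partition("=")
                key, raw = key.strip(), raw.strip()
                if key in ("min_report_threshold",):
                    values[key] = int(raw)
                elif key == "z":
                    values[key] = float(raw)
                elif key == "zero_cell_correction":
                    values[key] = raw.lower() in ("1", "true", "yes")
                elif key == "statins":
                    values[key] = tuple(s.strip().upper() for s in raw.split(",") if s.strip())
                else:
                    values[key] = raw
        return cls(**values)  # type: ignore[arg-type]


@dataclass
class RunResult:
    """Artifacts and stage counts from one pipeline run."""

    counts: dict[str, int]
    retained_drugs: frozenset[str]
    signals: dict[str, list[SignalResult]]
    reports: list[Report] = field(repr=False, default_factory=list)
    out_dir: Optional[Path] = None


def _load_definitions(config: RunConfig) -> tuple[CaseDefinition, Optional[CaseDefinition], Optional[CaseDefinition]]:
    if config.event_terms_path is not None:
        event_def = casedef.load_case_definition("event", config.event_terms_path)
    else:
        event_def = CaseDefinition("event", frozenset({"RHABDOMYOLYSIS"}))
    hepatic_def = (
        casedef.load_case_definition("hepatic", config.hepatic_terms_path)
        if config.hepatic_terms_path
        else None
    )
    aki_def = (
        casedef.build_aki_definition(config.aki_terms_path) if config.aki_terms_path else None
    )
    return event_def, hepatic_def, aki_def


def _date_filter(
    reports: Sequence[Report],
    start: Optional[datetime.date],
    end: Optional[datetime.date],
    counts: dict[str, int],
) -> list[Report]:
    kept = []
    missing = 0
    for report in reports:
        if start is None and end is None:
            kept.append(report)
            continue
        if report.receipt_date is None:
            missing += 1
            continue
        if start is not None and report.receipt_date < start:
            continue
        if end is not None and report.receipt_date > end:
            continue
        kept.append(report)
    counts["excluded_missing_receipt_date"] = missing
    return kept


def _signal_set(
    reports: Sequence[Report],
    dictionary: expo.DrugDictionary,
    event_def: CaseDefinition,
    hepatic_def: Optional[CaseDefinition],
    aki_def: Optional[CaseDefinition],
    drugs: Sequence[str],
    variant: str,
    config: RunConfig,
) -> list[SignalResult]:
    flags = casedef.flag_reports(reports, event_def, hepatic_def, aki_def)
    exposures = [expo.primary_suspect_exposures(r, dictionary) for r in reports]
    results = []
    for drug in drugs:
        table = dispro.build_table(flags, exposures, drug)
        results.append(
            dispro.compute_signal(
                drug, variant, table, z=config.z, correction=config.zero_cell_correction
            )
        )
    return results


def _subgroup_signals(
    reports: Sequence[Report],
    dictionary: expo.DrugDictionary,
    event_def: CaseDefinition,
    hepatic_def: Optional[CaseDefinition],
    aki_def: Optional[CaseDefinition],
    drugs: Sequence[str],
    config: RunConfig,
) -> list[SignalResult]:
    flags = casedef.flag_reports(reports, event_def, hepatic_def, aki_def)
    exposures = [expo.primary_suspect_exposures(r, dictionary) for r in reports]
    results = []
    conditions = [
        name
        for name, definition in (("hepatic", hepatic_def), ("aki", aki_def))
        if definition is not None
    ]
    for drug in drugs:
        for condition in conditions:
            with_table, without_table = dispro.subgroup_tables(flags, exposures, drug, condition)
            for tag, table in (("with", with_table), ("without", without_table)):
                results.append(
                    dispro.compute_signal(
                        drug,
                        f"subgroup:{condition}:{tag}",
                        table,
                        z=config.z,
                        correction=config.zero_cell_correction,
                    )
                )
    return results


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write run artifacts.

    Outputs in config.out_dir: signals_crude.tsv, signals_adjusted.tsv,
    signals_subgroup.tsv, dedup_audit.tsv, run_log.txt.
    """
    counts: dict[str, int] = {}
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        demo = read_table(config.demo_path, "demo", config.dialect, config.column_map)
        drug = read_table(config.drug_path, "drug", config.dialect, config.column_map)
        reac = read_table(config.reac_path, "reac", config.dialect, config.column_map)
        reports = assemble_reports(demo, drug, reac)
        counts["raw_report_versions"] = len(reports)
        with_drugs = [r for r in reports if r.drugs]
        counts["dropped_no_drug_rows"] = len(reports) - len(with_drugs)
        reports = with_drugs

        stage = "dedup"
        audit: list[dedup_mod.AuditRecord] = []
        reports = dedup_mod.dedup_by_case(reports, audit)
        counts["post_case_dedup"] = len(reports)
        reports = dedup_mod.dedup_by_profile(reports, audit)
        counts["post_profile_dedup"] = len(reports)
        dedup_mod.write_audit_log(audit, out_dir / "dedup_audit.tsv")

        stage = "date_filter"
        reports = _date_filter(reports, config.date_start, config.date_end, counts)
        counts["analyzed_reports"] = len(reports)

        stage = "exposure"
        dictionary = (
            expo.DrugDictionary.from_tsv(config.dictionary_path)
            if config.dictionary_path
            else expo.default_dictionary()
        )
        exposure_counts = expo.count_exposures(reports, dictionary)
        retained = expo.filter_min_reports(exposure_counts, config.min_report_threshold)
        counts["drugs_with_any_ps_report"] = len(exposure_counts)
        counts["drugs_retained"] = len(retained)
        drugs = sorted(retained)

        stage = "case_definition"
        event_def, hepatic_def, aki_def = _load_definitions(config)
        flags = casedef.flag_reports(reports, event_def, hepatic_def, aki_def)
        counts["event_reports"] = sum(f.is_event for f in flags)

        stage = "disproportionality"
        signals: dict[str, list[SignalResult]] = {}
        signals["crude"] = _signal_set(
            reports, dictionary, event_def, hepatic_def, aki_def, drugs, "crude", config
        )
        adjusted_reports = dispro.remove_statin_reports(reports, config.statins, dictionary)
        counts["adjusted_reports"] = len(adjusted_reports)
        signals["adjusted"] = _signal_set(
            adjusted_reports, dictionary, event_def, hepatic_def, aki_def, drugs, "adjusted", config
        )
        signals["subgroup"] = _subgroup_signals(
            reports, dictionary, event_def, hepatic_def, aki_def, drugs, config
        )

        stage = "write_outputs"
        dispro.write_signals_tsv(signals["crude"], out_dir / "signals_crude.tsv")
        dispro.write_signals_tsv(signals["adjusted"], out_dir / "signals_adjusted.tsv")
        dispro.write_signals_tsv(signals["subgroup"], out_dir / "signals_subgroup.tsv")
        with open(out_dir / "run_log.txt", "w", encoding="utf-8") as handle:
            for key, value in counts.items():
                handle.write(f"{key}: {value}\n")
            handle.write(f"retained_drugs: {','.join(drugs)}\n")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 — re-tag with the failing stage
        raise PipelineError(stage, str(exc)) from exc

    return RunResult(
        counts=counts,
        retained_drugs=retained,
        signals=signals,
        reports=reports,
        out_dir=out_dir,
    )
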