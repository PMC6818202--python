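"""Synthetic FAERS-like data with known ground truth.

The generator emulates the statistical structure a report-level
disproportionality analysis assumes: each unique case has one primary-suspect
drug, an event indicator whose odds are multiplied by a per-drug true
reporting odds ratio (so the planted parameter is exactly the quantity the
ROR estimates), optional statin co-reporting that further multiplies the
event odds (confounding), condition PTs (hepatic / acute kidney injury), and
two kinds of planted duplicates: extra case versions under the same case
number and profile duplicates under a new case number with identical
age / sex / event date / country.

:func:`generate` writes modern-dialect demo/drug/reac files plus a
ground-truth manifest; :func:`sample_population` exposes the same case-level
sampling without file output for simulation studies (CI coverage, confounding
direction).  All randomness flows from a single ``numpy`` generator seeded
from the config, and demographic 4-tuples are drawn unique across distinct
cases, so planted profile duplicates are the only stage-2 matches and a fixed
seed yields byte-identical files.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .disproportionality import STATINS
from .faers_io import RawDemoRow, RawDrugRow, RawReacRow, write_table
from .model import ContingencyTable

EVENT_PT = "RHABDOMYOLYSIS"

#: Decoy reaction vocabulary (disjoint from the event and condition terms).
DECOY_PTS = (
    "PYREXIA",
    "NAUSEA",
    "VOMITING",
    "HEADACHE",
    "DIZZINESS",
    "RASH",
    "PRURITUS",
    "DIARRHOEA",
    "FATIGUE",
    "DYSPNOEA",
    "INSOMNIA",
    "COUGH",
    "ARTHRALGIA",
    "BACK PAIN",
    "HYPOTENSION",
    "HYPERTENSION",
    "ANAEMIA",
    "CONSTIPATION",
    "ABDOMINAL PAIN",
    "OEDEMA PERIPHERAL",
    "CHEST PAIN",
    "PALPITATIONS",
    "SOMNOLENCE",
    "TREMOR",
    "URTICARIA",
)

#: Background (non-catalog) primary-suspect drugs.
DECOY_DRUGS = (
    "PARACETAMOL",
    "IBUPROFEN",
    "OMEPRAZOLE",
    "METFORMIN",
    "LISINOPRIL",
    "AMLODIPINE",
    "WARFARIN",
    "GABAPENTIN",
    "SERTRALINE",
    "PREDNISONE",
)

#: Condition PTs planted when a condition flag is on (subsets of the shipped
#: synthetic SMQ stand-in term lists).
HEPATIC_PTS = ("HEPATIC FAILURE", "LIVER INJURY", "JAUNDICE", "HEPATOTOXICITY")
AKI_PTS = ("ACUTE KIDNEY INJURY", "RENAL FAILURE ACUTE", "ANURIA", "OLIGURIA")

COUNTRIES = ("US", "JP", "DE", "FR", "GB", "CA", "IT", "BR")


@dataclass(frozen=True)
class DrugSpec:
    """Marginal exposure probability, synonyms and planted true ROR for one drug."""

    p_exposure: float
    true_ror: float = 1.0
    synonyms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_exposure <= 1.0:
            raise ValueError(f"p_exposure must be in [0,1], got {self.p_exposure}")
        if self.true_ror <= 0:
            raise ValueError(f"true_ror must be > 0, got {self.true_ror}")


def _default_missingness() -> dict[str, float]:
    return {"age": 0.1, "sex": 0.05, "event_date": 0.2, "reporter_country": 0.05}


def _default_condition_rates() -> dict[str, float]:
    return {"hepatic": 0.05, "aki": 0.05}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Probabilities are per unique case.  ``statin_corr`` is the probability of
    statin co-reporting given a catalog-drug exposure; ``statin_bg_rate`` the
    same for background-drug reports; ``statin_event_boost`` multiplies the
    event odds when a statin is co-reported.  ``condition_rates_by_drug``
    overrides a condition's rate for specific (condition, drug) pairs.
    """

    n_cases: int
    drug_catalog: dict[str, DrugSpec] = field(default_factory=dict)
    seed: int = 0
    duplicate_version_rate: float = 0.2
    profile_duplicate_rate: float = 0.1
    event_base_rate: float = 0.05
    statins: tuple[str, ...] = tuple(sorted(STATINS))
    statin_corr: float = 0.3
    statin_bg_rate: float = 0.05
    statin_event_boost: float = 10.0
    condition_rates: dict[str, float] = field(default_factory=_default_condition_rates)
    condition_rates_by_drug: dict[tuple[str, str], float] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=_default_missingness)

    def __post_init__(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be >= 0")
        probs = [
            self.duplicate_version_rate,
            self.profile_duplicate_rate,
            self.event_base_rate,
            self.statin_corr,
            self.statin_bg_rate,
            *self.condition_rates.values(),
            *self.condition_rates_by_drug.values(),
            *self.missingness.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if not 0.0 < self.event_base_rate < 1.0:
            raise ValueError("event_base_rate must lie strictly in (0, 1)")
        if self.statin_event_boost <= 0:
            raise ValueError("statin_event_boost must be > 0")
        total_p = sum(spec.p_exposure for spec in self.drug_catalog.values())
        if total_p > 1.0 + 1e-12:
            raise ValueError("catalog exposure probabilities sum past 1")
        self.drug_catalog = {k.strip().upper(): v for k, v in self.drug_catalog.items()}


def sample_population(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the case-level truth: one row per unique case.

    Columns: drug, exposed (catalog drug?), statin, event, hepatic, aki.
    Event odds = base_odds * true_ror(drug) * statin_event_boost^statin.
    """
    n = config.n_cases
    names = list(config.drug_catalog)
    probs = [config.drug_catalog[d].p_exposure for d in names]
    bg_mass = 1.0 - sum(probs)
    choice_names = names + ["__background__"]
    idx = rng.choice(len(choice_names), size=n, p=probs + [bg_mass])
    drug = np.array(choice_names, dtype=object)[idx]
    exposed = drug != "__background__"
    # Background cases get a decoy PS drug.
    n_bg = int((~exposed).sum())
    drug[~exposed] = rng.choice(np.array(DECOY_DRUGS, dtype=object), size=n_bg)

    p_statin = np.where(exposed, config.statin_corr, config.statin_bg_rate)
    statin = rng.random(n) < p_statin

    base_odds = config.event_base_rate / (1.0 - config.event_base_rate)
    ror = np.ones(n)
    for name, spec in config.drug_catalog.items():
        ror[drug == name] = spec.true_ror
    odds = base_odds * ror * np.where(statin, config.statin_event_boost, 1.0)
    event = rng.random(n) < odds / (1.0 + odds)

    frame = pd.DataFrame(
        {"drug": drug, "exposed": exposed, "statin": statin, "event": event}
    )
    for cond in ("hepatic", "aki"):
        base = config.condition_rates.get(cond, 0.0)
        rate = np.full(n, base)
        for (c, d), p in config.condition_rates_by_drug.items():
            if c == cond:
                rate[drug == d.strip().upper()] = p
        frame[cond] = rng.random(n) < rate
    return frame


def population_table(
    population: pd.DataFrame, drug: str, exclude_statin: bool = False
) -> ContingencyTable:
    """2x2 cells computed directly from a sampled case-level population."""
    pop = population[~population["statin"]] if exclude_statin else population
    exp = pop["drug"] == drug.strip().upper()
    ev = pop["event"]
    return ContingencyTable(
        int((exp & ev).sum()),
        int((exp & ~ev).sum()),
        int((~exp & ev).sum()),
        int((~exp & ~ev).sum()),
    )


class GroundTruthManifest:
    """Per-primary_id ground truth for one generated dataset.

    One manifest row per emitted report version.  ``lineage`` names the
    unique physical case a row belongs to (profile duplicates point at the
    case they clone); ``kind`` is original / version / profile_dup; exactly
    one row per lineage has ``is_canonical`` True and carries the truth used
    by :meth:`empirical_table`.
    """

    COLUMNS = (
        "primary_id",
        "case_id",
        "lineage",
        "kind",
        "is_canonical",
        "drug",
        "exposed",
        "statin",
        "event",
        "hepatic",
        "aki",
    )

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if frame["primary_id"].duplicated().any():
            raise ValueError("manifest must cover each primary_id exactly once")
        self.frame = frame.reset_index(drop=True)

    @property
    def n_unique_cases(self) -> int:
        return int(self.frame["lineage"].nunique()) if len(self.frame) else 0

    def truth(self) -> pd.DataFrame:
        """One row per unique case (the canonical rows)."""
        return self.frame[self.frame["is_canonical"]]

    def empirical_table(self, drug: str, exclude_statin: bool = False) -> ContingencyTable:
        return population_table(self.truth(), drug, exclude_statin=exclude_statin)

    def empirical_ror(self, drug: str) -> float:
        """Planted-truth ROR; error when any cell is degenerate."""
        t = self.empirical_table(drug)
        if t.zero_cells():
            raise ValueError(f"degenerate planted table for {drug}: {t}")
        return (t.a * t.d) / (t.b * t.c)

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.frame.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "GroundTruthManifest":
        frame = pd.read_csv(path, sep="\t", dtype={"primary_id": str, "case_id": str, "lineage": str})
        return cls(frame)


def _random_date(rng: np.random.Generator, start: datetime.date, end: datetime.date) -> datetime.date:
    span = (end - start).days
    return start + datetime.timedelta(days=int(rng.integers(0, span + 1)))


def _pick_name(rng: np.random.Generator, generic: str, spec: Optional[DrugSpec]) -> str:
    names = (generic,) + (spec.synonyms if spec else ())
    return names[int(rng.integers(0, len(names)))]


def generate(
    config: GeneratorConfig, out_dir: Union[str, Path]
) -> GroundTruthManifest:
    """Write demo/drug/reac files plus a manifest TSV; return the manifest.

    Files are modern-dialect, dollar-delimited.  Determinism: a fixed
    (config, seed) yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    population = sample_population(config, rng)

    demo_rows: list[RawDemoRow] = []
    drug_rows: list[RawDrugRow] = []
    reac_rows: list[RawReacRow] = []
    manifest_rows: list[dict] = []
    used_profiles: set[tuple] = set()
    date_lo, date_hi = datetime.date(2004, 1, 1), datetime.date(2017, 12, 31)

    def emit_version(
        case_id: str,
        version: int,
        receipt: datetime.date,
        profile: tuple,
        content: dict,
        lineage: str,
        kind: str,
        is_canonical: bool,
    ) -> None:
        primary_id = f"{case_id}{version}"
        age, sex, event_date, country = profile
        demo_rows.append(
            RawDemoRow(
                primary_id=primary_id,
                case_id=case_id,
                case_version=version,
                receipt_date=receipt,
                age=age,
                sex=sex,
                event_date=event_date,
                reporter_country=country,
            )
        )
        for seq, (role, name) in enumerate(content["drug_list"], start=1):
            drug_rows.append(
                RawDrugRow(
                    primary_id=primary_id,
                    drug_seq=seq,
                    role_code=role,
                    verbatim_name=name,
                    active_ingredient=None,
                )
            )
        for pt in content["reactions"]:
            reac_rows.append(RawReacRow(primary_id=primary_id, preferred_term=pt))
        manifest_rows.append(
            {
                "primary_id": primary_id,
                "case_id": case_id,
                "lineage": lineage,
                "kind": kind,
                "is_canonical": is_canonical,
                "drug": content["generic"],
                "exposed": content["exposed"],
                "statin": content["statin_generic"] is not None,
                "event": content["event"],
                "hepatic": content["hepatic"],
                "aki": content["aki"],
            }
        )

    next_case_number = 1_000_000
    for i in range(config.n_cases):
        row = population.iloc[i]
        case_id = str(next_case_number)
        next_case_number += 1

        # --- demographics; complete 4-tuples are unique across cases so
        # planted profile duplicates are the only stage-2 matches.
        while True:
            age = (float(rng.integers(1, 91)), "YR")
            sex = "M" if rng.random() < 0.5 else "F"
            event_date = _random_date(rng, date_lo, date_hi)
            country = COUNTRIES[int(rng.integers(0, len(COUNTRIES)))]
            key = (age, sex, event_date, country)
            if key not in used_profiles:
                used_profiles.add(key)
                break
        miss = config.missingness
        profile = (
            None if rng.random() < miss.get("age", 0.0) else age,
            None if rng.random() < miss.get("sex", 0.0) else sex,
            None if rng.random() < miss.get("event_date", 0.0) else event_date,
            None if rng.random() < miss.get("reporter_country", 0.0) else country,
        )
        receipt = _random_date(rng, event_date, date_hi)

        # --- drug and reaction content (shared verbatim across versions/clones)
        generic = str(row["drug"])
        spec = config.drug_catalog.get(generic)
        drug_list: list[tuple[str, str]] = [("PS", _pick_name(rng, generic, spec))]
        statin_generic: Optional[str] = None
        if bool(row["statin"]):
            statin_generic = config.statins[int(rng.integers(0, len(config.statins)))]
            drug_list.append(("C", statin_generic))
        reactions: set[str] = set()
        if bool(row["event"]):
            reactions.add(EVENT_PT)
        if bool(row["hepatic"]):
            reactions.add(HEPATIC_PTS[int(rng.integers(0, len(HEPATIC_PTS)))])
        if bool(row["aki"]):
            reactions.add(AKI_PTS[int(rng.integers(0, len(AKI_PTS)))])
        n_noise = int(rng.poisson(2.0))
        for _ in range(n_noise):
            reactions.add(DECOY_PTS[int(rng.integers(0, len(DECOY_PTS)))])
        if not reactions:  # a report always carries at least one PT
            reactions.add(DECOY_PTS[int(rng.integers(0, len(DECOY_PTS)))])
        content = {
            "generic": generic,
            "exposed": bool(row["exposed"]),
            "statin_generic": statin_generic,
            "event": bool(row["event"]),
            "hepatic": bool(row["hepatic"]),
            "aki": bool(row["aki"]),
            "drug_list": drug_list,
            "reactions": sorted(reactions),
        }

        lineage = case_id
        has_old_version = rng.random() < config.duplicate_version_rate
        if has_old_version:
            old_receipt = max(event_date, receipt - datetime.timedelta(days=30))
            emit_version(case_id, 1, old_receipt, profile, content, lineage, "version", False)
            emit_version(case_id, 2, receipt, profile, content, lineage, "original", True)
        else:
            emit_version(case_id, 1, receipt, profile, content, lineage, "original", True)

        # Profile duplicate: a second case number with identical 4-tuple and
        # content; only possible when all four fields are present.
        if all(f is not None for f in profile) and rng.random() < config.profile_duplicate_rate:
            dup_case_id = str(next_case_number)
            next_case_number += 1
            emit_version(dup_case_id, 1, receipt, profile, content, lineage, "profile_dup", False)

    write_table(demo_rows, out / "demo.txt", "demo")
    write_table(drug_rows, out / "drug.txt", "drug")
    write_table(reac_rows, out / "reac.txt", "reac")
    manifest = GroundTruthManifest(pd.DataFrame(manifest_rows, columns=list(GroundTruthManifest.COLUMNS)))
    manifest.to_tsv(out / "manifest.tsv")
    return manifest


def empirical_ror(manifest: GroundTruthManifest, drug: str) -> float:
    """Module-level convenience: planted-truth ROR from a manifest."""
    return manifest.empirical_ror(drug)
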