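"""Drug-name normalization, generic resolution and exposure selection.

FAERS drug names are free text: brand names, salt forms, dosage strings and
inconsistent capitalization.  Exposure is defined at the report level: a
report is exposed to a drug when any of its primary-suspect (PS) rows
resolves to that canonical generic through a synonym dictionary.  Matching
is exact after normalization — edit-distance matching would silently merge
distinct products and corrupt the contingency counts.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .model import Report

logger = logging.getLogger(__name__)

#: Trailing dosage/form tokens stripped during normalization.
STOP_TOKENS = frozenset({"TABLET", "CAPSULE", "INJECTION", "MG", "ML", "%"})

_NUMERIC = re.compile(r"^\d+(\.\d+)?$")
_NUMERIC_UNIT = re.compile(r"^\d+(\.\d+)?(MG|ML|%)$")


def normalize_name(verbatim: str) -> str:
    """Trim, upper-case, collapse whitespace, strip trailing dosage tokens.

    Tokens removed from the end (repeatedly): the fixed stop-list
    (TABLET, CAPSULE, INJECTION, MG, ML, %), pure numbers, and fused
    number+unit tokens such as ``500MG`` or ``0.9%``.
    """
    tokens = verbatim.strip().upper().split()
    while tokens:
        tail = tokens[-1]
        if tail in STOP_TOKENS or _NUMERIC.match(tail) or _NUMERIC_UNIT.match(tail):
            tokens.pop()
        else:
            break
    return " ".join(tokens)


class DrugDictionary:
    """Mapping canonical generic -> synonym set (brands, salts, spellings).

    Every generic maps to itself; synonym sets must be disjoint across
    generics after normalization (a shared synonym is a hard error, since
    resolution would be ambiguous).
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._synonyms: dict[str, frozenset[str]] = {}
        self._index: dict[str, str] = {}
        for generic, synonyms in mapping.items():
            generic_norm = normalize_name(generic)
            if not generic_norm:
                raise ValueError("empty generic name in dictionary")
            names = {generic_norm} | {normalize_name(s) for s in synonyms}
            names.discard("")
            for name in names:
                owner = self._index.get(name)
                if owner is not None and owner != generic_norm:
                    raise ValueError(
                        f"synonym {name!r} maps to both {owner!r} and {generic_norm!r}"
                    )
                self._index[name] = generic_norm
            self._synonyms[generic_norm] = frozenset(names)

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "DrugDictionary":
        """Load from TSV with columns generic, synonym (one synonym per line)."""
        mapping: dict[str, set[str]] = {}
        with open(path, "r", encoding="utf-8") as handle:
            header = handle.readline()
            if not header.lower().startswith("generic"):
                raise ValueError(f"dictionary {path}: expected header 'generic<TAB>synonym'")
            for line in handle:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"dictionary {path}: malformed line {line!r}")
                generic, synonym = parts
                mapping.setdefault(generic, set()).add(synonym)
        return cls(mapping)

    @property
    def generics(self) -> frozenset[str]:
        return frozenset(self._synonyms)

    def synonyms(self, generic: str) -> frozenset[str]:
        return self._synonyms[normalize_name(generic)]

    def lookup(self, name: str) -> Optional[str]:
        return self._index.get(normalize_name(name))


def default_dictionary() -> DrugDictionary:
    """The shipped fixture dictionary: studied antibiotics plus the seven statins."""
    path = resources.files("pvror.data") / "drug_dictionary.tsv"
    with resources.as_file(path) as real_path:
        return DrugDictionary.from_tsv(real_path)


def resolve_generic(
    verbatim: str,
    dictionary: DrugDictionary,
    active_ingredient: Optional[str] = None,
) -> Optional[str]:
    """Resolve a verbatim drug string to its canonical generic.

    The verbatim name is tried first; the active-ingredient field second.
    Returns None when neither matches any synonym set.
    """
    generic = dictionary.lookup(verbatim)
    if generic is not None:
        return generic
    if active_ingredient:
        generic = dictionary.lookup(active_ingredient)
        if generic is not None:
            logger.debug(
                "resolved %r via active ingredient %r -> %s", verbatim, active_ingredient, generic
            )
            return generic
    return None


def primary_suspect_exposures(report: Report, dictionary: DrugDictionary) -> frozenset[str]:
    """Canonical generics among the report's PS drug rows.

    Rows with other role codes never contribute exposure; unresolved PS rows
    are omitted.
    """
    generics = {
        resolve_generic(entry.verbatim_name, dictionary, entry.active_ingredient)
        for entry in report.drugs
        if entry.role_code == "PS"
    }
    generics.discard(None)
    return frozenset(generics)  # type: ignore[arg-type]


def all_role_generics(report: Report, dictionary: DrugDictionary) -> frozenset[str]:
    """Canonical generics among ALL drug rows regardless of role code."""
    generics = {
        resolve_generic(entry.verbatim_name, dictionary, entry.active_ingredient)
        for entry in report.drugs
    }
    generics.discard(None)
    return frozenset(generics)  # type: ignore[arg-type]


def count_exposures(
    reports: Sequence[Report], dictionary: DrugDictionary
) -> dict[str, int]:
    """Number of reports with each generic as a primary suspect."""
    counts: dict[str, int] = {}
    for report in reports:
        for generic in primary_suspect_exposures(report, dictionary):
            counts[generic] = counts.get(generic, 0) + 1
    return counts


def filter_min_reports(
    exposure_counts: Mapping[str, int], threshold: int = 3
) -> frozenset[str]:
    """Drop drugs with fewer than `threshold` PS reports overall."""
    if threshold < 1:
        raise ValueError(f"threshold must be >= 1, got {threshold}")
    return frozenset(g for g, count in exposure_counts.items() if count >= threshold)
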