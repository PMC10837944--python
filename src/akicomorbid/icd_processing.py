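"""Normalize, map, filter and truncate diagnosis codes into per-patient
ICD-10 category itemsets.

Codes are kept in canonical undotted uppercase form. The three prefix levels
are called ID-3 (category, 3 characters), ID-4 (4 characters) and ID-5
(5 characters). External-cause (V01-Y98) and health-status (Z00-Z99)
categories are excluded before mining.
"""

from __future__ import annotations

import csv
import enum
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set

logger = logging.getLogger(__name__)

AKI_ITEM = "AKI"
#: ICD-10 category for acute kidney failure; replaced by the AKI pseudo-item
AKI_CATEGORY = "N17"

_CANONICAL_RE = re.compile(r"^[A-Z][0-9A-Z]{2}[0-9A-Z]*$")


class Level(enum.IntEnum):
    """Code truncation level: number of leading characters kept."""

    ID3 = 3
    ID4 = 4
    ID5 = 5


@dataclass(frozen=True)
class IcdCode:
    """A diagnosis code with its canonical form and prefix views."""

    raw: str
    version: int = 10
    canonical: str = ""

    def __post_init__(self) -> None:
        if self.version not in (9, 10):
            raise ValueError(f"unsupported ICD version {self.version}")
        if not self.canonical:
            object.__setattr__(self, "canonical", canonicalize(self.raw))
        if self.version == 10 and not _CANONICAL_RE.match(self.canonical):
            raise ValueError(f"malformed ICD-10 code {self.raw!r}")

    @property
    def category(self) -> str:
        return self.canonical[:3]

    @property
    def subcategory(self) -> str:
        return self.canonical[:4]

    @property
    def detail(self) -> Optional[str]:
        return self.canonical if len(self.canonical) >= 5 else None

    def dotted(self) -> str:
        """Display form with the conventional dot after the category."""
        c = self.canonical
        return c if len(c) <= 3 else f"{c[:3]}.{c[3:]}"


def canonicalize(raw: str) -> str:
    """Undotted, uppercase, whitespace-stripped code string."""
    return raw.strip().replace(".", "").upper()


@dataclass
class TransactionSet:
    """Per-patient deduplicated itemsets plus the population size ``N``."""

    items: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items.items())


@dataclass
class GemMapping:
    """ICD-9 to ICD-10 equivalence table (one source may map to many targets)."""

    table: Dict[str, List[str]] = field(default_factory=dict)
    unmapped_count: int = 0

    @classmethod
    def from_csv(cls, path) -> "GemMapping":
        table: Dict[str, List[str]] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if header and header[0].lower() not in ("icd9", "icd_9"):
                # no header row; treat the first line as data
                table.setdefault(canonicalize(header[0]), []).append(canonicalize(header[1]))
            for row in reader:
                if len(row) >= 2 and row[0].strip():
                    table.setdefault(canonicalize(row[0]), []).append(canonicalize(row[1]))
        return cls(table=table)


def map_icd9_to_icd10(code: IcdCode, mapping: GemMapping) -> List[IcdCode]:
    """Map an ICD-9 code to its ICD-10 targets; ICD-10 input passes through.

    Unmapped ICD-9 codes are dropped (empty list) and counted on ``mapping``.
    """
    if code.version == 10:
        return [code]
    targets = mapping.table.get(code.canonical)
    if not targets:
        mapping.unmapped_count += 1
        logger.debug("ICD-9 code %s has no ICD-10 mapping; dropped", code.raw)
        return []
    return [IcdCode(raw=t, version=10) for t in targets]


def _excluded(category: str) -> bool:
    return "V01" <= category <= "Y98" or "Z00" <= category <= "Z99"


def filter_codes(codes: Iterable[IcdCode]) -> Set[IcdCode]:
    """Drop external-cause (V01-Y98) and health-status (Z00-Z99) categories."""
    return {c for c in codes if not _excluded(c.category)}


def truncate(code: IcdCode, level: Level) -> str:
    """Prefix of ``code`` at the requested level; short codes pass unchanged."""
    return code.canonical[: int(level)]


def build_transactions(
    cohort: Iterable,
    labels: Mapping[str, int],
    mapping: Optional[GemMapping] = None,
    min_codes: int = 2,
    level: Level = Level.ID3,
    aki_stages: Iterable[int] = (1, 2, 3),
    use_raw_n17: bool = False,
) -> TransactionSet:
    """Turn a cohort into per-patient itemsets: map -> filter -> truncate ->
    deduplicate, drop patients with fewer than ``min_codes`` items, then add
    the AKI pseudo-item for patients whose stage is in ``aki_stages``.

    ``labels`` maps patient id to AKI stage. By default raw N17 codes are
    removed and replaced by the label-derived pseudo-item; ``use_raw_n17``
    keeps them as ordinary items instead.
    """
    mapping = mapping or GemMapping()
    aki_stages = set(aki_stages)
    out: Dict[str, FrozenSet[str]] = {}
    for patient in cohort:
        mapped: List[IcdCode] = []
        for version, raw in patient.codes:
            try:
                code = IcdCode(raw=raw, version=version)
            except ValueError:
                logger.debug("skipping malformed code %r for %s", raw, patient.id)
                continue
            mapped.extend(map_icd9_to_icd10(code, mapping))
        kept = filter_codes(mapped)
        if not use_raw_n17:
            kept = {c for c in kept if c.category != AKI_CATEGORY}
        itemset = {truncate(c, level) for c in kept}
        if len(itemset) < min_codes:
            continue
        if labels.get(patient.id, 0) in aki_stages and not use_raw_n17:
            itemset.add(AKI_ITEM)
        elif labels.get(patient.id, 0) in aki_stages and use_raw_n17:
            itemset.add(AKI_CATEGORY)
        out[patient.id] = frozenset(itemset)
    return TransactionSet(items=out)


def _load_ranges(resource: str) -> List[tuple]:
    with resources.files("akicomorbid.data").joinpath(resource).open(newline="") as fh:
        reader = csv.DictReader(fh)
        return [tuple(row.values()) for row in reader]


_CHAPTERS: Optional[List[tuple]] = None


def chapter_of(category: str) -> str:
    """ICD-10 chapter numeral ("I" .. "XXII") for a 3-character category."""
    global _CHAPTERS
    if _CHAPTERS is None:
        _CHAPTERS = _load_ranges("icd10_chapters.csv")
    cat = canonicalize(category)[:3]
    for start, end, chapter, _label in _CHAPTERS:
        if start <= cat <= end:
            return chapter
    return "unknown"


def chapter_label(chapter: str) -> str:
    """Human-readable name for a chapter numeral."""
    global _CHAPTERS
    if _CHAPTERS is None:
        _CHAPTERS = _load_ranges("icd10_chapters.csv")
    for _start, _end, numeral, label in _CHAPTERS:
        if numeral == chapter:
            return label
    return "unknown"
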