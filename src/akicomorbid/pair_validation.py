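"""Confirm mined comorbidity pairs against reference datasets.

Three mechanisms are supported:

* membership confirmation against another mining run's pair set
  (the eICU-style check);
* a chi-square test on a local 2x2 co-occurrence count table keyed by
  concept-mapped codes (the COHD-style check, run offline);
* the fallback-replacement algorithm for codes that fail concept mapping
  at the category (ID-3) level: the category is replaced per patient by its
  observed 4-character (ID-4) expansions, the transactions are re-mined,
  and confirmation of any expansion confirms the category; expansions that
  still fail mapping are retried at 5 characters (ID-5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import pandas as pd
from scipy import stats

from .icd_processing import AKI_ITEM, Level, TransactionSet
from .rule_mining import MiningThresholds, PairRule, frequent_pairs

logger = logging.getLogger(__name__)

SIGNIFICANCE = 0.05


def canonical_pair(a: str, b: str) -> Tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class ReferencePairSet:
    """A reference dataset: confirmed pairs and/or co-occurrence counts.

    ``pairs`` supports membership confirmation; ``concept_map`` plus
    ``cooccurrence`` support the chi-square route. ``cooccurrence`` maps a
    canonical pair to ``(n_ab, n_a_only, n_b_only, n_neither)``.
    """

    source: str
    pairs: Set[Tuple[str, str]] = field(default_factory=set)
    concept_map: Dict[str, str] = field(default_factory=dict)
    cooccurrence: Dict[Tuple[str, str], Tuple[int, int, int, int]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.pairs = {canonical_pair(*p) for p in self.pairs}
        self.cooccurrence = {
            canonical_pair(*k): v for k, v in self.cooccurrence.items()
        }

    @classmethod
    def from_pair_csv(cls, path, source: Optional[str] = None) -> "ReferencePairSet":
        frame = pd.read_csv(path, dtype=str)
        name = source or (frame["source"].iloc[0] if "source" in frame and len(frame) else "reference")
        pairs = {canonical_pair(a, b) for a, b in zip(frame["code_a"], frame["code_b"])}
        return cls(source=name, pairs=pairs)

    @classmethod
    def from_cooccurrence_csv(
        cls, path, concept_map_path=None, source: str = "cohd"
    ) -> "ReferencePairSet":
        frame = pd.read_csv(path, dtype={"code_a": str, "code_b": str})
        cooc = {
            canonical_pair(r.code_a, r.code_b): (
                int(r.n_ab),
                int(r.n_a_only),
                int(r.n_b_only),
                int(r.n_neither),
            )
            for r in frame.itertuples(index=False)
        }
        cmap: Dict[str, str] = {}
        if concept_map_path is not None:
            mf = pd.read_csv(concept_map_path, dtype=str)
            cmap = dict(zip(mf["icd10"], mf["concept_id"]))
        return cls(source=source, concept_map=cmap, cooccurrence=cooc)


@dataclass
class ValidationVerdict:
    pair: Tuple[str, str]
    confirmed_by: Dict[str, bool] = field(default_factory=dict)
    matched_level: str = "none"  # "ID3" | "ID4" | "ID5" | "none"
    chi_square: Optional[float] = None
    p_value: Optional[float] = None

    @property
    def final(self) -> str:
        return "confirmed" if any(self.confirmed_by.values()) else "unconfirmed"


def confirm_by_membership(
    pairs: Iterable[Tuple[str, str]], reference: ReferencePairSet
) -> Dict[Tuple[str, str], bool]:
    """True for each pair present (unordered) in the reference pair set."""
    return {
        canonical_pair(*p): canonical_pair(*p) in reference.pairs for p in pairs
    }


def chi_square_2x2(
    n_ab: int, n_a_only: int, n_b_only: int, n_neither: int
) -> Tuple[Optional[float], Optional[float]]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns ``(None, None)`` when a row or column margin is zero, in which
    case the statistic is undefined and the pair cannot be confirmed.
    """
    if min(n_ab, n_a_only, n_b_only, n_neither) < 0:
        raise ValueError("counts must be non-negative")
    table = [[n_ab, n_a_only], [n_b_only, n_neither]]
    margins = (
        n_ab + n_a_only,
        n_b_only + n_neither,
        n_ab + n_b_only,
        n_a_only + n_neither,
    )
    if sum(margins) == 0 or any(m == 0 for m in margins):
        return None, None
    stat, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _chi_square_confirms(
    pair: Tuple[str, str], reference: ReferencePairSet
) -> Tuple[bool, Optional[float], Optional[float]]:
    counts = reference.cooccurrence.get(canonical_pair(*pair))
    if counts is None:
        return False, None, None
    stat, p = chi_square_2x2(*counts)
    if stat is None:
        return False, None, None
    return p < SIGNIFICANCE, stat, p


def _expansions(
    full_codes: Iterable[str], category: str, level: Level
) -> Set[str]:
    return {
        c[: int(level)]
        for c in full_codes
        if c.startswith(category) and len(c) > 3
    }


def _remine_with_replacement(
    transactions: TransactionSet,
    patient_full_codes: Mapping[str, Iterable[str]],
    category: str,
    level: Level,
    thresholds: MiningThresholds,
    aki_item: str,
) -> List[PairRule]:
    """Rebuild transactions with ``category`` replaced by each patient's
    observed finer-level expansions, then re-mine AKI pairs at the same
    thresholds."""
    replaced: Dict[str, FrozenSet[str]] = {}
    for pid, itemset in transactions:
        if category in itemset:
            finer = _expansions(patient_full_codes.get(pid, ()), category, level)
            itemset = (itemset - {category}) | finer
        replaced[pid] = itemset
    remined = frequent_pairs(TransactionSet(items=replaced), thresholds.min_sup)
    out = []
    for rule in remined:
        if aki_item not in (rule.item_a, rule.item_b):
            continue
        partner = rule.item_b if rule.item_a == aki_item else rule.item_a
        if partner.startswith(category) and thresholds.accepts(rule):
            out.append(rule)
    return out


def fallback_match(
    pair: Tuple[str, str],
    reference: ReferencePairSet,
    transactions: TransactionSet,
    patient_full_codes: Mapping[str, Iterable[str]],
    thresholds: Optional[MiningThresholds] = None,
    aki_item: str = AKI_ITEM,
) -> ValidationVerdict:
    """Validate one AKI pair through the ID-3 / ID-4 / ID-5 cascade.

    When the partner category maps to a reference concept, the chi-square
    check applies directly (matched level ID3) and no fallback runs.
    Otherwise the category is replaced by its per-patient ID-4 expansions
    and the re-mined expansion pairs are checked; expansions that still
    fail mapping descend to ID-5.
    """
    thresholds = thresholds or MiningThresholds.paper_defaults()
    a, b = pair
    partner = b if a == aki_item else a
    verdict = ValidationVerdict(pair=canonical_pair(a, b))

    if partner in reference.concept_map:
        ok, stat, p = _chi_square_confirms((aki_item, partner), reference)
        verdict.confirmed_by[reference.source] = ok
        verdict.chi_square, verdict.p_value = stat, p
        verdict.matched_level = "ID3" if ok else "none"
        return verdict

    id4_rules = _remine_with_replacement(
        transactions, patient_full_codes, partner, Level.ID4, thresholds, aki_item
    )
    unmapped_id4: List[str] = []
    for rule in id4_rules:
        sub = rule.partner(aki_item)
        if sub not in reference.concept_map:
            unmapped_id4.append(sub)
            continue
        ok, stat, p = _chi_square_confirms((aki_item, sub), reference)
        if ok:
            verdict.confirmed_by[reference.source] = True
            verdict.chi_square, verdict.p_value = stat, p
            verdict.matched_level = "ID4"
            return verdict

    if unmapped_id4:
        id5_rules = _remine_with_replacement(
            transactions, patient_full_codes, partner, Level.ID5, thresholds, aki_item
        )
        for rule in id5_rules:
            sub = rule.partner(aki_item)
            if sub not in reference.concept_map:
                continue
            ok, stat, p = _chi_square_confirms((aki_item, sub), reference)
            if ok:
                verdict.confirmed_by[reference.source] = True
                verdict.chi_square, verdict.p_value = stat, p
                verdict.matched_level = "ID5"
                return verdict

    verdict.confirmed_by[reference.source] = False
    verdict.matched_level = "none"
    return verdict


def validate_pairs(
    rules: Iterable[PairRule],
    membership_ref: Optional[ReferencePairSet] = None,
    cooccurrence_ref: Optional[ReferencePairSet] = None,
    transactions: Optional[TransactionSet] = None,
    patient_full_codes: Optional[Mapping[str, Iterable[str]]] = None,
    thresholds: Optional[MiningThresholds] = None,
    aki_item: str = AKI_ITEM,
) -> List[ValidationVerdict]:
    """Run every configured confirmation route over a list of mined pairs."""
    verdicts: List[ValidationVerdict] = []
    for rule in rules:
        pair = canonical_pair(rule.item_a, rule.item_b)
        if cooccurrence_ref is not None and transactions is not None:
            verdict = fallback_match(
                pair,
                cooccurrence_ref,
                transactions,
                patient_full_codes or {},
                thresholds,
                aki_item,
            )
        else:
            verdict = ValidationVerdict(pair=pair)
        if membership_ref is not None:
            flags = confirm_by_membership([pair], membership_ref)
            verdict.confirmed_by[membership_ref.source] = flags[pair]
        verdicts.append(verdict)
    return verdicts


def consistency_table(
    verdicts: Iterable[ValidationVerdict],
    source_a: str,
    source_b: str,
    literature_flags: Optional[Mapping[Tuple[str, str], bool]] = None,
) -> Dict[str, int]:
    """Cross-tabulate confirmation by two sources; the pairs confirmed by
    neither are split by the literature flag."""
    table = {
        "yes_yes": 0,
        "yes_no": 0,
        "no_yes": 0,
        "no_no": 0,
        "literature_yes": 0,
        "literature_no": 0,
        "total": 0,
    }
    literature_flags = literature_flags or {}
    for v in verdicts:
        a = bool(v.confirmed_by.get(source_a, False))
        b = bool(v.confirmed_by.get(source_b, False))
        key = f"{'yes' if a else 'no'}_{'yes' if b else 'no'}"
        table[key] += 1
        table["total"] += 1
        if not a and not b:
            if literature_flags.get(v.pair, False):
                table["literature_yes"] += 1
            else:
                table["literature_no"] += 1
    return table
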