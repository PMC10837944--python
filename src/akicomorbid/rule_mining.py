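"""Apriori frequent 1-/2-itemset mining and the three pair measures.

For a pair of items (A, B) over N patient transactions:

* ``sup``  = P(A and B), the joint occurrence fraction
* ``kulc`` = (P(A|B) + P(B|A)) / 2, the Kulczynski measure
* ``lift`` = sup / (P(A) * P(B)); 1 means independence

Candidate pairs are generated only from frequent single items (Apriori
pruning), so the output matches brute-force enumeration exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Optional, Set

from .icd_processing import AKI_ITEM, TransactionSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairRule:
    """An item pair with its counts and interestingness measures."""

    item_a: str
    item_b: str
    n_a: int
    n_b: int
    n_ab: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_ab <= min(self.n_a, self.n_b) <= self.n_total):
            raise ValueError(
                f"inconsistent counts for ({self.item_a},{self.item_b}): "
                f"n_ab={self.n_ab} n_a={self.n_a} n_b={self.n_b} N={self.n_total}"
            )

    @property
    def sup(self) -> float:
        return self.n_ab / self.n_total

    @property
    def kulc(self) -> float:
        return 0.5 * (self.n_ab / self.n_a + self.n_ab / self.n_b)

    @property
    def lift(self) -> float:
        return (self.n_ab * self.n_total) / (self.n_a * self.n_b)

    @property
    def importance(self) -> float:
        """sup * kulc — the node-size / ranking score."""
        return self.sup * self.kulc

    def partner(self, item: str = AKI_ITEM) -> str:
        """The other item of the pair relative to ``item``."""
        if self.item_a == item:
            return self.item_b
        if self.item_b == item:
            return self.item_a
        raise ValueError(f"{item} is not part of pair ({self.item_a},{self.item_b})")


@dataclass(frozen=True)
class MiningThresholds:
    """Cut-offs for pair retention.

    ``min_sup`` is compared inclusively (>=); ``min_kulc`` and ``min_lift``
    strictly (>) unless ``strict`` is False. The published setting
    "(sup:8; kulc:0; lift:1)" is read as min_sup=0.08, min_kulc=0,
    min_lift=1 — see :meth:`paper_defaults`.
    """

    min_sup: float = 0.08
    min_kulc: float = 0.0
    min_lift: float = 1.0
    strict: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_sup <= 1.0:
            raise ValueError("min_sup must be in [0, 1]")
        if self.min_lift < 0:
            raise ValueError("min_lift must be >= 0")

    @classmethod
    def paper_defaults(cls) -> "MiningThresholds":
        return cls(min_sup=0.08, min_kulc=0.0, min_lift=1.0)

    def accepts(self, rule: PairRule) -> bool:
        if rule.sup < self.min_sup:
            return False
        if self.strict:
            return rule.kulc > self.min_kulc and rule.lift > self.min_lift
        return rule.kulc >= self.min_kulc and rule.lift >= self.min_lift


def _item_index(transactions: TransactionSet) -> Dict[str, Set[str]]:
    index: Dict[str, Set[str]] = {}
    for pid, itemset in transactions:
        for item in itemset:
            index.setdefault(item, set()).add(pid)
    return index


def frequent_items(transactions: TransactionSet, min_sup: float = 0.0) -> Dict[str, int]:
    """Items whose patient count / N is at least ``min_sup``."""
    if transactions.n == 0:
        raise ValueError("empty transaction set")
    index = _item_index(transactions)
    n = transactions.n
    return {
        item: len(pids) for item, pids in index.items() if len(pids) / n >= min_sup
    }


def frequent_pairs(
    transactions: TransactionSet, min_sup: float = 0.0
) -> List[PairRule]:
    """All distinct item pairs with joint support >= ``min_sup``.

    Candidates come only from frequent 1-itemsets: a pair's support cannot
    exceed either item's support, so no qualifying pair is missed.
    """
    if transactions.n == 0:
        raise ValueError("empty transaction set")
    index = _item_index(transactions)
    n = transactions.n
    frequent = sorted(
        item for item, pids in index.items() if len(pids) / n >= min_sup
    )
    rules: List[PairRule] = []
    for a, b in combinations(frequent, 2):
        n_ab = len(index[a] & index[b])
        if n_ab / n >= min_sup:
            rules.append(
                PairRule(
                    item_a=a,
                    item_b=b,
                    n_a=len(index[a]),
                    n_b=len(index[b]),
                    n_ab=n_ab,
                    n_total=n,
                )
            )
    return rules


def mine_comorbidities(
    transactions: TransactionSet,
    thresholds: Optional[MiningThresholds] = None,
    aki_item: str = AKI_ITEM,
) -> List[PairRule]:
    """AKI-centered pair rules passing all three thresholds.

    Pairs are re-oriented so ``item_a`` is the AKI item and sorted by
    sup * kulc descending, ties broken by partner code ascending.
    """
    thresholds = thresholds or MiningThresholds.paper_defaults()
    if not any(aki_item in itemset for _, itemset in transactions):
        logger.warning("no transaction contains %r; nothing to mine", aki_item)
        return []
    rules = []
    for rule in frequent_pairs(transactions, thresholds.min_sup):
        if aki_item not in (rule.item_a, rule.item_b):
            continue
        if not thresholds.accepts(rule):
            continue
        if rule.item_a != aki_item:
            rule = PairRule(
                item_a=aki_item,
                item_b=rule.item_a,
                n_a=rule.n_b,
                n_b=rule.n_a,
                n_ab=rule.n_ab,
                n_total=rule.n_total,
            )
        rules.append(rule)
    rules.sort(key=lambda r: (-r.importance, r.item_b))
    return rules


def pairs_to_records(rules: Iterable[PairRule]) -> List[dict]:
    """Plain-dict form for CSV/JSON serialization."""
    return [
        {
            "item_a": r.item_a,
            "item_b": r.item_b,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "n_ab": r.n_ab,
            "N": r.n_total,
            "sup": r.sup,
            "kulc": r.kulc,
            "lift": r.lift,
        }
        for r in rules
    ]
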