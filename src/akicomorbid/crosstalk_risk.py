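"""Stage-stratified risk-factor mining and organ-crosstalk scoring.

Risk factors for severe (stage 3) AKI are partner codes mined for stage 3
and absent from the stage 1 and stage 2 lists. Organ crosstalk is scored per
organ class u as

    score_u = sum over AKI pairs j in u of sup(AKI, j) * kulc(AKI, j)

using a category-range table mapping ICD-10 categories to organ classes
(heart, lung, liver, brain, gut; everything else -> "other"). The bundled
default table is a transparent stand-in and fully user-overridable.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

from .icd_processing import AKI_ITEM, GemMapping, Level, build_transactions
from .rule_mining import MiningThresholds, PairRule, mine_comorbidities

logger = logging.getLogger(__name__)

ORGAN_CLASSES = ("heart", "lung", "liver", "brain", "gut", "other")


@dataclass
class OrganMap:
    """Maps ICD-10 categories to organ classes via inclusive ranges."""

    ranges: List[Tuple[str, str, str]] = field(default_factory=list)

    @classmethod
    def default(cls) -> "OrganMap":
        with resources.files("akicomorbid.data").joinpath("organ_map.csv").open(
            newline=""
        ) as fh:
            rows = [
                (r["range_start"], r["range_end"], r["organ"])
                for r in csv.DictReader(fh)
            ]
        return cls(ranges=rows)

    @classmethod
    def from_csv(cls, path) -> "OrganMap":
        with open(path, newline="") as fh:
            rows = [
                (r["range_start"], r["range_end"], r["organ"])
                for r in csv.DictReader(fh)
            ]
        return cls(ranges=rows)

    def classify(self, category: str) -> str:
        cat = category[:3].upper()
        for start, end, organ in self.ranges:
            if start <= cat <= end:
                return organ
        return "other"


@dataclass
class CrosstalkReport:
    """Per-organ scores with the contributing pairs ranked by sup * kulc."""

    scores: Dict[str, float]
    top_pairs: Dict[str, List[PairRule]]

    @property
    def ranking(self) -> List[str]:
        return sorted(self.scores, key=lambda u: (-self.scores[u], u))

    def to_dict(self) -> dict:
        return {
            "scores": dict(self.scores),
            "ranking": self.ranking,
            "top_pairs": {
                organ: [
                    {
                        "item": r.partner(),
                        "sup": r.sup,
                        "kulc": r.kulc,
                        "lift": r.lift,
                    }
                    for r in rules
                ]
                for organ, rules in self.top_pairs.items()
            },
        }


def stage_specific_pairs(
    cohort: Iterable,
    labels: Mapping[str, int],
    thresholds: Optional[MiningThresholds] = None,
    mapping: Optional[GemMapping] = None,
    min_codes: int = 2,
    level: Level = Level.ID3,
) -> Dict[int, List[PairRule]]:
    """Mine AKI pairs separately per stage, granting the AKI item only to
    patients of that exact stage (stage-s vs. everyone else)."""
    cohort = list(cohort)
    out: Dict[int, List[PairRule]] = {}
    for stage in (1, 2, 3):
        if not any(labels.get(p.id, 0) == stage for p in cohort):
            logger.warning("no patients at stage %d; empty pair list", stage)
            out[stage] = []
            continue
        transactions = build_transactions(
            cohort,
            labels,
            mapping=mapping,
            min_codes=min_codes,
            level=level,
            aki_stages=(stage,),
        )
        out[stage] = mine_comorbidities(transactions, thresholds)
    return out


def severe_risk_factors(stage_lists: Mapping[int, Iterable[PairRule]]) -> List[str]:
    """Partner codes unique to the stage-3 list (absent from stages 1 and 2)."""
    partners = {
        stage: {rule.partner() for rule in stage_lists.get(stage, [])}
        for stage in (1, 2, 3)
    }
    unique = partners[3] - partners[1] - partners[2]
    return sorted(unique)


def crosstalk_scores(
    pairs: Iterable[PairRule],
    organ_map: Optional[OrganMap] = None,
    top_n: int = 3,
) -> CrosstalkReport:
    """Partition AKI pairs by organ class and score each class."""
    organ_map = organ_map or OrganMap.default()
    by_class: Dict[str, List[PairRule]] = {u: [] for u in ORGAN_CLASSES}
    for rule in pairs:
        organ = organ_map.classify(rule.partner())
        by_class.setdefault(organ, []).append(rule)
    scores = {
        organ: sum(r.importance for r in rules) for organ, rules in by_class.items()
    }
    top = {
        organ: sorted(rules, key=lambda r: (-r.importance, r.partner()))[:top_n]
        for organ, rules in by_class.items()
    }
    return CrosstalkReport(scores=scores, top_pairs=top)
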