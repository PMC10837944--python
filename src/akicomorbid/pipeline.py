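"""End-to-end orchestration: simulate -> stage -> transactions -> mine ->
validate -> network -> crosstalk, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import crosstalk_risk, disease_network, pair_validation
from .icd_processing import (
    AKI_ITEM,
    GemMapping,
    IcdCode,
    Level,
    TransactionSet,
    build_transactions,
    filter_codes,
    map_icd9_to_icd10,
)
from .kdigo_staging import AkiLabel, stage_patient
from .rule_mining import MiningThresholds, PairRule, mine_comorbidities, pairs_to_records
from .synthetic_cohort import CohortBundle, SimConfig, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single-file configuration for a full pipeline run."""

    out_dir: str
    cohort_dir: Optional[str] = None
    simulate: Optional[dict] = None  # SimConfig fields; used when cohort absent
    seed: int = 0
    min_sup: float = 0.08
    min_kulc: float = 0.0
    min_lift: float = 1.0
    min_codes: int = 2
    level: int = 3
    stage_filter: int = 1
    top_k: int = 284
    gem_path: Optional[str] = None
    eicu_pairs_path: Optional[str] = None
    cohd_cooccurrence_path: Optional[str] = None
    concept_map_path: Optional[str] = None
    organ_map_path: Optional[str] = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def thresholds(self) -> MiningThresholds:
        return MiningThresholds(
            min_sup=self.min_sup, min_kulc=self.min_kulc, min_lift=self.min_lift
        )

    def config_hash(self) -> str:
        # out_dir is where results land, not what they are; exclude it so
        # runs of the same analysis hash identically wherever they're written
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, outputs: Optional[dict] = None):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage
        self.outputs = outputs or {}


def labels_to_frame(labels: List[AkiLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": lab.id,
                "stage": lab.stage,
                "onset_hours": lab.onset_hours,
                "criterion": lab.criterion,
            }
            for lab in labels
        ],
        columns=["id", "stage", "onset_hours", "criterion"],
    )


def labels_from_csv(path) -> Dict[str, int]:
    frame = pd.read_csv(path, dtype={"id": str})
    return dict(zip(frame["id"], frame["stage"].astype(int)))


def transactions_to_json(transactions: TransactionSet, path) -> None:
    payload = {
        "n": transactions.n,
        "items": {pid: sorted(items) for pid, items in transactions},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def transactions_from_json(path) -> TransactionSet:
    payload = json.loads(Path(path).read_text())
    return TransactionSet(
        items={pid: frozenset(items) for pid, items in payload["items"].items()}
    )


def pairs_from_csv(path) -> List[PairRule]:
    frame = pd.read_csv(path, dtype={"item_a": str, "item_b": str})
    return [
        PairRule(
            item_a=r.item_a,
            item_b=r.item_b,
            n_a=int(r.n_a),
            n_b=int(r.n_b),
            n_ab=int(r.n_ab),
            n_total=int(r.N),
        )
        for r in frame.itertuples(index=False)
    ]


def patient_full_codes(cohort, mapping: Optional[GemMapping] = None) -> Dict[str, set]:
    """Per-patient canonical ICD-10 codes after mapping and filtering, at
    full precision (used by the validation fallback)."""
    mapping = mapping or GemMapping()
    out: Dict[str, set] = {}
    for patient in cohort:
        codes = []
        for version, raw in patient.codes:
            try:
                code = IcdCode(raw=raw, version=version)
            except ValueError:
                continue
            codes.extend(map_icd9_to_icd10(code, mapping))
        out[patient.id] = {c.canonical for c in filter_codes(codes)}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, path: Optional[Path] = None, **counts) -> None:
        manifest["stages"][stage] = counts
        if path is not None:
            manifest["outputs"][stage] = str(path)
        logger.info("stage %s: %s", stage, counts)

    # --- cohort ---------------------------------------------------------
    if config.cohort_dir is not None:
        cohort_dir = Path(config.cohort_dir)
        if not cohort_dir.exists():
            raise PipelineError("cohort", f"cohort directory not found: {cohort_dir}")
        cohort = read_cohort(cohort_dir)
        record("cohort", cohort_dir, patients=len(cohort))
    elif config.simulate is not None:
        sim_fields = dict(config.simulate)
        sim_fields.setdefault("seed", config.seed)
        sim_cfg = SimConfig(**{
            **sim_fields,
            "stage_mix": tuple(sim_fields.get("stage_mix", (0.6, 0.25, 0.1, 0.05))),
            "code_catalog": [tuple(c) for c in sim_fields.get("code_catalog", [])],
            "planted_pairs": [tuple(p) for p in sim_fields.get("planted_pairs", [])],
            "weight_range": tuple(sim_fields.get("weight_range", (55.0, 95.0))),
        })
        bundle = generate_cohort(sim_cfg)
        cohort_dir = out_dir / "cohort"
        write_cohort(bundle, cohort_dir)
        cohort = bundle.patients
        record("cohort", cohort_dir, patients=len(cohort))
    else:
        raise PipelineError("cohort", "neither cohort_dir nor simulate configured")

    # --- KDIGO staging --------------------------------------------------
    labels = [stage_patient(p) for p in cohort]
    labels_path = out_dir / "labels.csv"
    labels_to_frame(labels).to_csv(labels_path, index=False)
    label_map = {lab.id: lab.stage for lab in labels}
    record(
        "staging",
        labels_path,
        patients=len(labels),
        aki=sum(1 for lab in labels if lab.has_aki),
    )

    # --- transactions ---------------------------------------------------
    mapping = GemMapping.from_csv(config.gem_path) if config.gem_path else GemMapping()
    aki_stages = tuple(range(config.stage_filter, 4))
    transactions = build_transactions(
        cohort,
        label_map,
        mapping=mapping,
        min_codes=config.min_codes,
        level=Level(config.level),
        aki_stages=aki_stages,
    )
    tx_path = out_dir / "transactions.json"
    transactions_to_json(transactions, tx_path)
    record("transactions", tx_path, patients=transactions.n,
           dropped=len(cohort) - transactions.n, unmapped_icd9=mapping.unmapped_count)

    # --- mining ---------------------------------------------------------
    rules = mine_comorbidities(transactions, config.thresholds())
    pairs_path = out_dir / "comorbidities.csv"
    pd.DataFrame(
        pairs_to_records(rules),
        columns=["item_a", "item_b", "n_a", "n_b", "n_ab", "N", "sup", "kulc", "lift"],
    ).to_csv(pairs_path, index=False)
    record("mining", pairs_path, pairs=len(rules))

    # --- validation (optional) -----------------------------------------
    verdicts = None
    membership_ref = None
    cooc_ref = None
    if config.eicu_pairs_path:
        membership_ref = pair_validation.ReferencePairSet.from_pair_csv(
            config.eicu_pairs_path, source="eicu"
        )
    if config.cohd_cooccurrence_path:
        cooc_ref = pair_validation.ReferencePairSet.from_cooccurrence_csv(
            config.cohd_cooccurrence_path, config.concept_map_path, source="cohd"
        )
    if membership_ref is not None or cooc_ref is not None:
        verdicts = pair_validation.validate_pairs(
            rules,
            membership_ref=membership_ref,
            cooccurrence_ref=cooc_ref,
            transactions=transactions,
            patient_full_codes=patient_full_codes(cohort, mapping),
            thresholds=config.thresholds(),
        )
        verdicts_path = out_dir / "verdicts.csv"
        pd.DataFrame(
            [
                {
                    "code_a": v.pair[0],
                    "code_b": v.pair[1],
                    "matched_level": v.matched_level,
                    "chi_square": v.chi_square,
                    "p_value": v.p_value,
                    "final": v.final,
                    **{f"confirmed_by_{s}": ok for s, ok in v.confirmed_by.items()},
                }
                for v in verdicts
            ]
        ).to_csv(verdicts_path, index=False)
        record(
            "validation",
            verdicts_path,
            pairs=len(verdicts),
            confirmed=sum(1 for v in verdicts if v.final == "confirmed"),
        )

    # --- disease network ------------------------------------------------
    graph = disease_network.build_network(rules, verdicts, top_k=config.top_k)
    graph_path = out_dir / "disease_network.graphml"
    disease_network.export_graph(graph, graph_path, format="graphml")
    record("network", graph_path, nodes=graph.number_of_nodes(),
           edges=graph.number_of_edges())

    # --- crosstalk and severe-AKI risk factors --------------------------
    organ_map = (
        crosstalk_risk.OrganMap.from_csv(config.organ_map_path)
        if config.organ_map_path
        else crosstalk_risk.OrganMap.default()
    )
    report = crosstalk_risk.crosstalk_scores(rules, organ_map)
    crosstalk_path = out_dir / "crosstalk.json"
    crosstalk_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    record("crosstalk", crosstalk_path,
           classes=sum(1 for s in report.scores.values() if s > 0))

    stage_lists = crosstalk_risk.stage_specific_pairs(
        cohort, label_map, config.thresholds(), mapping,
        min_codes=config.min_codes, level=Level(config.level),
    )
    risks = crosstalk_risk.severe_risk_factors(stage_lists)
    risk_path = out_dir / "risk_factors.csv"
    pd.DataFrame({"code": risks}).to_csv(risk_path, index=False)
    record("risk_factors", risk_path, codes=len(risks))

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
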