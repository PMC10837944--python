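"""Synthetic ICU cohorts with known ground truth.

Generates MIMIC-shaped tables (patients, creatinine events, urine-output
events, diagnoses) in which every patient's AKI stage is planted by
construction and pairwise diagnosis associations can be planted at a chosen
lift. Stage trajectories are built with a safety margin around the staging
thresholds so the staging module recovers the planted stage exactly as long
as ``scr_noise_sd`` stays below ~0.02 mg/dl.

All distributional choices here are stand-ins: the generator exists to make
the downstream pipeline testable, not to model ICU physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .icd_processing import AKI_ITEM
from .kdigo_staging import PatientRecord

#: mid-band creatinine fold increase used to plant each stage
_STAGE_SCR_FACTOR = {1: 1.7, 2: 2.5, 3: 3.5}
#: (rate ml/kg/h, duration h) used to plant each stage via urine output
_STAGE_UO_EPISODE = {1: (0.40, 8), 2: (0.40, 14), 3: (0.20, 26)}

_SEXES = ("F", "M")
_ETHNICITIES = ("white", "black", "asian", "hispanic", "other")


class PlantingError(ValueError):
    """A planted pair implies a 2x2 cell probability outside [0, 1]."""


@dataclass(frozen=True)
class SimConfig:
    n_patients: int
    seed: int = 0
    stage_mix: Tuple[float, float, float, float] = (0.6, 0.25, 0.1, 0.05)
    code_catalog: Sequence[Tuple[str, float]] = ()
    planted_pairs: Sequence[Tuple[str, str, float]] = ()
    weight_range: Tuple[float, float] = (55.0, 95.0)
    scr_noise_sd: float = 0.02
    horizon: float = 72.0
    uo_route_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if abs(sum(self.stage_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.stage_mix):
            raise ValueError("stage_mix must be non-negative and sum to 1")
        for code, prev in self.code_catalog:
            if not 0.0 < prev < 1.0:
                raise ValueError(f"prevalence of {code} must be in (0, 1)")
        if not 0.0 <= self.uo_route_fraction <= 1.0:
            raise ValueError("uo_route_fraction must be in [0, 1]")
        if self.horizon < 24:
            raise ValueError("horizon must be at least 24 hours")
        self._validate_planting()

    @property
    def p_aki(self) -> float:
        return 1.0 - self.stage_mix[0]

    def _marginal(self, item: str) -> float:
        if item == AKI_ITEM:
            return self.p_aki
        for code, prev in self.code_catalog:
            if code == item:
                return prev
        raise ValueError(f"planted item {item} is not in the code catalog")

    def _validate_planting(self) -> None:
        seconds = set()
        for item_a, item_b, lift in self.planted_pairs:
            if lift < 0:
                raise PlantingError(f"({item_a},{item_b}): lift must be >= 0")
            if item_b == AKI_ITEM:
                item_a, item_b = item_b, item_a
            if item_b == AKI_ITEM:
                raise PlantingError("cannot plant the AKI item against itself")
            if item_b in seconds:
                raise PlantingError(
                    f"item {item_b} is the conditioned element of two planted pairs"
                )
            seconds.add(item_b)
            p_a, p_b = self._marginal(item_a), self._marginal(item_b)
            p_ab = lift * p_a * p_b
            cells = (p_ab, p_a - p_ab, p_b - p_ab, 1 - p_a - p_b + p_ab)
            if any(c < -1e-12 or c > 1 + 1e-12 for c in cells):
                raise PlantingError(
                    f"planting ({item_a},{item_b}) at lift {lift} puts a 2x2 "
                    f"cell outside [0,1]: {cells}"
                )


@dataclass
class CohortBundle:
    patients: List[PatientRecord]
    truth_labels: Dict[str, int]
    truth_pairs: List[Tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient ids must be unique")
        missing = set(ids) - set(self.truth_labels)
        if missing:
            raise ValueError(f"truth_labels missing patients: {sorted(missing)[:5]}")


def _truncnorm(rng: np.random.Generator, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.zeros(size)
    return np.clip(rng.normal(0.0, sd, size), -2.5 * sd, 2.5 * sd)


def _scr_trajectory(
    rng: np.random.Generator, stage: int, cfg: SimConfig, via_uo: bool
) -> List[Tuple[float, float]]:
    baseline = rng.uniform(0.6, 1.2)
    times = np.arange(0.0, cfg.horizon + 1e-9, 6.0)
    values = np.full(times.shape, baseline)
    if stage >= 1 and not via_uo:
        factor = _STAGE_SCR_FACTOR[stage]
        candidates = times[(times >= 12.0) & (times <= cfg.horizon - 6.0)]
        onset = rng.choice(candidates) if len(candidates) else times[-1]
        values = np.where(times >= onset, factor * baseline, baseline)
    values = values + _truncnorm(rng, cfg.scr_noise_sd, len(times))
    values = np.maximum(values, 0.05)
    return list(zip(times.tolist(), values.tolist()))


def _uo_trajectory(
    rng: np.random.Generator, stage: int, cfg: SimConfig, via_uo: bool, weight: float
) -> List[Tuple[float, float]]:
    n_hours = int(cfg.horizon)
    rates = rng.uniform(0.9, 1.4) + rng.uniform(-0.1, 0.1, n_hours)
    rates = np.maximum(rates, 0.6)
    if stage >= 1 and via_uo:
        low_rate, dur = _STAGE_UO_EPISODE[stage]
        start = int(rng.integers(2, n_hours - dur - 1))
        rates[start : start + dur] = np.clip(
            low_rate + rng.uniform(-0.05, 0.05, dur), 0.05, low_rate + 0.05
        )
    volumes = rates * weight
    return [(float(h), float(v)) for h, v in enumerate(volumes)]


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Draw a cohort with planted stages and planted pair associations.

    Deterministic for a given seed: the root seed is split into per-patient
    substreams so patient i's data does not depend on how many patients
    precede it.
    """
    root = np.random.default_rng(config.seed)
    stages = root.choice(4, size=config.n_patients, p=list(config.stage_mix))
    streams = np.random.SeedSequence(config.seed).spawn(config.n_patients)

    planted = []
    for a, b, lift in config.planted_pairs:
        if b == AKI_ITEM:
            a, b = b, a
        planted.append((a, b, lift))
    planted_seconds = {b for _a, b, _l in planted}

    patients: List[PatientRecord] = []
    truth: Dict[str, int] = {}
    for i in range(config.n_patients):
        rng = np.random.default_rng(streams[i])
        pid = f"P{i:06d}"
        stage = int(stages[i])
        via_uo = (
            stage >= 1
            and rng.random() < config.uo_route_fraction
            and config.horizon >= _STAGE_UO_EPISODE[stage][1] + 4
        )
        weight = float(rng.uniform(*config.weight_range))

        # diagnosis itemset: planted pairs first (conditional draws), then
        # the independent remainder of the catalog
        present: Dict[str, bool] = {AKI_ITEM: stage >= 1}
        for a, b, lift in planted:
            if a not in present:
                present[a] = rng.random() < config._marginal(a)
            p_a, p_b = config._marginal(a), config._marginal(b)
            if present[a]:
                p_cond = min(lift * p_b, 1.0)
            else:
                p_cond = p_b * (1.0 - lift * p_a) / (1.0 - p_a)
            present[b] = rng.random() < p_cond
        codes = []
        for code, prev in config.code_catalog:
            if code in planted_seconds or code in present:
                keep = present.get(code, False)
            else:
                keep = rng.random() < prev
            if keep:
                codes.append((10, code))
        # planted first-elements not in the catalog (other than AKI)
        for a, _b, _l in planted:
            if a != AKI_ITEM and present.get(a) and all(c != a for _v, c in codes):
                codes.append((10, a))

        patients.append(
            PatientRecord(
                id=pid,
                sex=str(rng.choice(_SEXES)),
                age_years=float(rng.uniform(18, 95)),
                ethnicity=str(rng.choice(_ETHNICITIES)),
                weight_kg=weight,
                scr_series=_scr_trajectory(rng, stage, config, via_uo),
                uo_series=_uo_trajectory(rng, stage, config, via_uo, weight),
                codes=codes,
            )
        )
        truth[pid] = stage

    return CohortBundle(
        patients=patients,
        truth_labels=truth,
        truth_pairs=list(planted),
    )


_PATIENT_COLS = ["id", "sex", "age_years", "ethnicity", "weight_kg"]
_SCR_COLS = ["id", "time_hours", "scr_mg_dl"]
_UO_COLS = ["id", "time_hours", "volume_ml"]
_DX_COLS = ["id", "icd_version", "code"]


def write_cohort(bundle: CohortBundle, directory) -> List[Path]:
    """Write the four MIMIC-shaped CSV tables; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pats = pd.DataFrame(
        [
            {
                "id": p.id,
                "sex": p.sex,
                "age_years": p.age_years,
                "ethnicity": p.ethnicity,
                "weight_kg": p.weight_kg,
            }
            for p in bundle.patients
        ],
        columns=_PATIENT_COLS,
    )
    scr = pd.DataFrame(
        [
            {"id": p.id, "time_hours": t, "scr_mg_dl": v}
            for p in bundle.patients
            for t, v in p.scr_series
        ],
        columns=_SCR_COLS,
    )
    uo = pd.DataFrame(
        [
            {"id": p.id, "time_hours": t, "volume_ml": v}
            for p in bundle.patients
            for t, v in p.uo_series
        ],
        columns=_UO_COLS,
    )
    dx = pd.DataFrame(
        [
            {"id": p.id, "icd_version": ver, "code": code}
            for p in bundle.patients
            for ver, code in p.codes
        ],
        columns=_DX_COLS,
    )
    paths = []
    for name, frame in (
        ("patients.csv", pats),
        ("scr_events.csv", scr),
        ("uo_events.csv", uo),
        ("diagnoses.csv", dx),
    ):
        path = directory / name
        frame.to_csv(path, index=False)
        paths.append(path)
    return paths


def read_cohort(directory) -> List[PatientRecord]:
    """Read the four CSV tables back into patient records."""
    directory = Path(directory)
    for name in ("patients.csv", "scr_events.csv", "uo_events.csv", "diagnoses.csv"):
        if not (directory / name).exists():
            raise FileNotFoundError(f"missing cohort table: {directory / name}")
    pats = pd.read_csv(directory / "patients.csv", dtype={"id": str})
    scr = pd.read_csv(directory / "scr_events.csv", dtype={"id": str})
    uo = pd.read_csv(directory / "uo_events.csv", dtype={"id": str})
    dx = pd.read_csv(directory / "diagnoses.csv", dtype={"id": str, "code": str})

    scr_by = {pid: g for pid, g in scr.groupby("id")} if len(scr) else {}
    uo_by = {pid: g for pid, g in uo.groupby("id")} if len(uo) else {}
    dx_by = {pid: g for pid, g in dx.groupby("id")} if len(dx) else {}

    records = []
    for row in pats.itertuples(index=False):
        pid = row.id
        s = scr_by.get(pid)
        u = uo_by.get(pid)
        d = dx_by.get(pid)
        weight = None if pd.isna(row.weight_kg) else float(row.weight_kg)
        records.append(
            PatientRecord(
                id=pid,
                sex=row.sex,
                age_years=float(row.age_years),
                ethnicity=row.ethnicity,
                weight_kg=weight,
                scr_series=(
                    []
                    if s is None
                    else list(
                        zip(
                            s.sort_values("time_hours")["time_hours"].tolist(),
                            s.sort_values("time_hours")["scr_mg_dl"].tolist(),
                        )
                    )
                ),
                uo_series=(
                    []
                    if u is None
                    else list(
                        zip(
                            u.sort_values("time_hours")["time_hours"].tolist(),
                            u.sort_values("time_hours")["volume_ml"].tolist(),
                        )
                    )
                ),
                codes=(
                    []
                    if d is None
                    else [(int(v), c) for v, c in zip(d["icd_version"], d["code"])]
                ),
            )
        )
    return records
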