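"""Detect and stage acute kidney injury from creatinine and urine-output streams.

Staging follows the KDIGO consensus bands:

* serum creatinine (Scr, mg/dl): AKI when a value reaches >= 1.5x its
  baseline (rolling minimum over the preceding 7 days) or rises by
  >= 0.3 mg/dl relative to any value measured within the prior 48 h.
  Stage 1 for 1.5-1.9x baseline or the absolute-rise rule, stage 2 for
  2.0-2.9x, stage 3 for >= 3.0x or a qualifying rise reaching >= 4.0 mg/dl.
* urine output (Uo, ml/kg/h): stage 1 for < 0.5 sustained 6-12 h, stage 2
  for < 0.5 sustained >= 12 h, stage 3 for < 0.3 sustained >= 24 h or
  anuria >= 12 h.

A patient's stage is the worse of the two criteria.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

#: hours in the creatinine baseline look-back window (7 days)
BASELINE_WINDOW_H = 168.0
#: hours in the absolute-increase look-back window
ABS_WINDOW_H = 48.0
#: mg/dl absolute increase that qualifies as AKI within ABS_WINDOW_H
ABS_INCREASE = 0.3
#: mg/dl ceiling that upgrades a qualifying rise to stage 3
STAGE3_ABS_SCR = 4.0

#: ml/kg/h rate thresholds and sustained-hour requirements per stage
UO_RATE_STAGE12 = 0.5
UO_RATE_STAGE3 = 0.3
UO_HOURS_STAGE1 = 6
UO_HOURS_STAGE2 = 12
UO_HOURS_STAGE3 = 24
UO_HOURS_ANURIA = 12
#: charting gaps longer than this (hours) break a sustained episode
UO_MAX_GAP_H = 2


@dataclass
class PatientRecord:
    """One ICU stay: demographics plus the raw measurement streams.

    ``scr_series`` and ``uo_series`` are time-ordered ``(hours, value)``
    pairs; creatinine in mg/dl, urine output in ml per charting interval.
    ``codes`` holds ``(version, raw_code)`` diagnosis tuples.
    """

    id: str
    sex: str = "unknown"
    age_years: float = 18.0
    ethnicity: str = "unknown"
    weight_kg: Optional[float] = None
    scr_series: Sequence[Tuple[float, float]] = field(default_factory=list)
    uo_series: Sequence[Tuple[float, float]] = field(default_factory=list)
    codes: Sequence[Tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("scr_series", "uo_series"):
            series = getattr(self, name)
            times = [t for t, _ in series]
            if any(b < a for a, b in zip(times, times[1:])):
                raise ValueError(f"{name} times must be non-decreasing for {self.id}")
        if any(v <= 0 for _, v in self.scr_series):
            raise ValueError(f"scr values must be > 0 for {self.id}")
        if self.weight_kg is not None and not self.weight_kg > 0:
            raise ValueError(f"weight_kg must be positive for {self.id}")


@dataclass(frozen=True)
class AkiLabel:
    """Per-stay AKI verdict: flag, stage 0-3, onset and triggering stream."""

    id: str
    has_aki: bool
    stage: int
    onset_hours: Optional[float] = None
    criterion: Optional[str] = None  # "scr" | "uo" | "both"

    def __post_init__(self) -> None:
        if self.has_aki != (self.stage >= 1):
            raise ValueError("has_aki must match stage >= 1")
        if self.has_aki != (self.onset_hours is not None):
            raise ValueError("onset present iff has_aki")


def baseline_scr(scr_series: Sequence[Tuple[float, float]], t: float) -> float:
    """Baseline creatinine at time ``t``: minimum over the window ``(t-168h, t]``.

    Raises ``ValueError`` when no measurement falls at or before ``t``.
    """
    window = [v for (ti, v) in scr_series if t - BASELINE_WINDOW_H < ti <= t]
    if not window:
        raise ValueError(f"no creatinine measurement in ({t - BASELINE_WINDOW_H}, {t}]")
    return min(window)


def scr_stage(scr_series: Sequence[Tuple[float, float]]) -> Tuple[int, Optional[float]]:
    """Stage the creatinine stream; returns ``(stage, onset_hours)``.

    The stage is the highest band attained over the stay; onset is the time
    of the first measurement satisfying any AKI criterion.
    """
    if not scr_series:
        raise ValueError("empty creatinine series")
    stage = 0
    onset: Optional[float] = None
    for i, (t, v) in enumerate(scr_series):
        base = baseline_scr(scr_series, t)
        ratio = v / base
        abs_rise = any(
            v - v_prev >= ABS_INCREASE
            for (t_prev, v_prev) in scr_series[:i]
            if t - t_prev <= ABS_WINDOW_H
        )
        here = 0
        if ratio >= 3.0:
            here = 3
        elif ratio >= 2.0:
            here = 2
        elif ratio >= 1.5 or abs_rise:
            here = 1
        if here >= 1 and v >= STAGE3_ABS_SCR:
            here = 3
        if here >= 1 and onset is None:
            onset = t
        stage = max(stage, here)
    return stage, onset


def _hourly_bins(uo_series: Sequence[Tuple[float, float]]) -> dict[int, float]:
    bins: dict[int, float] = {}
    for t, vol in uo_series:
        h = math.floor(t)
        bins[h] = bins.get(h, 0.0) + vol
    return bins


def _episodes(hours: Sequence[int], low: Sequence[bool]) -> list[Tuple[int, int]]:
    """Maximal runs of qualifying hours; charting gaps <= UO_MAX_GAP_H are
    bridged, longer gaps (or a non-qualifying hour) end the episode.

    Returns ``(start_hour, duration)`` with duration spanning bridged gaps.
    """
    episodes: list[Tuple[int, int]] = []
    start: Optional[int] = None
    prev: Optional[int] = None
    for h, is_low in zip(hours, low):
        if is_low:
            if start is not None and prev is not None and h - prev - 1 > UO_MAX_GAP_H:
                episodes.append((start, prev + 1 - start))
                start = h
            elif start is None:
                start = h
            prev = h
        else:
            if start is not None and prev is not None:
                episodes.append((start, prev + 1 - start))
            start = None
    if start is not None and prev is not None:
        episodes.append((start, prev + 1 - start))
    return episodes


def uo_stage(
    uo_series: Sequence[Tuple[float, float]], weight_kg: float
) -> Tuple[int, Optional[float]]:
    """Stage the urine-output stream; returns ``(stage, onset_hours)``.

    Volumes are binned hourly; the hourly rate is volume / weight. An episode
    is a maximal run of hours below a rate threshold (gaps <= 2 h bridged).
    Onset is the hour at which the shortest qualifying episode completes.
    """
    if not weight_kg or weight_kg <= 0:
        raise ValueError("weight must be known and positive")
    bins = _hourly_bins(uo_series)
    if not bins:
        return 0, None
    hours = sorted(bins)
    rates = [bins[h] / weight_kg for h in hours]

    stage = 0
    onset: Optional[float] = None

    def consider(thresholds_low: Sequence[bool], min_hours: int, new_stage: int) -> None:
        nonlocal stage, onset
        for start, dur in _episodes(hours, thresholds_low):
            if dur >= min_hours:
                t_met = float(start + min_hours)
                if stage < new_stage:
                    stage = new_stage
                if onset is None or t_met < onset:
                    onset = t_met

    lt_05 = [r < UO_RATE_STAGE12 for r in rates]
    lt_03 = [r < UO_RATE_STAGE3 for r in rates]
    zero = [r == 0.0 for r in rates]
    consider(lt_05, UO_HOURS_STAGE1, 1)
    consider(lt_05, UO_HOURS_STAGE2, 2)
    consider(lt_03, UO_HOURS_STAGE3, 3)
    consider(zero, UO_HOURS_ANURIA, 3)
    return stage, onset


def stage_patient(patient: PatientRecord) -> AkiLabel:
    """Combine both criteria: stage = max(scr, uo); onset = earliest qualifying."""
    s_scr, onset_scr = (0, None)
    if patient.scr_series:
        s_scr, onset_scr = scr_stage(patient.scr_series)
    s_uo, onset_uo = (0, None)
    if patient.uo_series:
        if patient.weight_kg is None or patient.weight_kg <= 0:
            logger.warning(
                "patient %s: missing weight, urine-output criterion skipped", patient.id
            )
        else:
            s_uo, onset_uo = uo_stage(patient.uo_series, patient.weight_kg)
    if not patient.scr_series and not patient.uo_series:
        logger.warning("patient %s: no measurements, defaulting to stage 0", patient.id)

    stage = max(s_scr, s_uo)
    if stage == 0:
        return AkiLabel(id=patient.id, has_aki=False, stage=0)
    onsets = [o for o in (onset_scr, onset_uo) if o is not None]
    if s_scr == stage and s_uo == stage:
        criterion = "both"
    elif s_uo == stage:
        criterion = "uo"
    else:
        criterion = "scr"
    return AkiLabel(
        id=patient.id,
        has_aki=True,
        stage=stage,
        onset_hours=min(onsets),
        criterion=criterion,
    )
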