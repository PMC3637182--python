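"""Longitudinal disease-endpoint derivation for SOD1-type mouse studies.

Turns per-session observation records (weight, hindlimb tremor, extension
reflex, wire-hang latencies, righting time) into time-to-event endpoints:

* early symptom onset — tremor OR loss of hindlimb extension in two
  consecutive observations, dated to the first of the pair by default
  ("appearance" reads as first occurrence; the alternative dating is
  available via ``dating="second"``);
* weight-loss onset — first sustained drop of >= ``drop_fraction`` (default
  5%) below the running peak weight, "sustained" meaning the peak is never
  re-attained afterwards;
* last full wire hang — the greatest age at which the best of three trials
  still reaches the 60 s cap;
* humane-endpoint checks — righting failure (> 15 s) or >= 20% loss from
  peak weight;
* death-mode censoring classification for survival analysis;

plus the innervation-percentage aggregation for NMJ scoring and the dosing
arithmetic (20 ul volume bracketing, formulation powder weight).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

HANG_CAP_S = 60.0
RIGHTING_LIMIT_S = 15.0
WEIGHT_LOSS_CRITERION = 0.20


@dataclass
class ObservationRecord:
    mouse_id: str
    age_days: int
    weight_g: float
    tremor: bool = False
    extension_loss: bool = False
    hang_latencies_s: list[float] = field(default_factory=list)
    righting_s: float | None = None

    def __post_init__(self):
        if self.age_days < 0:
            raise ValueError("age_days must be >= 0")
        if self.weight_g <= 0:
            raise ValueError("weight_g must be > 0")
        for h in self.hang_latencies_s:
            if not 0 <= h <= HANG_CAP_S:
                raise ValueError(f"hang latency {h} outside [0, {HANG_CAP_S}]")


@dataclass
class MouseTimeline:
    mouse_id: str
    records: list[ObservationRecord]

    def __post_init__(self):
        ages = [r.age_days for r in self.records]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("record ages must be strictly increasing")

    @property
    def peak_weight_g(self) -> float:
        return max(r.weight_g for r in self.records)

    def running_peaks(self) -> list[float]:
        peaks, cur = [], -math.inf
        for r in self.records:
            cur = max(cur, r.weight_g)
            peaks.append(cur)
        return peaks


@dataclass
class EventResult:
    endpoint_name: str
    age_days: float
    observed: bool  # True = event, False = right-censored
    degenerate: bool = False  # boundary cases (e.g. never achieved a full hang)


class DeathMode(enum.Enum):
    RIGHTING_FAILURE = "righting_failure"
    WEIGHT_LOSS = "weight_loss"
    BOTH = "both"
    FOUND_DEAD_NOT_NEAR_CRITERIA = "found_dead_not_near_criteria"
    FOUND_DEAD_NEAR_CRITERIA = "found_dead_near_criteria"
    INJURY_EUTHANASIA = "injury_euthanasia"
    WEIGHT_ONLY_NO_OTHER_SIGNS = "weight_only_no_other_signs"


#: death modes treated as non-disease deaths (right-censored in survival analysis)
CENSORED_MODES = frozenset(
    {
        DeathMode.FOUND_DEAD_NOT_NEAR_CRITERIA,
        DeathMode.INJURY_EUTHANASIA,
        DeathMode.WEIGHT_ONLY_NO_OTHER_SIGNS,
    }
)


@dataclass
class DeathRecord:
    mouse_id: str
    age_days: float
    mode: DeathMode

    @property
    def censored(self) -> bool:
        return classify_death(self.mode)


@dataclass
class DosePlan:
    weight_g: float
    nominal_dose_mg_per_kg: float
    concentration_mg_per_ml: float
    exact_volume_ul: float
    bracket_volume_ul: float
    actual_dose_mg_per_kg: float


@dataclass
class InnervationResult:
    percent: float
    left_percent: float | None
    right_percent: float | None
    asymmetric: bool  # True when only one side could be scored


def best_of_three_hang(latencies: list[float]) -> float | None:
    """Maximal latency over up to three trials; ``None`` marks a missed session."""
    if not latencies:
        return None
    for h in latencies:
        if not 0 <= h <= HANG_CAP_S:
            raise ValueError(f"hang latency {h} outside [0, {HANG_CAP_S}]")
    return max(latencies)


def early_symptom_onset(timeline: MouseTimeline, dating: str = "first") -> EventResult:
    """Onset = tremor or extension loss in two consecutive observations.

    Dated to the first of the earliest positive pair (``dating="first"``,
    default) or to the confirming second observation (``dating="second"``).
    With no such pair the mouse is right-censored at its last observation.
    """
    if dating not in ("first", "second"):
        raise ValueError("dating must be 'first' or 'second'")
    recs = timeline.records
    if not recs:
        raise ValueError("timeline has no records")
    positive = [r.tremor or r.extension_loss for r in recs]
    for i in range(len(recs) - 1):
        if positive[i] and positive[i + 1]:
            idx = i if dating == "first" else i + 1
            return EventResult("early_symptom_onset", recs[idx].age_days, True)
    return EventResult("early_symptom_onset", recs[-1].age_days, False)


def weight_loss_onset(timeline: MouseTimeline, drop_fraction: float = 0.05) -> EventResult:
    """First sustained drop >= ``drop_fraction`` below the running peak.

    Sustained: no later weight re-attains the running peak current at the
    candidate observation, so transient dips followed by renewed growth are
    ignored and the search resumes after the later peak.
    """
    if not 0 < drop_fraction < 1:
        raise ValueError("drop_fraction must be in (0, 1)")
    recs = timeline.records
    if len(recs) < 2:
        return EventResult("weight_loss_onset", recs[-1].age_days, False)
    peaks = timeline.running_peaks()
    weights = [r.weight_g for r in recs]
    for i in range(1, len(recs)):
        if weights[i] <= (1 - drop_fraction) * peaks[i]:
            if all(w < peaks[i] for w in weights[i + 1 :]):
                return EventResult("weight_loss_onset", recs[i].age_days, True)
    return EventResult("weight_loss_onset", recs[-1].age_days, False)


def last_full_hang_age(timeline: MouseTimeline) -> EventResult:
    """Greatest age whose best-of-three hang reaches the 60 s cap.

    Still hanging the full 60 s at the final session -> right-censored there.
    Mice that never achieve a full hang get a flagged degenerate event at
    their first hang session.
    """
    sessions = [
        (r.age_days, best_of_three_hang(r.hang_latencies_s))
        for r in timeline.records
        if r.hang_latencies_s
    ]
    if not sessions:
        raise ValueError("timeline has no wire-hang data")
    full = [age for age, best in sessions if best is not None and best >= HANG_CAP_S]
    if not full:
        return EventResult("last_full_hang", sessions[0][0], True, degenerate=True)
    last_full = max(full)
    if last_full == sessions[-1][0]:
        return EventResult("last_full_hang", last_full, False)
    return EventResult("last_full_hang", last_full, True)


def euthanasia_due(
    record: ObservationRecord, peak_weight_g: float
) -> tuple[bool, str | None]:
    """Humane-endpoint check for one observation.

    Righting failure is strictly > 15 s; the weight criterion includes the
    20% boundary (weight <= 0.80 x peak). A missing righting measurement
    passes that criterion.
    """
    righting_fail = record.righting_s is not None and record.righting_s > RIGHTING_LIMIT_S
    weight_fail = record.weight_g <= (1 - WEIGHT_LOSS_CRITERION) * peak_weight_g
    if righting_fail and weight_fail:
        return True, "both"
    if righting_fail:
        return True, "righting_failure"
    if weight_fail:
        return True, "weight_loss"
    return False, None


def classify_death(mode: DeathMode) -> bool:
    """True if the death mode is censored (non-disease) in survival analysis."""
    if not isinstance(mode, DeathMode):
        raise TypeError(f"unknown death mode {mode!r}")
    return mode in CENSORED_MODES


def innervation_percent(
    scores_left: list[bool], scores_right: list[bool]
) -> InnervationResult:
    """Animal-level NMJ innervation: mean of the two per-side percentages
    (not pooled counts); falls back to the scored side if one is empty."""
    def side(scores):
        return 100.0 * sum(scores) / len(scores) if scores else None

    left, right = side(scores_left), side(scores_right)
    if left is None and right is None:
        raise ValueError("no scored synapses on either side")
    if left is None or right is None:
        val = left if left is not None else right
        return InnervationResult(val, left, right, asymmetric=True)
    return InnervationResult((left + right) / 2.0, left, right, asymmetric=False)


def dose_volume_bracketed(
    weight_g: float, nominal_mg_per_kg: float, conc_mg_per_ml: float = 10.0
) -> DosePlan:
    """Round the exact dosing volume to the nearest 20 ul (ties round up)
    and recompute the dose actually delivered."""
    if weight_g <= 0:
        raise ValueError("weight_g must be > 0")
    exact_ul = weight_g * nominal_mg_per_kg / conc_mg_per_ml
    bracket_ul = 20.0 * math.floor(exact_ul / 20.0 + 0.5)
    actual = bracket_ul * conc_mg_per_ml / weight_g
    return DosePlan(
        weight_g=weight_g,
        nominal_dose_mg_per_kg=nominal_mg_per_kg,
        concentration_mg_per_ml=conc_mg_per_ml,
        exact_volume_ul=exact_ul,
        bracket_volume_ul=bracket_ul,
        actual_dose_mg_per_kg=actual,
    )


def formulation_powder_weight(volume_ml: float, conc_mg_per_ml: float = 10.0,
                              salt_correction: float = 0.915) -> float:
    """Powder weight (mg) for a suspension at ``conc_mg_per_ml``, corrected
    for the salt factor to attain free-base equivalency: W = conc/0.915 x V."""
    if volume_ml <= 0:
        raise ValueError("volume_ml must be > 0")
    return conc_mg_per_ml / salt_correction * volume_ml


# --- cohort-level helpers over the timelines CSV schema -------------------

def timelines_from_frame(df) -> list[MouseTimeline]:
    """Build timelines from a long-format frame with columns
    mouse_id, age_days, weight_g, tremor, extension_loss,
    hang1_s..hang3_s, righting_s (the schema written by alsquant.cohort;
    the same schema is accepted for real data)."""
    out = []
    for mouse_id, grp in df.groupby("mouse_id", sort=True):
        grp = grp.sort_values("age_days")
        records = []
        for row in grp.itertuples(index=False):
            hangs = [
                getattr(row, c)
                for c in ("hang1_s", "hang2_s", "hang3_s")
                if hasattr(row, c) and getattr(row, c) == getattr(row, c)  # not NaN
            ]
            righting = getattr(row, "righting_s", None)
            if righting != righting:  # NaN
                righting = None
            records.append(
                ObservationRecord(
                    mouse_id=str(mouse_id),
                    age_days=int(row.age_days),
                    weight_g=float(row.weight_g),
                    tremor=bool(row.tremor),
                    extension_loss=bool(row.extension_loss),
                    hang_latencies_s=hangs,
                    righting_s=righting,
                )
            )
        out.append(MouseTimeline(mouse_id=str(mouse_id), records=records))
    return out


def derive_events(timelines: list[MouseTimeline], drop_fraction: float = 0.05,
                  dating: str = "first"):
    """All three behavioural endpoints for every mouse, as a tidy frame
    (mouse_id, endpoint, age_days, observed, degenerate)."""
    import pandas as pd

    rows = []
    for tl in timelines:
        results = [
            early_symptom_onset(tl, dating=dating),
            weight_loss_onset(tl, drop_fraction=drop_fraction),
        ]
        if any(r.hang_latencies_s for r in tl.records):
            results.append(last_full_hang_age(tl))
        for res in results:
            rows.append(
                {
                    "mouse_id": tl.mouse_id,
                    "endpoint": res.endpoint_name,
                    "age_days": res.age_days,
                    "observed": res.observed,
                    "degenerate": res.degenerate,
                }
            )
    return pd.DataFrame(rows)
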