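"""Validation harness: diary alignment, exclusion rules and validity metrics.

The gold standard is an observer diary: an ordered, gap-free sequence of
intervals labeled ON / OFF / INTERMEDIATE / UNDEFINED. Algorithm decisions
(episode fluencies) are labeled by the diary interval containing the
episode midpoint, after excluding:

* a ±5 min synchronisation margin around every motor-phase transition,
* episodes that straddle a transition,
* INTERMEDIATE intervals (no dichotomous gold standard exists for them),
* UNDEFINED intervals and timestamps with no gold standard at all.

Validity is sensitivity / specificity / PPV / NPV with **OFF as the
positive class**, computed per patient over repeated 20/80
calibration/evaluation splits (30 by default) and then summarised across
the cohort (mean, median, IQR). Two variants are reported: all walking
segments, and only segments with >= 10 strides.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from math import nan
from pathlib import Path

import numpy as np

from .calibration import OFF, ON, ThresholdCalibrator, make_split
from .errors import CalibrationInfeasibleError, DataError, DegenerateSeparationError
from .strides import EpisodeFluency

STATES = (ON, OFF, "INTERMEDIATE", "UNDEFINED")
DEFAULT_MARGIN_S = 300.0
DEFAULT_MIN_STRIDES = 10
DEFAULT_N_REPEATS = 30

DROP_REASONS = (
    "no_gold",
    "margin",
    "straddles_transition",
    "intermediate",
    "undefined",
    "no_fluency",
)


# ----------------------------------------------------------------------
# Diary


@dataclass(frozen=True)
class DiaryInterval:
    start_s: float
    end_s: float
    state: str


class DiaryTimeline:
    """Ordered, non-overlapping, gap-free labeled intervals."""

    def __init__(self, intervals: list[DiaryInterval]):
        if not intervals:
            raise DataError("diary must contain at least one interval")
        for iv in intervals:
            if iv.state not in STATES:
                raise DataError(f"unknown diary state {iv.state!r}")
            if iv.end_s <= iv.start_s:
                raise DataError(f"empty/negative diary interval {iv}")
        for a, b in zip(intervals, intervals[1:]):
            if abs(b.start_s - a.end_s) > 1e-6:
                raise DataError(
                    f"diary not gap-free: {a.end_s} -> {b.start_s}"
                )
        self.intervals = list(intervals)

    @property
    def span(self) -> tuple[float, float]:
        return self.intervals[0].start_s, self.intervals[-1].end_s

    def state_at(self, t: float) -> str | None:
        """State of the interval containing t (intervals half-open [start, end))."""
        lo, hi = self.span
        if t < lo or t >= hi:
            return None
        for iv in self.intervals:
            if iv.start_s <= t < iv.end_s:
                return iv.state
        return None

    def transitions(self) -> list[float]:
        """Boundary times between differing states."""
        return [
            b.start_s
            for a, b in zip(self.intervals, self.intervals[1:])
            if a.state != b.state
        ]

    def minutes_in_state(self, state: str) -> float:
        return sum(
            (iv.end_s - iv.start_s) for iv in self.intervals if iv.state == state
        ) / 60.0

    # ------------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "DiaryTimeline":
        intervals = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                intervals.append(
                    DiaryInterval(
                        float(row["start_s"]), float(row["end_s"]), row["state"]
                    )
                )
        return cls(intervals)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["start_s", "end_s", "state"])
            for iv in self.intervals:
                w.writerow([f"{iv.start_s:.3f}", f"{iv.end_s:.3f}", iv.state])


def transition_exclusion_mask(
    diary: DiaryTimeline, margin_s: float = DEFAULT_MARGIN_S
) -> list[tuple[float, float]]:
    """Union of [t - margin, t + margin] around every state transition."""
    raw = [(t - margin_s, t + margin_s) for t in diary.transitions()]
    return merge_intervals(raw)


def merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [tuple(m) for m in merged]


def _in_mask(t: float, mask: list[tuple[float, float]]) -> bool:
    return any(lo <= t <= hi for lo, hi in mask)


# ----------------------------------------------------------------------
# Decision labeling


@dataclass
class LabeledDecision:
    decision: EpisodeFluency
    label: str  # ON or OFF


@dataclass
class LabelingResult:
    labeled: list[LabeledDecision]
    dropped: dict[str, int]

    @property
    def n_scored(self) -> int:
        return len(self.labeled)

    @property
    def n_input(self) -> int:
        return self.n_scored + sum(self.dropped.values())


def label_decisions(
    decisions: list[EpisodeFluency],
    diary: DiaryTimeline,
    mask: list[tuple[float, float]] | None = None,
    margin_s: float = DEFAULT_MARGIN_S,
) -> LabelingResult:
    """Attach gold-standard labels; drop excluded decisions with a reason code.

    Checks are applied in a fixed order (no_fluency, no_gold, margin,
    straddle, interval state) so each dropped decision carries exactly one
    reason and the accounting identity n_input = n_scored + sum(drops)
    holds by construction.
    """
    if mask is None:
        mask = transition_exclusion_mask(diary, margin_s)
    transitions = diary.transitions()
    dropped = {r: 0 for r in DROP_REASONS}
    labeled: list[LabeledDecision] = []
    for d in decisions:
        if not d.has_decision:
            dropped["no_fluency"] += 1
            continue
        t = d.timestamp
        state = diary.state_at(t)
        if state is None:
            dropped["no_gold"] += 1
            continue
        if _in_mask(t, mask):
            dropped["margin"] += 1
            continue
        if any(d.start_time < tr < d.end_time for tr in transitions):
            dropped["straddles_transition"] += 1
            continue
        if state == "INTERMEDIATE":
            dropped["intermediate"] += 1
            continue
        if state == "UNDEFINED":
            dropped["undefined"] += 1
            continue
        labeled.append(LabeledDecision(decision=d, label=state))
    return LabelingResult(labeled=labeled, dropped=dropped)


def filter_min_strides(
    decisions: list[LabeledDecision], min_strides: int = DEFAULT_MIN_STRIDES
) -> list[LabeledDecision]:
    """Keep decisions from walking segments with >= min_strides strides."""
    return [d for d in decisions if d.decision.stride_count >= min_strides]


# ----------------------------------------------------------------------
# Metrics (OFF is the positive class)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv")


def _safe_div(num: int, den: int) -> float:
    return num / den if den else nan


def confusion_metrics(pred, truth) -> tuple[ConfusionCounts, MetricSet]:
    """Sensitivity/specificity/PPV/NPV with OFF positive; 0/0 -> NaN (undefined)."""
    pred = np.asarray(pred).astype(str)
    truth = np.asarray(truth).astype(str)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth length mismatch")
    cc = ConfusionCounts(
        tp=int(np.sum((pred == OFF) & (truth == OFF))),
        fp=int(np.sum((pred == OFF) & (truth == ON))),
        tn=int(np.sum((pred == ON) & (truth == ON))),
        fn=int(np.sum((pred == ON) & (truth == OFF))),
    )
    metrics = MetricSet(
        sensitivity=_safe_div(cc.tp, cc.tp + cc.fn),
        specificity=_safe_div(cc.tn, cc.tn + cc.fp),
        ppv=_safe_div(cc.tp, cc.tp + cc.fp),
        npv=_safe_div(cc.tn, cc.tn + cc.fn),
    )
    return cc, metrics


def render_metric(value: float, precision: int = 2) -> str:
    """Undefined metrics render as a dash, as in clinical validity tables."""
    return "-" if not np.isfinite(value) else f"{value:.{precision}f}"


# ----------------------------------------------------------------------
# Repeated-split validation protocol


@dataclass
class PatientValidation:
    patient_id: str
    n_on: int
    n_off: int
    minutes_on_diary: float
    minutes_off_diary: float
    minutes_on_scored: float
    minutes_off_scored: float
    mean: dict = field(default_factory=dict)  # metric -> mean over repeats
    sd: dict = field(default_factory=dict)


@dataclass
class VariantReport:
    variant: str
    per_patient: list[PatientValidation]
    excluded: list[str]
    cohort: dict = field(default_factory=dict)  # metric -> {mean, median, iqr}


@dataclass
class ValidationReport:
    n_repeats: int
    base_seed: int
    min_strides: int
    variants: dict[str, VariantReport] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(v):
            return None if (isinstance(v, float) and not np.isfinite(v)) else v

        out = {
            "n_repeats": self.n_repeats,
            "base_seed": self.base_seed,
            "min_strides": self.min_strides,
            "iqr_convention": "linear-interpolation quantiles (type 7)",
            "variants": {},
        }
        for name, var in self.variants.items():
            out["variants"][name] = {
                "excluded_patients": var.excluded,
                "cohort": {
                    m: {k: _clean(v) for k, v in s.items()}
                    for m, s in var.cohort.items()
                },
                "per_patient": [
                    {
                        "patient_id": p.patient_id,
                        "n_segments_on": p.n_on,
                        "n_segments_off": p.n_off,
                        "minutes_on_diary": p.minutes_on_diary,
                        "minutes_off_diary": p.minutes_off_diary,
                        "minutes_on_scored": p.minutes_on_scored,
                        "minutes_off_scored": p.minutes_off_scored,
                        "metrics": {
                            m: {
                                "mean": _clean(p.mean[m]),
                                "sd": _clean(p.sd[m]),
                                "rendered": render_metric(p.mean[m]),
                            }
                            for m in METRIC_NAMES
                        },
                    }
                    for p in var.per_patient
                ],
            }
        return out


def _scored_minutes(decisions: list[LabeledDecision], label: str) -> float:
    return sum(
        d.decision.end_time - d.decision.start_time
        for d in decisions
        if d.label == label
    ) / 60.0


def _validate_patient(
    patient_id: str,
    decisions: list[LabeledDecision],
    diary: DiaryTimeline,
    n_repeats: int,
    base_seed: int,
    fraction: float,
) -> PatientValidation:
    """Repeat split -> threshold -> classify -> metrics; mean (SD) over repeats.

    Raises CalibrationInfeasibleError when a class has < 2 decisions.
    """
    values = np.array([d.decision.mean_fluency for d in decisions])
    labels = np.array([d.label for d in decisions])
    per_repeat = {m: [] for m in METRIC_NAMES}
    for r in range(1, n_repeats + 1):
        seed = base_seed + r
        plan = make_split(labels, fraction=fraction, seed=seed, repeat_index=r)
        try:
            cal = ThresholdCalibrator(random_state=seed).fit(
                values[plan.calibration_idx], labels[plan.calibration_idx]
            )
            theta = cal.theta_
        except DegenerateSeparationError as exc:
            theta = exc.theta
        pred = np.where(values[plan.evaluation_idx] > theta, ON, OFF)
        _, metrics = confusion_metrics(pred, labels[plan.evaluation_idx])
        for m in METRIC_NAMES:
            per_repeat[m].append(getattr(metrics, m))

    mean, sd = {}, {}
    for m in METRIC_NAMES:
        arr = np.array(per_repeat[m])
        finite = arr[np.isfinite(arr)]
        mean[m] = float(finite.mean()) if finite.size else nan
        sd[m] = float(finite.std(ddof=0)) if finite.size else nan
    return PatientValidation(
        patient_id=patient_id,
        n_on=int(np.sum(labels == ON)),
        n_off=int(np.sum(labels == OFF)),
        minutes_on_diary=diary.minutes_in_state(ON),
        minutes_off_diary=diary.minutes_in_state(OFF),
        minutes_on_scored=_scored_minutes(decisions, ON),
        minutes_off_scored=_scored_minutes(decisions, OFF),
        mean=mean,
        sd=sd,
    )


def _cohort_summary(per_patient: list[PatientValidation]) -> dict:
    cohort = {}
    for m in METRIC_NAMES:
        vals = np.array([p.mean[m] for p in per_patient])
        vals = vals[np.isfinite(vals)]  # undefined excluded pairwise
        if vals.size:
            cohort[m] = {
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "iqr": [float(np.percentile(vals, 25)), float(np.percentile(vals, 75))],
                "n_patients": int(vals.size),
            }
        else:
            cohort[m] = {"mean": nan, "median": nan, "iqr": [nan, nan], "n_patients": 0}
    return cohort


def run_validation(
    patients: dict[str, tuple[list[LabeledDecision], DiaryTimeline]],
    n_repeats: int = DEFAULT_N_REPEATS,
    base_seed: int = 0,
    fraction: float = 0.2,
    min_strides: int = DEFAULT_MIN_STRIDES,
) -> ValidationReport:
    """Full protocol over a cohort, for both segment-length variants.

    ``patients`` maps patient id to (labeled decision stream, diary).
    Patients whose calibration split is infeasible in a variant are listed
    as excluded for that variant.
    """
    report = ValidationReport(
        n_repeats=n_repeats, base_seed=base_seed, min_strides=min_strides
    )
    variants = {
        "all_segments": lambda d: d,
        "min_strides": lambda d: filter_min_strides(d, min_strides),
    }
    for name, select in variants.items():
        per_patient, excluded = [], []
        for pid, (decisions, diary) in patients.items():
            subset = select(decisions)
            try:
                per_patient.append(
                    _validate_patient(
                        pid, subset, diary, n_repeats, base_seed, fraction
                    )
                )
            except CalibrationInfeasibleError:
                excluded.append(pid)
        report.variants[name] = VariantReport(
            variant=name,
            per_patient=per_patient,
            excluded=excluded,
            cohort=_cohort_summary(per_patient),
        )
    return report


def mean_output_interval_min(decisions: list[EpisodeFluency]) -> float:
    """Mean time between successive algorithm outputs, in minutes."""
    times = sorted(d.timestamp for d in decisions if d.has_decision)
    if len(times) < 2:
        return nan
    return float(np.mean(np.diff(times)) / 60.0)
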