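"""Patient-specific ON/OFF threshold calibration (Phase 4, threshold side).

The episode fluency is a scalar, so the "splitting hyperplane" of a
linear-kernel maximum-margin SVM trained on a calibration subset is itself
a scalar: the patient's threshold theta. Episodes with mean fluency above
theta are ON, at or below theta OFF.

Calibration data are a stratified random 20% of a patient's labeled ON/OFF
decisions; the split is repeated (30 times in the validation protocol) to
average out selection effects. The SVM's C is chosen by cross-validated
accuracy with 10 folds when both classes have at least 10 patterns, else 2
folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import CalibrationInfeasibleError, DegenerateSeparationError

DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))

ON, OFF = "ON", "OFF"


@dataclass
class SplitPlan:
    """One stratified 20/80 calibration/evaluation split."""

    repeat_index: int
    fraction: float
    calibration_idx: np.ndarray
    evaluation_idx: np.ndarray
    seed: int


@dataclass
class PatientThreshold:
    patient_id: str
    theta: float
    cv_folds_used: int
    calibration_size: dict = field(default_factory=dict)
    seed: int = 0


def make_split(
    labels, fraction: float = 0.2, seed: int = 0, repeat_index: int = 0
) -> SplitPlan:
    """Stratified random calibration split: ceil(fraction · n_class) per class.

    Raises CalibrationInfeasibleError when either class has fewer than two
    decisions — the patient cannot enter the validation protocol.
    """
    y = np.asarray(labels)
    if y.size == 0:
        raise CalibrationInfeasibleError("no labeled decisions")
    cal_parts = []
    for cls in (OFF, ON):
        idx = np.flatnonzero(y == cls)
        if idx.size < 2:
            raise CalibrationInfeasibleError(
                f"class {cls} has {idx.size} decisions (<2); patient excluded"
            )
        rng = np.random.default_rng(seed + (0 if cls == OFF else 1))
        take = ceil(fraction * idx.size)
        cal_parts.append(rng.permutation(idx)[:take])
    cal = np.sort(np.concatenate(cal_parts))
    mask = np.zeros(y.size, dtype=bool)
    mask[cal] = True
    return SplitPlan(
        repeat_index=repeat_index,
        fraction=fraction,
        calibration_idx=cal,
        evaluation_idx=np.flatnonzero(~mask),
        seed=seed,
    )


class ThresholdCalibrator(BaseEstimator, ClassifierMixin):
    """1-D linear-SVM threshold between ON and OFF episode fluencies.

    fit(X, y) accepts fluency scalars (n,) or (n, 1) and string labels
    "ON"/"OFF". The fitted ``theta_`` is the zero-crossing of the SVM
    decision function; ``predict`` applies the fixed clinical rule
    fluency > theta -> ON, else OFF.

    Attributes
    ----------
    theta_ : float
    cv_folds_used_ : 10 when both classes have >= 10 patterns, else 2;
        0 when a class has a single pattern (no CV possible, default C).
    C_ : selected regularization.
    classes_ : array(["OFF", "ON"])
    """

    def __init__(
        self,
        C_grid=DEFAULT_C_GRID,
        class_weight="balanced",
        random_state: int = 0,
    ):
        self.C_grid = C_grid
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y).astype(str)
        if x.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        labels = set(np.unique(y))
        if labels != {ON, OFF}:
            raise ValueError(f"need both ON and OFF in calibration data, got {labels}")
        if np.unique(x).size == 1:
            raise DegenerateSeparationError(
                "all calibration fluencies identical; no separating margin",
                theta=float(x[0]),
            )
        n_min = min(int(np.sum(y == ON)), int(np.sum(y == OFF)))
        yb = (y == ON).astype(int)

        if n_min >= 2:
            folds = 10 if n_min >= 10 else 2
            cv = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=self.random_state
            )
            search = GridSearchCV(
                SVC(kernel="linear", class_weight=self.class_weight),
                {"C": list(self.C_grid)},
                scoring="accuracy",
                cv=cv,
            )
            search.fit(x[:, None], yb)
            svc: SVC = search.best_estimator_
            best_C = float(search.best_params_["C"])
        else:
            # a single pattern in a class cannot be cross-validated; fit the
            # max-margin separator at default regularization
            folds = 0
            best_C = 1.0
            svc = SVC(kernel="linear", C=best_C, class_weight=self.class_weight)
            svc.fit(x[:, None], yb)
        w = float(svc.coef_[0, 0])
        b = float(svc.intercept_[0])
        if w == 0.0:
            # no usable direction (pathological); fall back to class-mean midpoint
            theta = 0.5 * (x[yb == 1].mean() + x[yb == 0].mean())
        else:
            theta = -b / w
        self.theta_ = float(theta)
        self.C_ = best_C
        self.cv_folds_used_ = folds  # 0 = CV skipped (singleton class)
        self.classes_ = np.array([OFF, ON])
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "theta_")
        x = np.asarray(X, dtype=float).reshape(-1)
        return np.where(x > self.theta_, ON, OFF)


def fit_threshold(
    fluencies, labels, patient_id: str = "", seed: int = 0
) -> PatientThreshold:
    """Fit a patient threshold; wrapper around ThresholdCalibrator."""
    cal = ThresholdCalibrator(random_state=seed).fit(fluencies, labels)
    y = np.asarray(labels).astype(str)
    return PatientThreshold(
        patient_id=patient_id,
        theta=cal.theta_,
        cv_folds_used=cal.cv_folds_used_,
        calibration_size={
            ON: int(np.sum(y == ON)),
            OFF: int(np.sum(y == OFF)),
        },
        seed=seed,
    )


def classify_motor_state(mean_fluency: float, thr: PatientThreshold) -> str | None:
    """ON iff fluency strictly exceeds theta; equal-or-lower is OFF.

    Undefined (NaN) fluency emits no decision (returns None).
    """
    if not np.isfinite(mean_fluency):
        return None
    return ON if mean_fluency > thr.theta else OFF
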