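"""Walking detection (Phase 1): band-power features + RBF-SVM window classifier.

Each 3.2 s window is summarised by the axis-summed spectral power in two
frequency bands ([0.1, 3] Hz and [0.1, 10] Hz by default) and classified as
walking / not-walking by a support vector machine with a radial basis
function kernel whose C and gamma are chosen by stratified 10-fold
cross-validation. Consecutive walking windows form walking episodes.

The band pair itself was originally selected from all 19,900 ordered pairs
over the 0.1 Hz grid up to 20 Hz with a ReliefF feature ranking; that
selection procedure is reproduced here (`enumerate_band_candidates`,
`relieff_rank`) as an offline tool, while the runtime classifier ships with
the two fixed bands.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .recording import AccelerometerRecording
from .spectral import (
    PHASE1_BANDS,
    AnalysisWindow,
    FrequencyBand,
    WindowingConfig,
    segment_windows,
    window_feature_matrix,
)

DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-15, 4, 2))


# ----------------------------------------------------------------------
# Band candidate enumeration (offline band-selection tool)


@dataclass(frozen=True)
class BandCandidateSet:
    grid: tuple[float, ...]
    candidates: tuple[FrequencyBand, ...]

    def __len__(self):
        return len(self.candidates)


def enumerate_band_candidates(
    grid_step: float = 0.1, max_hz: float = 20.0
) -> BandCandidateSet:
    """All ordered band pairs (b1 < b2) on the regular grid {step, 2·step, …, max}.

    The default grid has 200 values and therefore C(200, 2) = 19,900
    candidates, in lexicographic order.
    """
    n = max_hz / grid_step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"grid step {grid_step} does not divide max {max_hz}")
    n = int(round(n))
    grid = tuple(round(grid_step * i, 10) for i in range(1, n + 1))
    candidates = tuple(
        FrequencyBand(grid[i], grid[j])
        for i in range(len(grid))
        for j in range(i + 1, len(grid))
    )
    return BandCandidateSet(grid=grid, candidates=candidates)


# ----------------------------------------------------------------------
# ReliefF


def relieff_rank(
    features: np.ndarray, labels: np.ndarray, k_neighbors: int = 10
) -> np.ndarray:
    """Deterministic ReliefF weights for binary-labeled feature vectors.

    Features are min–max scaled to [0, 1]; every instance serves as an
    anchor; distances are Manhattan on the scaled features; for each anchor
    the k nearest same-class (hits) and other-class (misses) neighbours
    contribute their per-feature absolute differences, misses positively
    and hits negatively, averaged over anchors and neighbours. Higher
    weight = more class-discriminative feature.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("ReliefF requires exactly two classes present")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if k_neighbors >= min(counts.values()):
        raise ValueError(
            f"k_neighbors={k_neighbors} must be smaller than the smallest "
            f"class size {min(counts.values())}"
        )

    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Xs = (X - lo) / span

    n = Xs.shape[0]
    D = cdist(Xs, Xs, metric="cityblock")
    np.fill_diagonal(D, np.inf)

    W = np.zeros(Xs.shape[1])
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        hits = same[np.argsort(D[i, same], kind="stable")[:k_neighbors]]
        misses = other[np.argsort(D[i, other], kind="stable")[:k_neighbors]]
        W += np.abs(Xs[misses] - Xs[i]).mean(axis=0)
        W -= np.abs(Xs[hits] - Xs[i]).mean(axis=0)
    return W / n


# ----------------------------------------------------------------------
# Window classifier


class WalkingWindowClassifier(BaseEstimator, ClassifierMixin):
    """RBF-SVM walking / not-walking classifier over band-power features.

    Parameters
    ----------
    bands : tuple of FrequencyBand
        Bands whose powers form the feature vector (informational; the
        estimator itself consumes a precomputed feature matrix).
    C_grid, gamma_grid : sequences of positive floats
        Hyperparameter grids searched by stratified cross-validated
        accuracy.
    cv_folds : int, default 10
    class_weight : passed to the underlying SVC ("balanced" by default —
        rest dominates daily recordings).
    random_state : int, fold shuffling seed.

    Attributes
    ----------
    C_, gamma_ : selected hyperparameters.
    cv_accuracy_ : best mean cross-validated accuracy.
    support_vectors_, dual_coef_, intercept_ : fitted decision function.
    classes_ : array([0, 1]) — 1 is walking.

    Notes
    -----
    Prediction evaluates the RBF decision function directly from the stored
    support vectors, with ties at the boundary resolved to not-walking
    (conservative: avoids spurious strides).
    """

    def __init__(
        self,
        bands=PHASE1_BANDS,
        C_grid=DEFAULT_C_GRID,
        gamma_grid=DEFAULT_GAMMA_GRID,
        cv_folds: int = 10,
        class_weight="balanced",
        random_state: int = 0,
    ):
        self.bands = bands
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.cv_folds = cv_folds
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, p) with matching labels")
        if not set(np.unique(y)) <= {0, 1} or np.unique(y).size < 2:
            raise ValueError("labels must contain both classes 0 and 1")
        if min(np.sum(y == 0), np.sum(y == 1)) < self.cv_folds:
            raise ValueError(
                f"need at least cv_folds={self.cv_folds} examples per class"
            )
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")

        cv = StratifiedKFold(
            n_splits=self.cv_folds, shuffle=True, random_state=self.random_state
        )
        search = GridSearchCV(
            SVC(kernel="rbf", class_weight=self.class_weight),
            {"C": list(self.C_grid), "gamma": list(self.gamma_grid)},
            scoring="accuracy",
            cv=cv,
        )
        search.fit(X, y)
        svc: SVC = search.best_estimator_
        self.C_ = float(search.best_params_["C"])
        self.gamma_ = float(search.best_params_["gamma"])
        self.cv_accuracy_ = float(search.best_score_)
        self.support_vectors_ = np.asarray(svc.support_vectors_, dtype=float)
        self.dual_coef_ = np.asarray(svc.dual_coef_[0], dtype=float)
        self.intercept_ = float(svc.intercept_[0])
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "support_vectors_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        K = np.exp(-self.gamma_ * cdist(X, self.support_vectors_, "sqeuclidean"))
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        # strictly positive margin -> walking; boundary ties -> not-walking
        return (self.decision_function(X) > 0).astype(int)

    # -------------------------------------------------- serialization
    def to_json(self, path: str | Path | None = None) -> str:
        check_is_fitted(self, "support_vectors_")
        payload = {
            "format": "gaitfluct-walking-model",
            "version": 1,
            "bands": [[b.lo, b.hi] for b in self.bands],
            "C": self.C_,
            "gamma": self.gamma_,
            "cv_accuracy": self.cv_accuracy_,
            "support_vectors": self.support_vectors_.tolist(),
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "cv_folds": self.cv_folds,
            "random_state": self.random_state,
        }
        body = json.dumps(payload, sort_keys=True)
        doc = json.dumps(
            {"checksum": hashlib.sha256(body.encode()).hexdigest(), "model": payload},
            indent=1,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "WalkingWindowClassifier":
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        doc = json.loads(text)
        payload = doc["model"]
        body = json.dumps(payload, sort_keys=True)
        if hashlib.sha256(body.encode()).hexdigest() != doc["checksum"]:
            raise ValueError("walking model checksum mismatch")
        model = cls(
            bands=tuple(FrequencyBand(lo, hi) for lo, hi in payload["bands"]),
            cv_folds=payload["cv_folds"],
            random_state=payload["random_state"],
        )
        model.C_ = payload["C"]
        model.gamma_ = payload["gamma"]
        model.cv_accuracy_ = payload["cv_accuracy"]
        model.support_vectors_ = np.asarray(payload["support_vectors"], dtype=float)
        model.dual_coef_ = np.asarray(payload["dual_coef"], dtype=float)
        model.intercept_ = float(payload["intercept"])
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = model.support_vectors_.shape[1]
        return model


def train_walking_model(
    windows: list[AnalysisWindow],
    labels,
    *,
    bands=PHASE1_BANDS,
    rate_hz: float = 40.0,
    **kwargs,
) -> WalkingWindowClassifier:
    """Convenience wrapper: featurize labeled windows and fit the classifier."""
    X = window_feature_matrix(windows, bands, rate_hz)
    model = WalkingWindowClassifier(bands=bands, **kwargs)
    return model.fit(X, np.asarray(labels))


# ----------------------------------------------------------------------
# Episode assembly


@dataclass
class WalkingEpisode:
    """A maximal run of consecutive windows classified as walking."""

    episode_id: int
    first_window: int
    last_window: int  # inclusive
    start_time: float
    end_time: float

    @property
    def n_windows(self) -> int:
        return self.last_window - self.first_window + 1

    @property
    def window_indices(self) -> range:
        return range(self.first_window, self.last_window + 1)


def episodes_from_labels(
    labels: np.ndarray, cfg: WindowingConfig | None = None
) -> list[WalkingEpisode]:
    """Group consecutive walking-labeled windows into maximal episodes."""
    cfg = cfg or WindowingConfig()
    labels = np.asarray(labels).astype(bool)
    episodes: list[WalkingEpisode] = []
    start = None
    for i, lab in enumerate(labels):
        if lab and start is None:
            start = i
        elif not lab and start is not None:
            episodes.append(_make_episode(len(episodes), start, i - 1, cfg))
            start = None
    if start is not None:
        episodes.append(_make_episode(len(episodes), start, len(labels) - 1, cfg))
    return episodes


def _make_episode(eid, first, last, cfg: WindowingConfig) -> WalkingEpisode:
    return WalkingEpisode(
        episode_id=eid,
        first_window=first,
        last_window=last,
        start_time=first * cfg.window_seconds,
        end_time=(last + 1) * cfg.window_seconds,
    )


def detect_walking(
    rec40: AccelerometerRecording,
    model: WalkingWindowClassifier,
    cfg: WindowingConfig | None = None,
):
    """Classify every window of an analysis-rate recording; assemble episodes.

    Returns ``(labels, episodes, windows)``.
    """
    cfg = cfg or WindowingConfig()
    windows = segment_windows(rec40, cfg)
    if not windows:
        return np.zeros(0, dtype=int), [], []
    X = window_feature_matrix(windows, model.bands, cfg.analysis_rate_hz)
    labels = model.predict(X)
    return labels, episodes_from_labels(labels, cfg), windows
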