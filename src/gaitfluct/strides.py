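"""Stride segmentation and spectral fluency (Phases 2–4, detection side).

Within each walking episode the forward trunk acceleration shows a relative
maximum at every initial contact (heel strike) — the Zijlstra–Hof
observation for lumbar-worn sensors. Because a waist sensor sees the
contacts of both feet, a stride (same foot to same foot) spans two
consecutive contact events: stride k runs from event 2k to event 2k+2.

Gait initiation/termination transients are removed twice, as in the source
protocol: the first and last window of an episode are excluded before
contact detection, and the first two and last two strides are excluded from
the episode average.

Each stride is scored by the axis-summed spectral power of its samples in
[0.1, 10] Hz (duration-normalised, g^2): the "fluency", higher in ON.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .spectral import (
    FLUENCY_BAND,
    FrequencyBand,
    WindowingConfig,
    band_power,
    periodogram_bins,
)
from .walking import BandCandidateSet, WalkingEpisode

_FREQ_TOL = 1e-9

#: Physiological floor on step period: max cadence ≈ 2.9 steps/s.
DEFAULT_MIN_SEPARATION_S = 0.35
DEFAULT_MIN_PROMINENCE_G = 0.05
#: Plausible stride (two-step) duration bounds in seconds.
STRIDE_DURATION_BOUNDS = (0.5, 4.0)
#: Strides needed before the 2+2 boundary exclusion leaves anything to average.
MIN_STRIDES_FOR_DECISION = 5


@dataclass(frozen=True)
class PeakParams:
    min_separation_s: float = DEFAULT_MIN_SEPARATION_S
    min_prominence_g: float = DEFAULT_MIN_PROMINENCE_G


@dataclass
class InitialContactEvent:
    sample_index: int  # at the analysis rate, absolute within the recording
    time: float
    amplitude: float


@dataclass
class Stride:
    start_index: int
    end_index: int  # half-open [start, end)
    samples: np.ndarray  # (end-start, 3)
    fluency: float | None = None

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


@dataclass
class EpisodeFluency:
    """One algorithm output: the averaged fluency of a walking episode.

    ``stride_count`` is the pre-exclusion stride count (used by the
    ≥10-stride filter); ``mean_fluency`` is NaN when fewer than
    ``MIN_STRIDES_FOR_DECISION`` strides were found. ``timestamp`` is the
    episode midpoint, the single instant used for diary lookup.
    """

    episode_id: int
    stride_count: int
    mean_fluency: float
    start_time: float
    end_time: float

    @property
    def timestamp(self) -> float:
        return 0.5 * (self.start_time + self.end_time)

    @property
    def has_decision(self) -> bool:
        return np.isfinite(self.mean_fluency)


# ----------------------------------------------------------------------


def trim_episode_boundaries(
    ep: WalkingEpisode, cfg: WindowingConfig | None = None
) -> tuple[int, int]:
    """Sample range (half-open, analysis rate) of the episode interior.

    The first and last window are dropped as gait initiation/termination;
    episodes of fewer than three windows have no interior.
    """
    cfg = cfg or WindowingConfig()
    w = cfg.window_samples
    if ep.n_windows < 3:
        return (0, 0)
    return ((ep.first_window + 1) * w, ep.last_window * w)


def detect_initial_contacts(
    forward_signal: np.ndarray,
    rate_hz: float = 40.0,
    params: PeakParams | None = None,
    offset_index: int = 0,
) -> list[InitialContactEvent]:
    """Relative maxima of the forward acceleration = initial contact events.

    ``offset_index`` anchors indices/times to the full recording when the
    signal is an episode slice.
    """
    params = params or PeakParams()
    x = np.asarray(forward_signal, dtype=float)
    if x.size == 0:
        return []
    distance = max(1, int(round(params.min_separation_s * rate_hz)))
    peaks, _ = find_peaks(x, distance=distance, prominence=params.min_prominence_g)
    return [
        InitialContactEvent(
            sample_index=offset_index + int(p),
            time=(offset_index + int(p)) / rate_hz,
            amplitude=float(x[p]),
        )
        for p in peaks
    ]


def build_strides(
    events: list[InitialContactEvent],
    signal: np.ndarray,
    rate_hz: float = 40.0,
    offset_index: int = 0,
    duration_bounds: tuple[float, float] = STRIDE_DURATION_BOUNDS,
) -> list[Stride]:
    """Pair contact events two-by-two into strides (event i to event i+2).

    ``signal`` is the 3-axis segment the event indices refer to, offset by
    ``offset_index``. Strides whose duration falls outside
    ``duration_bounds`` are discarded.
    """
    if len(events) < 3:
        return []
    lo, hi = duration_bounds
    strides = []
    for i in range(0, len(events) - 2, 2):
        a, b = events[i].sample_index, events[i + 2].sample_index
        duration = (b - a) / rate_hz
        if not (lo <= duration <= hi):
            continue
        seg = signal[a - offset_index : b - offset_index]
        strides.append(Stride(start_index=a, end_index=b, samples=np.asarray(seg)))
    return strides


def stride_fluency(
    stride: Stride,
    rate_hz: float = 40.0,
    band: FrequencyBand = FLUENCY_BAND,
) -> float | None:
    """Spectral fluency of one stride; None (stride dropped) if too short."""
    if stride.n_samples < 8:
        stride.fluency = None
        return None
    val = band_power(stride.samples, band, rate_hz)
    stride.fluency = val
    return val


def episode_fluency(
    strides: list[Stride],
    episode: WalkingEpisode,
    rate_hz: float = 40.0,
    band: FrequencyBand = FLUENCY_BAND,
) -> EpisodeFluency:
    """Average stride fluency, disregarding the two initial and two final strides."""
    values = [stride_fluency(s, rate_hz, band) for s in strides]
    values = [v for v in values if v is not None]
    count = len(values)
    if count >= MIN_STRIDES_FOR_DECISION:
        mean = float(np.mean(values[2:-2]))
    else:
        mean = float("nan")
    return EpisodeFluency(
        episode_id=episode.episode_id,
        stride_count=count,
        mean_fluency=mean,
        start_time=episode.start_time,
        end_time=episode.end_time,
    )


# ----------------------------------------------------------------------
# Offline band search (Phase 3 selection): which band maximises ON/OFF AUROC


@dataclass
class BandSearchResult:
    best_band: FrequencyBand
    best_auc: float
    aucs: np.ndarray  # aligned with candidates.candidates


def _rank_auc(scores: np.ndarray, positive: np.ndarray) -> np.ndarray:
    """Column-wise AUROC by the average-rank Mann–Whitney statistic."""
    from scipy.stats import rankdata

    ranks = rankdata(scores, axis=0)
    n_pos = int(positive.sum())
    n_neg = scores.shape[0] - n_pos
    r_pos = ranks[positive].sum(axis=0)
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def auc_band_search(
    stride_samples: list[np.ndarray],
    labels,
    candidates: BandCandidateSet,
    rate_hz: float = 40.0,
) -> BandSearchResult:
    """AUROC of single-band stride power as an ON score, for every candidate band.

    The per-stride periodogram is computed once; each candidate band's power
    is a prefix-sum difference over that stride's own frequency grid, so the
    full 19,900-band sweep stays cheap. Ties in the argmax break
    lexicographically (first candidate in enumeration order wins).
    """
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("band search requires both ON and OFF strides")
    positive = y == "ON" if "ON" in classes.astype(str) else y == classes.max()

    b1 = np.array([b.lo for b in candidates.candidates])
    b2 = np.array([b.hi for b in candidates.candidates])
    scores = np.empty((len(stride_samples), len(candidates.candidates)))
    for i, seg in enumerate(stride_samples):
        freqs, contrib = periodogram_bins(seg, rate_hz)
        cum = np.concatenate([[0.0], np.cumsum(contrib)])
        lo_idx = np.searchsorted(freqs, b1 - _FREQ_TOL, side="left")
        hi_idx = np.searchsorted(freqs, b2 + _FREQ_TOL, side="left")
        scores[i] = cum[hi_idx] - cum[lo_idx]

    aucs = _rank_auc(scores, np.asarray(positive))
    best = int(np.argmax(aucs))
    return BandSearchResult(
        best_band=candidates.candidates[best], best_auc=float(aucs[best]), aucs=aucs
    )
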