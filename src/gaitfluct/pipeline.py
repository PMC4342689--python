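"""End-to-end composition: recording -> decisions -> labeled cohort validation."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .evaluation import (
    DEFAULT_MARGIN_S,
    DEFAULT_MIN_STRIDES,
    DEFAULT_N_REPEATS,
    DiaryTimeline,
    LabelingResult,
    ValidationReport,
    label_decisions,
    run_validation,
    transition_exclusion_mask,
)
from .recording import AccelerometerRecording
from .simulate import (
    GaitModelParams,
    SyntheticPatient,
    make_schedule,
    simulate_cohort,
)
from .spectral import FLUENCY_BAND, WindowingConfig, resample_to_analysis_rate
from .strides import (
    EpisodeFluency,
    PeakParams,
    build_strides,
    detect_initial_contacts,
    episode_fluency,
    trim_episode_boundaries,
)
from .walking import WalkingWindowClassifier, detect_walking, train_walking_model


def extract_decisions(
    rec: AccelerometerRecording,
    model: WalkingWindowClassifier,
    cfg: WindowingConfig | None = None,
    peak_params: PeakParams | None = None,
    band=FLUENCY_BAND,
) -> list[EpisodeFluency]:
    """Run phases 1-4 (detection side) on one recording.

    Resamples to the analysis rate if needed, detects walking episodes,
    trims episode boundaries, finds initial contacts on the forward axis,
    builds strides, and averages stride fluencies per episode.
    """
    cfg = cfg or WindowingConfig()
    rec40 = (
        rec
        if abs(rec.sampling_rate_hz - cfg.analysis_rate_hz) < 1e-6
        else resample_to_analysis_rate(rec, cfg.analysis_rate_hz)
    )
    labels, episodes, _ = detect_walking(rec40, model, cfg)
    rate = cfg.analysis_rate_hz
    forward = rec40.axis("forward")
    decisions = []
    for ep in episodes:
        lo, hi = trim_episode_boundaries(ep, cfg)
        if hi <= lo:
            continue
        events = detect_initial_contacts(
            forward[lo:hi], rate, peak_params, offset_index=lo
        )
        strides = build_strides(events, rec40.data[lo:hi], rate, offset_index=lo)
        decisions.append(episode_fluency(strides, ep, rate, band))
    return decisions


def train_default_walking_model(
    seed: int = 0,
    n_sessions: int = 3,
    session_duration_s: float = 1200.0,
    max_windows_per_class: int = 300,
    gait: GaitModelParams | None = None,
    **model_kwargs,
) -> WalkingWindowClassifier:
    """Train the walking classifier on a dedicated synthetic training cohort.

    Emulates the protocol's first part: separate subjects provide labeled
    walking / not-walking windows (a window is labeled walking when more
    than half its samples fall inside a true walking bout). Training
    sessions alternate motor phases quickly (5 min median) so both ON and
    OFF gait appear among the walking windows. Classes are subsampled to
    at most ``max_windows_per_class`` windows each, balanced
    deterministically under ``seed``.
    """
    from .spectral import segment_windows, window_feature_matrix

    cfg = WindowingConfig()
    sched = make_schedule(session_duration_s, phase_median_s=300.0)
    patients = simulate_cohort(n_sessions, gait=gait, sched=sched,
                               base_seed=seed + 77_000)
    feats, labels = [], []
    for p in patients:
        rec40 = resample_to_analysis_rate(p.recording, cfg.analysis_rate_hz)
        windows = segment_windows(rec40, cfg)
        # ground-truth mask is at the sensor rate; downsample by index
        ratio = p.recording.sampling_rate_hz / cfg.analysis_rate_hz
        for w in windows:
            i0 = int(w.index * cfg.window_samples * ratio)
            i1 = int((w.index + 1) * cfg.window_samples * ratio)
            frac = p.walking_mask[i0:i1].mean() if i1 > i0 else 0.0
            labels.append(int(frac > 0.5))
        feats.append(window_feature_matrix(windows, rate_hz=cfg.analysis_rate_hz))
    X = np.vstack(feats)
    y = np.asarray(labels)

    rng = np.random.default_rng(seed)
    keep = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        keep.append(rng.permutation(idx)[:max_windows_per_class])
    keep = np.sort(np.concatenate(keep))
    model = WalkingWindowClassifier(random_state=seed, **model_kwargs)
    return model.fit(X[keep], y[keep])


def label_patient(
    patient: SyntheticPatient,
    model: WalkingWindowClassifier,
    margin_s: float = DEFAULT_MARGIN_S,
    **extract_kwargs,
) -> LabelingResult:
    """Decisions for one synthetic patient, labeled against their diary."""
    decisions = extract_decisions(patient.recording, model, **extract_kwargs)
    mask = transition_exclusion_mask(patient.diary, margin_s)
    return label_decisions(decisions, patient.diary, mask, margin_s)


def validate_synthetic_cohort(
    patients: list[SyntheticPatient],
    model: WalkingWindowClassifier,
    n_repeats: int = DEFAULT_N_REPEATS,
    base_seed: int = 0,
    margin_s: float = DEFAULT_MARGIN_S,
    min_strides: int = DEFAULT_MIN_STRIDES,
) -> tuple[ValidationReport, dict]:
    """Full protocol on a simulated cohort.

    Returns the validation report and a per-patient dict of LabelingResult
    (for exclusion accounting).
    """
    labeled = {}
    labeling = {}
    for p in patients:
        res = label_patient(p, model, margin_s)
        labeling[p.patient_id] = res
        labeled[p.patient_id] = (res.labeled, p.diary)
    report = run_validation(
        labeled,
        n_repeats=n_repeats,
        base_seed=base_seed,
        min_strides=min_strides,
    )
    return report, labeling


def contact_detection_scores(
    patient: SyntheticPatient,
    peak_params: PeakParams | None = None,
    rate_hz: float = 40.0,
    edge_trim_s: float = 2.0,
    tolerance_s: float = 0.05,
) -> dict:
    """Score initial-contact detection against simulator ground truth.

    For each walking bout, contacts are detected on the forward axis of
    the resampled signal inside the bout interior (``edge_trim_s`` from
    each end, mirroring the episode-boundary trimming that excludes gait
    initiation/termination). A ground-truth contact counts as recovered
    when a detected event lies within ``tolerance_s`` of it; each detected
    event may match one truth contact. Also compares per-bout stride
    counts (event pairs two apart) between detection and truth.

    Returns a dict with ``recall``, ``n_truth``, ``n_matched``,
    ``stride_count_pairs`` (list of (detected, truth) per bout).
    """
    rec40 = resample_to_analysis_rate(patient.recording, rate_hz)
    forward = rec40.axis("forward")
    n_truth = n_matched = 0
    stride_pairs = []
    for bout in patient.bouts:
        lo_t, hi_t = bout.start_s + edge_trim_s, bout.end_s - edge_trim_s
        if hi_t <= lo_t:
            continue
        lo, hi = int(round(lo_t * rate_hz)), int(round(hi_t * rate_hz))
        events = detect_initial_contacts(
            forward[lo:hi], rate_hz, peak_params, offset_index=lo
        )
        det_times = np.array([e.time for e in events])
        truth = bout.contact_times[
            (bout.contact_times >= lo_t) & (bout.contact_times <= hi_t)
        ]
        used = np.zeros(det_times.size, dtype=bool)
        for tc in truth:
            if det_times.size == 0:
                break
            d = np.abs(det_times - tc)
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= tolerance_s:
                used[j] = True
                n_matched += 1
        n_truth += truth.size
        stride_pairs.append(
            (max(0, (det_times.size - 1) // 2), max(0, (truth.size - 1) // 2))
        )
    return {
        "recall": n_matched / n_truth if n_truth else float("nan"),
        "n_truth": n_truth,
        "n_matched": n_matched,
        "stride_count_pairs": stride_pairs,
    }


# ----------------------------------------------------------------------
# Decision-stream CSV (the detector's output artifact)


def write_decisions_csv(decisions: list[EpisodeFluency], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["episode_id", "timestamp_s", "stride_count", "mean_fluency"])
        for d in decisions:
            w.writerow(
                [
                    d.episode_id,
                    f"{d.timestamp:.3f}",
                    d.stride_count,
                    "" if not d.has_decision else f"{d.mean_fluency:.9g}",
                ]
            )


def read_decisions_csv(path: str | Path) -> list[EpisodeFluency]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            ts = float(row["timestamp_s"])
            fl = float(row["mean_fluency"]) if row["mean_fluency"] else float("nan")
            # timestamp was the midpoint; width is not stored, reuse midpoint
            out.append(
                EpisodeFluency(
                    episode_id=int(row["episode_id"]),
                    stride_count=int(row["stride_count"]),
                    mean_fluency=fl,
                    start_time=ts,
                    end_time=ts,
                )
            )
    return out
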