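"""Walking detector: band enumeration, ReliefF, SVM training, episodes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gaitfluct as gf
from gaitfluct.spectral import periodogram_bins, segment_windows
from gaitfluct.walking import WalkingWindowClassifier


# ---------------------------------------------------------------- candidates


def test_full_grid_candidate_count_matches_combinatorial_oracle():
    cands = gf.enumerate_band_candidates(0.1, 20.0)
    assert len(cands.grid) == 200
    assert len(cands) == math.comb(200, 2) == 19_900
    # lexicographic and valid
    assert cands.candidates[0] == gf.FrequencyBand(0.1, 0.2)
    assert cands.candidates[-1] == gf.FrequencyBand(19.9, 20.0)


def test_two_point_grid_single_candidate():
    cands = gf.enumerate_band_candidates(0.5, 1.0)
    assert [tuple(b) for b in cands.candidates] == [(0.5, 1.0)]


def test_non_dividing_step_rejected():
    with pytest.raises(ValueError, match="divide"):
        gf.enumerate_band_candidates(0.3, 20.0)


# ---------------------------------------------------------------- ReliefF


def test_relieff_ranks_informative_above_noise():
    rng = np.random.default_rng(0)
    y = np.repeat([0, 1], 30)
    X = np.column_stack([y + 0.01 * rng.standard_normal(60),
                         rng.standard_normal(60)])
    w = gf.relieff_rank(X, y, k_neighbors=5)
    assert w[0] > w[1]


def test_relieff_duplicate_columns_get_equal_weights():
    rng = np.random.default_rng(1)
    y = np.repeat([0, 1], 20)
    col = rng.standard_normal(40) + y
    X = np.column_stack([col, col])
    w = gf.relieff_rank(X, y, k_neighbors=3)
    assert abs(w[0] - w[1]) < 1e-12


def test_relieff_matches_hand_worked_six_point_trace():
    # 1 feature, k=1: per-anchor (nearest-miss diff − nearest-hit diff),
    # averaged: (0.7+0.6+0.5+0.5+0.6+0.7)/6 = 0.6
    X = np.array([[0.0], [0.1], [0.2], [0.8], [0.9], [1.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    w = gf.relieff_rank(X, y, k_neighbors=1)
    assert w[0] == pytest.approx(0.6, abs=1e-12)


def test_relieff_single_class_rejected():
    with pytest.raises(ValueError, match="two classes"):
        gf.relieff_rank(np.zeros((6, 1)), np.zeros(6), k_neighbors=1)


def test_relieff_full_band_grid_prefers_step_band(busy_patient):
    """On gait-vs-rest windows the 19,900-band ReliefF ranking puts a band
    containing the step frequency above a band entirely above 15 Hz."""
    rec40 = gf.resample_to_analysis_rate(busy_patient.recording, 40.0)
    windows = segment_windows(rec40)
    ratio = busy_patient.recording.sampling_rate_hz / 40.0
    labels = np.array(
        [
            int(
                busy_patient.walking_mask[
                    int(w.index * 128 * ratio) : int((w.index + 1) * 128 * ratio)
                ].mean()
                > 0.5
            )
            for w in windows
        ]
    )
    rng = np.random.default_rng(3)
    keep = np.concatenate(
        [rng.permutation(np.flatnonzero(labels == c))[:60] for c in (0, 1)]
    )
    keep.sort()

    cands = gf.enumerate_band_candidates(0.1, 20.0)
    b1 = np.array([b.lo for b in cands.candidates])
    b2 = np.array([b.hi for b in cands.candidates])
    feats = np.empty((keep.size, len(cands)))
    for row, wi in enumerate(keep):
        freqs, contrib = periodogram_bins(windows[wi].samples, 40.0)
        cum = np.concatenate([[0.0], np.cumsum(contrib)])
        lo = np.searchsorted(freqs, b1 - 1e-9, side="left")
        hi = np.searchsorted(freqs, b2 + 1e-9, side="left")
        feats[row] = cum[hi] - cum[lo]

    w = gf.relieff_rank(feats, labels[keep], k_neighbors=10)
    step_f = busy_patient.gait.step_frequency_hz["ON"]
    in_step = [i for i, b in enumerate(cands.candidates)
               if b.lo <= step_f <= b.hi]
    above15 = [i for i, b in enumerate(cands.candidates) if b.lo >= 15.0]
    assert max(w[in_step]) > max(w[above15])


# ---------------------------------------------------------------- SVM


def _gaussian_clusters(n=200, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, 2))
    y = np.repeat([0, 1], n // 2)
    X[y == 1] += sep
    return X, y


def test_separable_clusters_reach_high_cv_accuracy():
    X, y = _gaussian_clusters()
    model = WalkingWindowClassifier(random_state=0).fit(X, y)
    assert model.cv_accuracy_ >= 0.95
    assert np.mean(model.predict(X) == y) >= 0.95


def test_shuffled_labels_give_chance_cv_accuracy():
    X, y = _gaussian_clusters()
    rng = np.random.default_rng(42)
    model = WalkingWindowClassifier(random_state=0).fit(X, rng.permutation(y))
    assert 0.35 <= model.cv_accuracy_ <= 0.65


def test_singleton_grids_select_exactly_those_hyperparameters():
    X, y = _gaussian_clusters(n=60)
    model = WalkingWindowClassifier(
        C_grid=(4.0,), gamma_grid=(0.25,), random_state=0
    ).fit(X, y)
    assert model.C_ == 4.0 and model.gamma_ == 0.25


def test_training_order_permutation_invariance():
    X, y = _gaussian_clusters(n=80, seed=3)
    m1 = WalkingWindowClassifier(random_state=1).fit(X, y)
    perm = np.random.default_rng(9).permutation(len(y))
    m2 = WalkingWindowClassifier(random_state=1).fit(X[perm], y[perm])
    assert (m1.C_, m1.gamma_) == (m2.C_, m2.gamma_)
    grid = np.random.default_rng(0).uniform(-1, 7, size=(50, 2))
    np.testing.assert_allclose(
        m1.decision_function(grid), m2.decision_function(grid), atol=1e-8
    )


def test_degenerate_labels_rejected():
    with pytest.raises(ValueError, match="both classes"):
        WalkingWindowClassifier().fit(np.zeros((30, 2)), np.zeros(30))


def test_json_round_trip_preserves_predictions(tmp_path):
    X, y = _gaussian_clusters(n=60)
    model = WalkingWindowClassifier(random_state=0).fit(X, y)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = WalkingWindowClassifier.from_json(path)
    np.testing.assert_array_equal(back.predict(X), model.predict(X))
    # tampering breaks the checksum
    text = path.read_text().replace('"C":', '"C_":', 1)
    with pytest.raises((ValueError, KeyError)):
        WalkingWindowClassifier.from_json(text)


# ---------------------------------------------------------------- episodes


def test_run_length_episode_assembly():
    eps = gf.episodes_from_labels([1, 1, 0, 1])
    assert [(e.first_window, e.last_window) for e in eps] == [(0, 1), (3, 3)]
    assert eps[0].start_time == 0.0 and eps[0].end_time == pytest.approx(6.4)
    assert gf.episodes_from_labels([0, 0, 0]) == []


@settings(deadline=None, max_examples=50)
@given(st.lists(st.booleans(), max_size=60))
def test_episode_partition_property(labels):
    """Every walking window is in exactly one episode; episodes are
    non-adjacent maximal runs that reconstruct the label vector."""
    eps = gf.episodes_from_labels(labels)
    covered = sorted(i for e in eps for i in e.window_indices)
    assert covered == [i for i, lab in enumerate(labels) if lab]
    assert len(covered) == len(set(covered))
    for a, b in zip(eps, eps[1:]):
        assert b.first_window > a.last_window + 1  # maximality


def test_detect_walking_recovers_two_bouts(walking_model):
    """Two gait bouts separated by rest -> exactly two episodes, each
    overlapping its true bout by >= 80% of windows."""
    rng = np.random.default_rng(12)
    rate, step_f = 40.0, 1.8
    segs, truth = [], []
    t_cursor = 0.0

    def rest(dur):
        nonlocal t_cursor
        segs.append(0.03 * rng.standard_normal((int(dur * rate), 3)))
        t_cursor += dur

    def walk(dur):
        nonlocal t_cursor
        n = int(dur * rate)
        t = np.arange(n) / rate
        block = 0.03 * rng.standard_normal((n, 3))
        for ax, amp in enumerate((0.25, 0.2, 0.1)):
            block[:, ax] += amp * np.cos(2 * np.pi * step_f * t) \
                + 0.3 * amp * np.cos(4 * np.pi * step_f * t)
        truth.append((t_cursor, t_cursor + dur))
        segs.append(block)
        t_cursor += dur

    rest(30); walk(20); rest(30); walk(13); rest(30)
    data = np.vstack(segs)
    data[:, 0] += 1.0  # gravity on the vertical axis
    rec = gf.AccelerometerRecording(
        "two-bouts", rate, np.arange(len(data)) / rate, data
    )
    labels, episodes, _ = gf.detect_walking(rec, walking_model)
    assert len(episodes) == 2
    for ep, (lo, hi) in zip(episodes, truth):
        true_windows = {i for i in range(len(labels))
                        if lo <= i * 3.2 and (i + 1) * 3.2 <= hi}
        got = set(ep.window_indices)
        assert len(got & true_windows) / len(true_windows) >= 0.8
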