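"""Diary alignment, exclusion rules, validity metrics and the repeat protocol."""

import numpy as np
import pytest

import gaitfluct as gf
from gaitfluct.calibration import OFF, ON
from gaitfluct.errors import DataError
from gaitfluct.evaluation import (
    LabeledDecision,
    merge_intervals,
    render_metric,
)
from gaitfluct.strides import EpisodeFluency


def _diary(*triples):
    return gf.DiaryTimeline([gf.DiaryInterval(*t) for t in triples])


def _decision(ts, fluency=1.0, strides=12, width=10.0, eid=0):
    return EpisodeFluency(
        episode_id=eid,
        stride_count=strides,
        mean_fluency=fluency,
        start_time=ts - width / 2,
        end_time=ts + width / 2,
    )


# ---------------------------------------------------------------- diary


def test_diary_must_be_gap_free_and_known_states():
    with pytest.raises(DataError, match="gap-free"):
        _diary((0, 100, ON), (150, 200, OFF))
    with pytest.raises(DataError, match="unknown"):
        _diary((0, 100, "DYSKINETIC"))


def test_diary_csv_round_trip(tmp_path):
    d = _diary((0, 3600, ON), (3600, 5400, OFF), (5400, 7200, "INTERMEDIATE"))
    p = tmp_path / "diary.csv"
    d.to_csv(p)
    back = gf.DiaryTimeline.from_csv(p)
    assert [(iv.start_s, iv.end_s, iv.state) for iv in back.intervals] == [
        (0, 3600, ON), (3600, 5400, OFF), (5400, 7200, "INTERMEDIATE")
    ]
    assert back.state_at(4000) == OFF
    assert back.state_at(-5) is None and back.state_at(7200) is None


# ---------------------------------------------------------------- exclusion


def test_single_transition_five_minute_margin():
    d = _diary((0, 3600, ON), (3600, 7200, OFF))
    assert gf.transition_exclusion_mask(d) == [(3300.0, 3900.0)]


def test_no_transitions_empty_mask():
    assert gf.transition_exclusion_mask(_diary((0, 7200, ON))) == []


def test_adjacent_same_state_is_not_a_transition():
    d = _diary((0, 3600, ON), (3600, 7200, ON))
    assert gf.transition_exclusion_mask(d) == []


def test_close_transitions_merge_into_union():
    d = _diary((0, 3600, ON), (3600, 4000, OFF), (4000, 7200, ON))
    mask = gf.transition_exclusion_mask(d)
    # [3300,3900] U [3700,4300] -> one interval of 1000 s
    assert mask == [(3300.0, 4300.0)]
    assert sum(hi - lo for lo, hi in mask) == 1000.0


def test_merge_intervals_oracle():
    assert merge_intervals([(5, 7), (0, 2), (1, 3)]) == [(0, 3), (5, 7)]


# ---------------------------------------------------------------- labeling


def test_label_decisions_drop_reasons_and_accounting():
    d = _diary((0, 3600, ON), (3600, 5400, OFF), (5400, 6000, "INTERMEDIATE"),
               (6000, 6600, "UNDEFINED"), (6600, 10000, ON))
    decisions = [
        _decision(1000, eid=0),           # mid-ON, far from boundaries -> ON
        _decision(3500, eid=1),           # within 5-min margin of 3600
        _decision(4500, eid=2),           # OFF interval, clear of margins... 4500-300? transition at 3600 and 5400: margins [3300,3900],[5100,5700],[5700,6300]->merged. 4500 clear -> OFF
        _decision(5750, eid=3),           # intermediate (but inside margin) -> margin
        _decision(12000, eid=4),          # outside diary span -> no gold
        _decision(2000, fluency=float("nan"), eid=5),  # no decision emitted
        _decision(8000, eid=6),           # ON
    ]
    res = gf.label_decisions(decisions, d)
    assert [ld.label for ld in res.labeled] == [ON, OFF, ON]
    assert res.dropped["margin"] == 2
    assert res.dropped["no_gold"] == 1
    assert res.dropped["no_fluency"] == 1
    assert res.n_input == len(decisions)  # accounting identity


def test_intermediate_and_undefined_dropped_outside_margins():
    d = _diary((0, 3600, "INTERMEDIATE"), (3600, 7200, "UNDEFINED"))
    decisions = [_decision(1000), _decision(5000)]
    res = gf.label_decisions(decisions, d)
    assert res.labeled == []
    assert res.dropped["intermediate"] == 1
    assert res.dropped["undefined"] == 1


def test_straddling_episode_dropped():
    d = _diary((0, 3600, ON), (3600, 7200, OFF))
    straddler = _decision(3599, width=10)  # spans 3594-3604, crosses 3600
    res = gf.label_decisions([straddler], d, mask=[])  # margin disabled
    assert res.dropped["straddles_transition"] == 1


def test_min_stride_filter_boundary_inclusive():
    decisions = [
        LabeledDecision(_decision(10, strides=c), ON) for c in (4, 10, 25)
    ]
    kept = gf.filter_min_strides(decisions, 10)
    assert [d.decision.stride_count for d in kept] == [10, 25]
    assert gf.filter_min_strides([], 10) == []
    assert set(map(id, kept)) <= set(map(id, decisions))  # subset


# ---------------------------------------------------------------- metrics


def test_confusion_metrics_hand_computed():
    pred = [OFF] * 9 + [ON] * 1 + [ON] * 18 + [OFF] * 2
    truth = [OFF] * 10 + [ON] * 20
    cc, m = gf.confusion_metrics(pred, truth)
    assert (cc.tp, cc.fn, cc.tn, cc.fp) == (9, 1, 18, 2)
    assert m.sensitivity == pytest.approx(0.9)
    assert m.specificity == pytest.approx(0.9)
    assert m.ppv == pytest.approx(9 / 11)
    assert m.npv == pytest.approx(18 / 19)


def test_degenerate_truth_gives_undefined_sensitivity():
    pred = [ON, ON, OFF]
    truth = [ON, ON, ON]
    _, m = gf.confusion_metrics(pred, truth)
    assert np.isnan(m.sensitivity)
    assert np.isfinite(m.specificity)
    assert render_metric(m.sensitivity) == "-"
    assert render_metric(m.specificity) == "0.67"


def test_perfect_prediction_all_ones():
    truth = [ON, OFF, ON, OFF]
    _, m = gf.confusion_metrics(truth, truth)
    assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)


def test_metrics_match_brute_force_recount():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(5, 60))
        pred = rng.choice([ON, OFF], n)
        truth = rng.choice([ON, OFF], n)
        cc, m = gf.confusion_metrics(pred, truth)
        tp = sum(1 for p, t in zip(pred, truth) if p == OFF and t == OFF)
        fp = sum(1 for p, t in zip(pred, truth) if p == OFF and t == ON)
        tn = sum(1 for p, t in zip(pred, truth) if p == ON and t == ON)
        fn = sum(1 for p, t in zip(pred, truth) if p == ON and t == OFF)
        assert (cc.tp, cc.fp, cc.tn, cc.fn) == (tp, fp, tn, fn)
        assert cc.total == n
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))


# ---------------------------------------------------------------- protocol


def _patient_decisions(rng, n_on, n_off, mu_on=5.0, mu_off=1.0, sd=0.1):
    decisions, t = [], 600.0
    for i in range(n_on + n_off):
        state = ON if i < n_on else OFF
        mu = mu_on if state == ON else mu_off
        decisions.append(
            LabeledDecision(
                _decision(t, fluency=float(rng.normal(mu, sd)),
                          strides=int(rng.integers(5, 30)), eid=i),
                state,
            )
        )
        t += 60.0
    return decisions


def test_zero_overlap_cohort_is_perfect_with_zero_sd():
    rng = np.random.default_rng(1)
    diary = _diary((0, 36000, ON))
    patients = {
        f"P{i}": (_patient_decisions(rng, 20, 15), diary) for i in range(3)
    }
    report = gf.run_validation(patients, n_repeats=10, base_seed=0)
    for var in report.variants.values():
        assert var.excluded == []
        for p in var.per_patient:
            for m in ("sensitivity", "specificity"):
                assert p.mean[m] == 1.0
                assert p.sd[m] == 0.0
        assert var.cohort["sensitivity"]["mean"] == 1.0


def test_scarce_off_patients_reported_excluded():
    rng = np.random.default_rng(2)
    diary = _diary((0, 36000, ON))
    patients = {}
    for i in range(15):
        n_off = 0 if i >= 11 else 12  # 4 patients lack OFF decisions
        patients[f"P{i}"] = (_patient_decisions(rng, 15, n_off), diary)
    report = gf.run_validation(patients, n_repeats=5, base_seed=0)
    assert sorted(report.variants["all_segments"].excluded) == [
        "P11", "P12", "P13", "P14"
    ]


def test_min_stride_variant_scores_no_more_than_all_segments():
    rng = np.random.default_rng(3)
    diary = _diary((0, 36000, ON))
    decisions = _patient_decisions(rng, 25, 25)
    report = gf.run_validation({"P": (decisions, diary)}, n_repeats=3, base_seed=1)
    p_all = report.variants["all_segments"].per_patient[0]
    p_min = report.variants["min_strides"].per_patient[0]
    assert p_min.n_on + p_min.n_off <= p_all.n_on + p_all.n_off


def test_chance_cohort_metrics_near_half():
    """Identical ON/OFF fluency distributions -> chance-level validity."""
    rng = np.random.default_rng(4)
    diary = _diary((0, 36000, ON))
    patients = {
        f"P{i}": (_patient_decisions(rng, 25, 25, mu_on=2.0, mu_off=2.0, sd=0.5),
                  diary)
        for i in range(5)
    }
    report = gf.run_validation(patients, n_repeats=30, base_seed=0)
    coh = report.variants["all_segments"].cohort
    assert 0.35 <= coh["sensitivity"]["mean"] <= 0.65
    assert 0.35 <= coh["specificity"]["mean"] <= 0.65


def test_report_serializes_with_dashes_for_undefined(tmp_path):
    rng = np.random.default_rng(5)
    diary = _diary((0, 36000, ON))
    report = gf.run_validation(
        {"P": (_patient_decisions(rng, 12, 12), diary)}, n_repeats=3, base_seed=0
    )
    doc = report.to_dict()
    assert doc["n_repeats"] == 3
    pp = doc["variants"]["all_segments"]["per_patient"][0]
    assert set(pp["metrics"]) == {"sensitivity", "specificity", "ppv", "npv"}
    import json

    json.dumps(doc)  # must be JSON-clean (NaN replaced by None)


def test_mean_output_interval_hand_computed():
    decisions = [_decision(t) for t in (0.0, 60.0, 180.0)]
    # gaps 60 s and 120 s -> mean 90 s = 1.5 min
    assert gf.mean_output_interval_min(decisions) == pytest.approx(1.5)
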