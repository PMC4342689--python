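"""Synthetic waist-accelerometer cohorts with ground truth.

No patient recordings are publicly deposited, so every stage of the
pipeline is exercised against a desk-scale simulator that emulates the
validation sessions: a 200 Hz triaxial waist signal alternating rest and
walking bouts, a gold-standard diary of ON / OFF / INTERMEDIATE / UNDEFINED
phases, and exact ground truth (walking mask, initial-contact times,
per-bout motor state).

Gait model
----------
During a walking bout each semantic axis carries the sum of three
harmonics of the step frequency; the forward axis has all harmonics in
cosine phase so its relative maxima fall exactly at the initial contacts.
The OFF state has lower harmonic amplitudes (ON = contrast x OFF, default
contrast 1.8) and a slower cadence (1.5 vs 1.9 steps/s), so spectral power
in [0.1, 10] Hz — the fluency — is systematically higher in ON. White
noise is added everywhere; rest segments occasionally carry a slow
(<0.1 Hz) posture drift, below the analysis band. The vertical axis rides
on a +1 g gravity bias.

Schedule
--------
Motor phases alternate ON/OFF with lognormal durations (median 1.5 h —
phases typically last one to a few hours), occasionally interrupted by
short INTERMEDIATE or UNDEFINED phases that exist to exercise the
exclusion rules. Walking bouts recur within phases at the activity level
of the monitored sessions (an algorithm output roughly every minute or
two): exponential inter-bout gaps (mean 60 s) and lognormal bout durations
(median 30 s). The diary is the true phase timeline shifted by a small
reporting latency.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from math import ceil, log, pi
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .calibration import OFF, ON
from .evaluation import DiaryInterval, DiaryTimeline
from .recording import DEFAULT_AXIS_ROLES, AccelerometerRecording, save_recording

SENSOR_RATE_HZ = 200.0
INTERMEDIATE, UNDEFINED = "INTERMEDIATE", "UNDEFINED"


@dataclass(frozen=True)
class GaitModelParams:
    """Waveform parameters of the harmonic gait model (amplitudes in g)."""

    step_frequency_hz: dict = field(
        default_factory=lambda: {ON: 1.9, OFF: 1.5, INTERMEDIATE: 1.7}
    )
    #: OFF-state harmonic amplitudes per semantic axis (fundamental, 2nd, 3rd).
    amplitudes: dict = field(
        default_factory=lambda: {
            "vertical": (0.18, 0.06, 0.03),
            "forward": (0.15, 0.05, 0.02),
            "lateral": (0.08, 0.03, 0.01),
        }
    )
    #: ON amplitudes = contrast x OFF amplitudes (>= 1); the single knob for
    #: power analyses. INTERMEDIATE sits midway.
    fluency_contrast: float = 1.8
    noise_sd: float = 0.03
    gravity_g: float = 1.0
    #: relative cadence variability (AR(1)-smoothed, tau = 2 s)
    cadence_jitter: float = 0.02
    drift_amplitude_g: float = 0.015

    def __post_init__(self):
        for state, f in self.step_frequency_hz.items():
            if not (0.5 <= f <= 3.0):
                raise ValueError(f"step frequency {f} Hz for {state} outside [0.5, 3]")
        if self.fluency_contrast < 1.0:
            raise ValueError("fluency_contrast must be >= 1")
        for axis, amps in self.amplitudes.items():
            if any(a < 0 for a in amps):
                raise ValueError(f"negative amplitude on {axis}")

    def state_scale(self, state: str) -> float:
        if state == ON:
            return self.fluency_contrast
        if state == INTERMEDIATE:
            return 0.5 * (1.0 + self.fluency_contrast)
        return 1.0  # OFF baseline; UNDEFINED phases reuse ON gait below


@dataclass(frozen=True)
class ScheduleParams:
    """Phase/bout schedule of one monitoring session."""

    total_duration_s: float = 10800.0  # sessions last 3-5 h; 3 h default
    phase_median_s: float = 5400.0
    phase_sigma: float = 0.5
    phase_bounds_s: tuple[float, float] = (900.0, 9000.0)
    intermediate_fraction: float = 0.10
    undefined_fraction: float = 0.05
    intermediate_median_s: float = 600.0
    undefined_median_s: float = 300.0
    bout_gap_mean_s: float = 60.0
    bout_duration_median_s: float = 30.0
    bout_sigma: float = 0.4
    bout_bounds_s: tuple[float, float] = (8.0, 120.0)
    bout_margin_s: float = 2.0
    diary_latency_s: float = 20.0
    #: when True the schedule never enters OFF — used to construct patients
    #: with insufficient motor data for the validation protocol
    scarce_off: bool = False

    def __post_init__(self):
        if self.bout_bounds_s[1] + 2 * self.bout_margin_s > self.phase_bounds_s[0]:
            raise ValueError("longest bout cannot fit inside the shortest phase")


def make_schedule(
    total_duration_s: float,
    phase_median_s: float = 5400.0,
    **overrides,
) -> ScheduleParams:
    """ScheduleParams with phase/bout bounds kept mutually consistent.

    Shrinking the phase median below the default requires shrinking the
    phase floor and the maximum bout length with it; this helper derives
    both so short desk-scale sessions remain valid schedules.
    """
    lo = max(120.0, phase_median_s / 3.0)
    hi = phase_median_s * 4.0
    margin = overrides.get("bout_margin_s", 2.0)
    bout_hi = min(120.0, lo - 2 * margin - 1.0)
    defaults = dict(
        total_duration_s=total_duration_s,
        phase_median_s=phase_median_s,
        phase_bounds_s=(lo, hi),
        bout_bounds_s=(8.0, bout_hi),
    )
    defaults.update(overrides)
    return ScheduleParams(**defaults)


@dataclass
class Bout:
    start_s: float
    end_s: float
    state: str
    contact_times: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SyntheticPatient:
    patient_id: str
    recording: AccelerometerRecording
    diary: DiaryTimeline
    bouts: list[Bout]
    walking_mask: np.ndarray  # bool, at the sensor rate
    seed: int
    gait: GaitModelParams
    sched: ScheduleParams

    @property
    def contact_times(self) -> np.ndarray:
        if not self.bouts:
            return np.empty(0)
        return np.concatenate([b.contact_times for b in self.bouts])


# ----------------------------------------------------------------------


def _lognormal(rng, median, sigma, bounds):
    return float(np.clip(rng.lognormal(log(median), sigma), *bounds))


def _build_phases(sched: ScheduleParams, rng) -> list[DiaryInterval]:
    """Alternating ON/OFF phases, sprinkled with INTERMEDIATE/UNDEFINED."""
    phases: list[DiaryInterval] = []
    t = 0.0
    main = ON if sched.scarce_off else rng.choice([ON, OFF])
    while t < sched.total_duration_s:
        u = rng.uniform()
        if phases and u < sched.undefined_fraction:
            state, dur = UNDEFINED, _lognormal(
                rng, sched.undefined_median_s, 0.4, (60.0, 900.0)
            )
        elif phases and u < sched.undefined_fraction + sched.intermediate_fraction:
            state, dur = INTERMEDIATE, _lognormal(
                rng, sched.intermediate_median_s, 0.4, (120.0, 1800.0)
            )
        else:
            state = main
            dur = _lognormal(rng, sched.phase_median_s, sched.phase_sigma,
                             sched.phase_bounds_s)
            main = ON if (sched.scarce_off or main == OFF) else OFF
        end = min(t + dur, sched.total_duration_s)
        phases.append(DiaryInterval(t, end, state))
        t = end
    return phases


def _build_bouts(phases, sched: ScheduleParams, rng) -> list[Bout]:
    bouts: list[Bout] = []
    for ph in phases:
        t = ph.start_s + sched.bout_margin_s
        limit = ph.end_s - sched.bout_margin_s
        while True:
            gap = rng.exponential(sched.bout_gap_mean_s)
            dur = _lognormal(
                rng, sched.bout_duration_median_s, sched.bout_sigma,
                sched.bout_bounds_s,
            )
            if t + gap + dur > limit:
                break
            bouts.append(Bout(start_s=t + gap, end_s=t + gap + dur, state=ph.state))
            t = t + gap + dur
    return bouts


def _synth_bout(bout: Bout, gait: GaitModelParams, rng, fs: float, phases_by_axis):
    """Harmonic waveform of one bout; returns (per-role signals, contact times)."""
    n = int(round((bout.end_s - bout.start_s) * fs))
    # walking state for waveform purposes; UNDEFINED phases walk like ON
    state = bout.state if bout.state != UNDEFINED else ON
    f0 = gait.step_frequency_hz.get(state, gait.step_frequency_hz[ON])
    scale = gait.state_scale(state)

    # AR(1)-smoothed cadence variability
    a = np.exp(-1.0 / (fs * 2.0))
    z = lfilter([np.sqrt(1 - a**2)], [1.0, -a], rng.standard_normal(n))
    f_inst = f0 * (1.0 + gait.cadence_jitter * z)
    phase = 2 * pi * np.cumsum(f_inst) / fs

    # half-cosine amplitude ramps emulate gait initiation/termination
    env = np.ones(n)
    r = min(int(round(1.0 * fs)), n // 2)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(pi * np.arange(r) / r))
        env[:r] *= ramp
        env[-r:] *= ramp[::-1]

    signals = {}
    for role, amps in gait.amplitudes.items():
        s = np.zeros(n)
        for h, amp in enumerate(amps, start=1):
            s += amp * np.cos(h * phase + phases_by_axis[role][h - 1])
        signals[role] = env * scale * s

    # ground-truth contacts: forward-axis cosine peaks, i.e. phase = 2*pi*k
    kmax = int(phase[-1] // (2 * pi))
    contacts = []
    for k in range(1, kmax + 1):
        idx = int(np.searchsorted(phase, 2 * pi * k))
        if idx == 0 or idx >= n:
            continue
        # linear interpolation of the crossing instant
        p0, p1 = phase[idx - 1], phase[idx]
        frac = (2 * pi * k - p0) / (p1 - p0)
        contacts.append(bout.start_s + (idx - 1 + frac) / fs)
    return signals, np.asarray(contacts)


def simulate_patient(
    gait: GaitModelParams | None = None,
    sched: ScheduleParams | None = None,
    seed: int = 0,
    patient_id: str = "SIM00",
) -> SyntheticPatient:
    """One synthetic monitoring session; bit-identical under a fixed seed."""
    gait = gait or GaitModelParams()
    sched = sched or ScheduleParams()
    rng = np.random.default_rng(seed)
    fs = SENSOR_RATE_HZ

    phases = _build_phases(sched, rng)
    bouts = _build_bouts(phases, sched, rng)

    n = int(round(sched.total_duration_s * fs))
    roles = {role: rng.standard_normal(n) * gait.noise_sd
             for role in ("vertical", "forward", "lateral")}
    roles["vertical"] += gait.gravity_g
    walking_mask = np.zeros(n, dtype=bool)

    # fixed per-patient harmonic phase offsets; forward stays in cosine phase
    # so its maxima mark the contacts
    phases_by_axis = {
        "forward": (0.0, 0.0, 0.0),
        "vertical": (pi / 2, rng.uniform(0, 2 * pi), rng.uniform(0, 2 * pi)),
        "lateral": (rng.uniform(0, 2 * pi),) * 3,
    }

    for bout in bouts:
        i0 = int(round(bout.start_s * fs))
        signals, contacts = _synth_bout(bout, gait, rng, fs, phases_by_axis)
        i1 = i0 + len(signals["forward"])
        for role, s in signals.items():
            roles[role][i0:i1] += s
        walking_mask[i0:i1] = True
        bout.contact_times = contacts

    # occasional sub-band posture drift during rest
    rest_edges = [0.0] + [t for b in bouts for t in (b.start_s, b.end_s)] + [
        sched.total_duration_s
    ]
    for lo, hi in zip(rest_edges[::2], rest_edges[1::2]):
        if hi - lo < 30.0 or rng.uniform() > 0.5:
            continue
        i0, i1 = int(round(lo * fs)), int(round(hi * fs))
        tt = np.arange(i1 - i0) / fs
        f_d = rng.uniform(0.02, 0.08)
        amp = gait.drift_amplitude_g * rng.uniform(0.5, 1.5)
        drift = amp * np.sin(2 * pi * f_d * tt + rng.uniform(0, 2 * pi))
        roles["forward"][i0:i1] += drift
        roles["lateral"][i0:i1] += drift * rng.uniform(0.3, 1.0)

    # map semantic roles onto sensor columns via the default convention
    data = np.empty((n, 3))
    for role, (axis, sign) in DEFAULT_AXIS_ROLES.items():
        data[:, {"ax": 0, "ay": 1, "az": 2}[axis]] = sign * roles[role]

    rec = AccelerometerRecording(
        patient_id=patient_id,
        sampling_rate_hz=fs,
        time=np.arange(n) / fs,
        data=data,
        axis_roles=dict(DEFAULT_AXIS_ROLES),
    )

    # diary: true timeline with interior boundaries delayed by the reporting
    # latency (the observer notices a phase change a little late)
    lat = sched.diary_latency_s
    T = sched.total_duration_s
    edges = [0.0] + [min(ph.end_s + lat, T) for ph in phases[:-1]] + [T]
    diary = DiaryTimeline(
        [
            DiaryInterval(lo, hi, ph.state)
            for lo, hi, ph in zip(edges[:-1], edges[1:], phases)
            if hi > lo
        ]
    )

    return SyntheticPatient(
        patient_id=patient_id,
        recording=rec,
        diary=diary,
        bouts=bouts,
        walking_mask=walking_mask,
        seed=seed,
        gait=gait,
        sched=sched,
    )


def simulate_cohort(
    n_patients: int,
    gait: GaitModelParams | None = None,
    sched: ScheduleParams | None = None,
    base_seed: int = 0,
    n_scarce_off: int = 0,
    jitter: bool = True,
    duration_range_s: tuple[float, float] | None = None,
) -> list[SyntheticPatient]:
    """Deterministic cohort with per-patient gait parameter jitter.

    The last ``n_scarce_off`` patients get an all-ON schedule so the
    validation protocol must exclude them. When ``duration_range_s`` is
    given, per-patient session lengths are drawn uniformly from it.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    gait = gait or GaitModelParams()
    sched = sched or ScheduleParams()
    master = np.random.default_rng(base_seed)
    patients = []
    for i in range(n_patients):
        freq_mult = master.uniform(0.92, 1.08) if jitter else 1.0
        amp_mult = master.uniform(0.8, 1.2) if jitter else 1.0
        seed = int(master.integers(0, 2**31 - 1))
        g = dataclasses.replace(
            gait,
            step_frequency_hz={
                s: min(3.0, max(0.5, f * freq_mult))
                for s, f in gait.step_frequency_hz.items()
            },
            amplitudes={
                axis: tuple(a * amp_mult for a in amps)
                for axis, amps in gait.amplitudes.items()
            },
        )
        s = sched
        if duration_range_s is not None:
            s = dataclasses.replace(
                s, total_duration_s=float(master.uniform(*duration_range_s))
            )
        if i >= n_patients - n_scarce_off:
            s = dataclasses.replace(s, scarce_off=True)
        patients.append(
            simulate_patient(g, s, seed=seed, patient_id=f"SIM{i + 1:02d}")
        )
    return patients


# ----------------------------------------------------------------------


def write_patient(patient: SyntheticPatient, out_dir: str | Path) -> dict:
    """Write recording CSV + metadata sidecar + diary CSV + ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec_path = out_dir / f"{patient.patient_id}.csv"
    save_recording(patient.recording, rec_path)
    diary_path = out_dir / f"{patient.patient_id}.diary.csv"
    patient.diary.to_csv(diary_path)
    truth_path = out_dir / f"{patient.patient_id}.truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "seed": patient.seed,
                "bouts": [
                    {
                        "start_s": b.start_s,
                        "end_s": b.end_s,
                        "state": b.state,
                        "contact_times": b.contact_times.tolist(),
                    }
                    for b in patient.bouts
                ],
            }
        )
    )
    return {
        "recording": str(rec_path),
        "diary": str(diary_path),
        "truth": str(truth_path),
    }
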