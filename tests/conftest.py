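"""Shared fixtures: small synthetic patients and a trained walking model.

Everything is generated programmatically and seeded; the expensive
fixtures are session-scoped so the suite builds them once.
"""

import numpy as np
import pytest

import gaitfluct as gf


@pytest.fixture(scope="session")
def wcfg():
    return gf.WindowingConfig()


@pytest.fixture(scope="session")
def busy_patient():
    """30 min session with fast-alternating ON/OFF phases and many bouts."""
    sched = gf.make_schedule(1800.0, phase_median_s=300.0)
    return gf.simulate_patient(seed=7, sched=sched, patient_id="BUSY")


@pytest.fixture(scope="session")
def walking_model():
    """Walking classifier trained on a small synthetic training cohort."""
    return gf.train_default_walking_model(
        seed=11, n_sessions=2, session_duration_s=600.0, max_windows_per_class=150
    )


@pytest.fixture(scope="session")
def busy_decisions(busy_patient, walking_model):
    """Episode fluency decisions extracted from the busy patient."""
    return gf.extract_decisions(busy_patient.recording, walking_model)


def make_tone_recording(
    freq_hz: float,
    duration_s: float,
    rate_hz: float = 200.0,
    amplitude: float = 1.0,
    axis: int = 0,
    patient_id: str = "tone",
) -> gf.AccelerometerRecording:
    """Single-axis sinusoid recording used as a spectral test signal."""
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    data = np.zeros((t.size, 3))
    data[:, axis] = amplitude * np.sin(2 * np.pi * freq_hz * t)
    return gf.AccelerometerRecording(
        patient_id=patient_id, sampling_rate_hz=rate_hz, time=t, data=data
    )
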