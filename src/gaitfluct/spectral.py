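"""Resampling, windowing and spectral band power.

All downstream stages consume the signal at a 40 Hz analysis rate, cut into
non-overlapping 3.2 s windows (128 samples), and score signal segments by
their spectral power inside a frequency band.

Band power here is the mean-removed, per-axis periodogram power summed over
the frequency bins whose centre lies inside the closed band, added across
the three axes, and normalised to mean-square units (g^2) so that a
stationary signal gives the same value regardless of segment length. With
that normalisation the band powers over a disjoint partition of
(0, Nyquist] add up exactly to the segment's mean-removed mean-square power
(Parseval), which the test suite exploits as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .recording import AccelerometerRecording

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class FrequencyBand:
    """Closed frequency interval [lo, hi] in Hz with hi > lo >= 0."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (0.0 <= self.lo < self.hi):
            raise ValueError(f"invalid band [{self.lo}, {self.hi}]")

    def __iter__(self):
        return iter((self.lo, self.hi))

    def __str__(self):
        return f"[{self.lo:g}, {self.hi:g}] Hz"


#: The two bands the walking detector uses as features.
PHASE1_BANDS: tuple[FrequencyBand, FrequencyBand] = (
    FrequencyBand(0.1, 3.0),
    FrequencyBand(0.1, 10.0),
)

#: The band used to score stride fluency.
FLUENCY_BAND = FrequencyBand(0.1, 10.0)


@dataclass(frozen=True)
class WindowingConfig:
    window_seconds: float = 3.2
    analysis_rate_hz: float = 40.0

    @property
    def window_samples(self) -> int:
        return int(round(self.window_seconds * self.analysis_rate_hz))


@dataclass
class AnalysisWindow:
    """One fixed-length window of the analysis-rate signal."""

    index: int
    start_time: float
    samples: np.ndarray  # (window_samples, 3)
    features: np.ndarray | None = field(default=None)


# ----------------------------------------------------------------------


def resample_to_analysis_rate(
    rec: AccelerometerRecording, target_hz: float = 40.0
) -> AccelerometerRecording:
    """Anti-aliased downsampling to the analysis rate.

    A linear-phase Kaiser FIR low-pass (cutoff 0.8 x target Nyquist, 60 dB
    design attenuation) is applied inside polyphase resampling, so content
    above the target Nyquist is suppressed by well over 40 dB.
    """
    fs = rec.sampling_rate_hz
    if target_hz > fs * (1 + 1e-9):
        raise ValueError(f"cannot upsample {fs} Hz to {target_hz} Hz")
    if abs(target_hz - fs) <= 1e-9 * fs:
        return AccelerometerRecording(
            patient_id=rec.patient_id,
            sampling_rate_hz=fs,
            time=rec.time.copy(),
            data=rec.data.copy(),
            axis_roles=dict(rec.axis_roles),
        )

    frac = Fraction(target_hz / fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    fs_up = fs * up
    nyq = target_hz / 2.0
    cutoff = 0.8 * nyq
    width = nyq - cutoff
    numtaps, beta = sps.kaiserord(60.0, width / (0.5 * fs_up))
    numtaps += 1 - numtaps % 2  # force odd length -> integer group delay
    h = sps.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs_up)
    y = sps.resample_poly(rec.data, up, down, axis=0, window=h * up, padtype="line")

    t0 = rec.time[0] if rec.n_samples else 0.0
    new_time = t0 + np.arange(y.shape[0]) / target_hz
    return AccelerometerRecording(
        patient_id=rec.patient_id,
        sampling_rate_hz=target_hz,
        time=new_time,
        data=y,
        axis_roles=dict(rec.axis_roles),
    )


def segment_windows(
    rec: AccelerometerRecording, cfg: WindowingConfig | None = None
) -> list[AnalysisWindow]:
    """Tile the recording into non-overlapping windows; remainder discarded."""
    cfg = cfg or WindowingConfig()
    if abs(rec.sampling_rate_hz - cfg.analysis_rate_hz) > 1e-6 * cfg.analysis_rate_hz:
        raise ValueError(
            f"recording at {rec.sampling_rate_hz} Hz, expected analysis rate "
            f"{cfg.analysis_rate_hz} Hz — resample first"
        )
    w = cfg.window_samples
    n_windows = rec.n_samples // w
    return [
        AnalysisWindow(
            index=i,
            start_time=i * cfg.window_seconds,
            samples=rec.data[i * w : (i + 1) * w],
        )
        for i in range(n_windows)
    ]


def periodogram_bins(samples: np.ndarray, rate_hz: float):
    """Frequencies and per-bin mean-square contributions, axes summed.

    Returns ``(freqs, contrib)`` where ``contrib[k]`` is the mean-square
    power (g^2) attributed to bin centre ``freqs[k]`` after per-axis mean
    removal; ``contrib.sum()`` equals the total mean-removed mean-square
    power of the segment (Parseval).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    m = x.shape[0]
    x = x - x.mean(axis=0)
    spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
    coef = np.full(spec.shape[0], 2.0)
    coef[0] = 1.0
    if m % 2 == 0:
        coef[-1] = 1.0  # Nyquist bin is not mirrored
    contrib = (coef[:, None] * spec).sum(axis=1) / m**2
    freqs = np.fft.rfftfreq(m, d=1.0 / rate_hz)
    return freqs, contrib


def band_power(samples: np.ndarray, band: FrequencyBand, rate_hz: float) -> float:
    """Axis-summed periodogram power (g^2) inside the closed band.

    Bin membership is decided by bin centre; the 0 Hz bin is excluded
    whenever ``band.lo > 0`` (and contributes nothing anyway because the
    per-axis mean is removed).
    """
    x = np.asarray(samples, dtype=float)
    m = x.shape[0]
    if m < 8:
        raise ValueError(f"segment too short for band power ({m} samples)")
    if band.hi > rate_hz / 2 + _FREQ_TOL:
        raise ValueError(f"band {band} exceeds Nyquist ({rate_hz / 2:g} Hz)")
    freqs, contrib = periodogram_bins(x, rate_hz)
    mask = (freqs >= band.lo - _FREQ_TOL) & (freqs <= band.hi + _FREQ_TOL)
    return float(contrib[mask].sum())


def compute_phase1_features(
    window: AnalysisWindow,
    bands: tuple[FrequencyBand, ...] = PHASE1_BANDS,
    rate_hz: float = 40.0,
) -> np.ndarray:
    """Band-power feature vector for one window; also stored on the window."""
    feats = np.array([band_power(window.samples, b, rate_hz) for b in bands])
    window.features = feats
    return feats


def window_feature_matrix(
    windows: list[AnalysisWindow],
    bands: tuple[FrequencyBand, ...] = PHASE1_BANDS,
    rate_hz: float = 40.0,
) -> np.ndarray:
    """Stack per-window band-power features into an (n_windows, n_bands) matrix."""
    if not windows:
        return np.empty((0, len(bands)))
    return np.vstack([compute_phase1_features(w, bands, rate_hz) for w in windows])
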