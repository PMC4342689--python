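"""Triaxial accelerometer recordings: data model and CSV/sidecar I/O.

A recording is a uniformly sampled triaxial acceleration time series in g
(1 g = 9.81 m/s^2), nominally captured at 200 Hz by a waist-worn sensor with
a ±6 g full scale. Axis semantics (which column is vertical / forward /
lateral, and with which sign) are carried explicitly because the stride
stage needs a declared forward axis.

CSV dialect: header ``time_s,ax_g,ay_g,az_g``, decimal point, comma
separator, UTF-8, one row per sample. A YAML sidecar (``<stem>.meta.yaml``)
carries patient id, sampling rate and the axis-role mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError

AXIS_NAMES = ("ax", "ay", "az")
ROLES = ("vertical", "forward", "lateral")

#: Default orientation for a waist-worn (left side) sensor: vertical axis is
#: ``ax`` and carries the +1 g gravity bias, forward is ``ay``, lateral ``az``.
DEFAULT_AXIS_ROLES: dict[str, tuple[str, int]] = {
    "vertical": ("ax", 1),
    "forward": ("ay", 1),
    "lateral": ("az", 1),
}

SENSOR_FULL_SCALE_G = 6.0

_CSV_COLUMNS = ["time_s", "ax_g", "ay_g", "az_g"]


@dataclass
class AccelerometerRecording:
    """Uniformly sampled triaxial acceleration in g.

    Parameters
    ----------
    patient_id : str
    sampling_rate_hz : float
        Nominal sampling rate; timestamps must agree with it to within a
        1% median deviation.
    time : (n,) float array, seconds, strictly increasing.
    data : (n, 3) float array, acceleration in g, columns ``ax, ay, az``.
    axis_roles : mapping role -> (axis name, sign)
        Bijection of {vertical, forward, lateral} onto {ax, ay, az}.
    """

    patient_id: str
    sampling_rate_hz: float
    time: np.ndarray
    data: np.ndarray
    axis_roles: dict[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_AXIS_ROLES)
    )
    range_violations: int = 0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise DataError("data must be an (n, 3) array")
        if self.time.shape[0] != self.data.shape[0]:
            raise DataError("time and data length mismatch")
        if self.sampling_rate_hz <= 0:
            raise DataError("sampling_rate_hz must be positive")
        self._validate_axis_roles()
        self._validate_time()
        self._check_range()

    def _validate_axis_roles(self):
        if set(self.axis_roles) != set(ROLES):
            raise DataError(f"axis_roles must map exactly {ROLES}")
        axes = [a for a, _ in self.axis_roles.values()]
        if sorted(axes) != sorted(AXIS_NAMES):
            raise DataError("axis_roles must be a bijection onto (ax, ay, az)")
        for role, (axis, sign) in self.axis_roles.items():
            if sign not in (-1, 1):
                raise DataError(f"axis sign for {role!r} must be ±1")

    def _validate_time(self):
        if len(self.time) < 2:
            return
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise DataError("timestamps must be strictly increasing")
        nominal = 1.0 / self.sampling_rate_hz
        if abs(np.median(dt) - nominal) > 0.01 * nominal:
            raise DataError(
                "sample spacing inconsistent with sampling_rate_hz "
                f"(median dt {np.median(dt):.6g}s vs nominal {nominal:.6g}s)"
            )

    def _check_range(self):
        # Sensor full scale is ±6 g; excursions are flagged, never silently kept.
        bad = int(np.sum(np.abs(self.data) > SENSOR_FULL_SCALE_G))
        if bad:
            warnings.warn(
                f"{bad} samples exceed the ±{SENSOR_FULL_SCALE_G:g} g sensor "
                "full scale",
                stacklevel=3,
            )
        self.range_violations = bad

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        if self.n_samples == 0:
            return 0.0
        return self.n_samples / self.sampling_rate_hz

    def axis(self, role: str) -> np.ndarray:
        """Signed 1-D signal for a semantic axis role (vertical/forward/lateral)."""
        name, sign = self.axis_roles[role]
        return sign * self.data[:, AXIS_NAMES.index(name)]


# ----------------------------------------------------------------------
# File I/O


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix("").with_suffix(".meta.yaml")


def save_recording(rec: AccelerometerRecording, path: str | Path) -> None:
    """Write the CSV dialect plus the YAML metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": rec.time,
            "ax_g": rec.data[:, 0],
            "ay_g": rec.data[:, 1],
            "az_g": rec.data[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    meta = {
        "patient_id": rec.patient_id,
        "sampling_rate_hz": float(rec.sampling_rate_hz),
        "axis_roles": {
            role: {"axis": axis, "sign": int(sign)}
            for role, (axis, sign) in rec.axis_roles.items()
        },
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def load_recording(
    path: str | Path,
    *,
    patient_id: str | None = None,
    sampling_rate_hz: float | None = None,
    axis_roles: dict[str, tuple[str, int]] | None = None,
) -> AccelerometerRecording:
    """Read a recording from the CSV dialect.

    Metadata comes from the YAML sidecar when present; keyword arguments
    override it. Without either, sampling rate is inferred from the median
    timestamp spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        try:
            meta = yaml.safe_load(sidecar.read_text()) or {}
        except yaml.YAMLError as exc:
            raise FormatError(f"bad metadata sidecar {sidecar}: {exc}") from exc

    if patient_id is None:
        patient_id = meta.get("patient_id", path.stem)
    if sampling_rate_hz is None:
        sampling_rate_hz = meta.get("sampling_rate_hz")
    if axis_roles is None and "axis_roles" in meta:
        axis_roles = {
            role: (spec["axis"], int(spec["sign"]))
            for role, spec in meta["axis_roles"].items()
        }

    t = df["time_s"].to_numpy(dtype=float)
    if sampling_rate_hz is None:
        if len(t) < 2:
            raise FormatError(f"{path}: cannot infer sampling rate from <2 samples")
        sampling_rate_hz = 1.0 / float(np.median(np.diff(t)))

    return AccelerometerRecording(
        patient_id=str(patient_id),
        sampling_rate_hz=float(sampling_rate_hz),
        time=t,
        data=df[["ax_g", "ay_g", "az_g"]].to_numpy(dtype=float),
        axis_roles=axis_roles or dict(DEFAULT_AXIS_ROLES),
    )
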