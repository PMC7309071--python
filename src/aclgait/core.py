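"""Shared domain types for the run-and-sidestep IMU pipeline.

Conventions used throughout the package:

* acceleration is expressed in g, angular rate in deg/s (the sensing
  ranges of the emulated hardware are +/-16 g and +/-2000 deg/s);
* axes follow the anatomical convention x = mediolateral,
  y = anteroposterior, z = vertical, so the y-z plane is the sagittal
  plane;
* the four sensor sites are the left/right shank and left/right thigh.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

SENSOR_IDS = ("left_shank", "left_thigh", "right_shank", "right_thigh")
LIMBS = ("left", "right")

ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0


class MonotonicityError(ValueError):
    """Raised when a timestamp vector is not strictly increasing."""


@dataclass
class ImuRecording:
    """One sensor's time-stamped tri-axial streams for one repetition.

    Parameters
    ----------
    sensor_id : str
        One of :data:`SENSOR_IDS`.
    t : ndarray, shape (n,)
        Sample times in seconds on the sensor's own clock; strictly
        increasing but not necessarily uniform.
    accel : ndarray, shape (n, 3)
        Tri-axial acceleration in g.
    gyro : ndarray, shape (n, 3)
        Tri-axial angular rate in deg/s.
    nominal_rate : float
        Nominal sampling rate in Hz (the hardware samples at 100 Hz).
    """

    sensor_id: str
    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    nominal_rate: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def validate(self) -> None:
        """Check the recording invariants, raising on violation."""
        if self.sensor_id not in SENSOR_IDS:
            raise ValueError(f"unknown sensor_id {self.sensor_id!r}")
        if self.t.ndim != 1 or self.t.size < 2:
            raise ValueError("need at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise MonotonicityError(
                f"timestamps not strictly increasing at index {idx + 1}"
            )
        if self.accel.shape != (self.t.size, 3) or self.gyro.shape != (self.t.size, 3):
            raise ValueError("accel/gyro must have shape (n_samples, 3)")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("non-finite timestamps")
        if np.nanmax(np.abs(self.accel)) > ACCEL_RANGE_G + 1e-9:
            raise ValueError("acceleration exceeds +/-16 g sensing range")
        if np.nanmax(np.abs(self.gyro)) > GYRO_RANGE_DPS + 1e-9:
            raise ValueError("angular rate exceeds +/-2000 deg/s sensing range")


@dataclass
class GroundTruth:
    """Programmed quantities carried alongside a synthetic repetition.

    All event times are expressed in true (scenario) time, before any
    per-sensor clock distortion is applied.
    """

    squat_time: float
    # per limb: initial/terminal contacts of every programmed stride unit
    ic: Dict[str, np.ndarray] = field(default_factory=dict)
    tc: Dict[str, np.ndarray] = field(default_factory=dict)
    gct: Dict[str, np.ndarray] = field(default_factory=dict)
    stance_pct: Dict[str, np.ndarray] = field(default_factory=dict)
    clock_offset: Dict[str, float] = field(default_factory=dict)
    clock_rate_error: Dict[str, float] = field(default_factory=dict)
    shank_yaw_deg: Dict[str, float] = field(default_factory=dict)
    sidestep_time: Optional[float] = None
    corrupted_strides: Dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class Repetition:
    """Four aligned recordings plus trial metadata for one run."""

    subject_id: str
    cohort: str  # "healthy" | "acl"
    trial_index: int
    direction: str  # sidestep direction, "left" | "right"
    recordings: Dict[str, ImuRecording]
    truth: Optional[GroundTruth] = None

    def validate(self) -> None:
        if set(self.recordings) != set(SENSOR_IDS):
            raise ValueError("repetition must contain all four sensors")
        for rec in self.recordings.values():
            rec.validate()


@dataclass
class AlignedRepetition:
    """Preprocessed repetition: shared uniform time base, frame-consistent.

    ``signals[sensor_id]`` maps to ``{"accel": (n, 3), "gyro": (n, 3)}``
    arrays sampled on the common grid ``t``; ``offsets`` records the
    per-sensor time shift applied during squat synchronization and
    ``rotations`` the yaw rotation applied to each shank sensor.
    """

    t: np.ndarray
    rate: float
    signals: Dict[str, Dict[str, np.ndarray]]
    offsets: Dict[str, float]
    rotations: Dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def gyro(self, sensor_id: str) -> np.ndarray:
        return self.signals[sensor_id]["gyro"]

    def accel(self, sensor_id: str) -> np.ndarray:
        return self.signals[sensor_id]["accel"]


STRIDE_COLUMNS = [
    "limb",
    "initial_contact",
    "terminal_contact",
    "next_initial_contact",
    "gct",
    "stp",
    "swp",
    "rstp",
    "rswp",
    "cadence",
]


def empty_stride_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=("object" if c == "limb" else float))
                         for c in STRIDE_COLUMNS})


def check_stride_invariants(table: pd.DataFrame, atol: float = 1e-9) -> None:
    """Assert the per-row stride-table identities.

    STP + SWP = GCT, rSTP + rSWP = 100, cadence = 1/GCT and the event
    ordering IC < TC < next IC must hold on every row.
    """
    if len(table) == 0:
        return
    if not np.allclose(table["stp"] + table["swp"], table["gct"], atol=atol):
        raise AssertionError("STP + SWP != GCT")
    if not np.allclose(table["rstp"] + table["rswp"], 100.0, atol=atol):
        raise AssertionError("rSTP + rSWP != 100%")
    if not np.allclose(table["cadence"], 1.0 / table["gct"], atol=atol):
        raise AssertionError("cadence != 1/GCT")
    ordered = (
        (table["initial_contact"] < table["terminal_contact"])
        & (table["terminal_contact"] < table["next_initial_contact"])
    )
    if not bool(ordered.all()):
        raise AssertionError("event ordering violated (IC < TC < next IC)")
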