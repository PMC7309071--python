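"""Synthetic multi-sensor IMU generator for the run-and-sidestep task.

Each generated repetition emulates the study protocol: a deep squat used
for temporal synchronization of the four sensors, a short run towards a
sidestep board, a 45-degree sidestep to the left or right, and a
deceleration to a stop.  Two cohorts are generated — healthy controls and
post-ACL athletes whose affected (by default left) limb carries longer
gait cycle times, a lower cadence and rougher high-frequency acceleration
content.

The stride waveform is a documented template, not a biomechanical
simulation: the mediolateral shank angular rate is modelled as one
dominant positive mid-swing lobe flanked by smaller negative lobes at
initial and terminal contact, which is the morphology shank gyroscopes
show in running and the shape the gait event detector keys on.  Ground
truth (programmed contact times, stride parameters, clock offsets, shank
mounting yaw) is carried alongside every repetition so downstream stages
can be tested against an oracle.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

from .core import (
    ACCEL_RANGE_G,
    GYRO_RANGE_DPS,
    GroundTruth,
    ImuRecording,
    Repetition,
    SENSOR_IDS,
)

__all__ = [
    "CohortSpec",
    "SubjectData",
    "Dataset",
    "generate_repetition",
    "generate_cohorts",
]


def _default_gct_means() -> Dict[Tuple[str, str], float]:
    # per-(cohort, limb) gait-cycle-time means in seconds
    return {
        ("acl", "left"): 0.514,
        ("acl", "right"): 0.503,
        ("healthy", "left"): 0.490,
        ("healthy", "right"): 0.509,
    }


def _default_stance_means() -> Dict[Tuple[str, str], float]:
    # per-(cohort, limb) relative stance phase means in % of GCT
    return {
        ("acl", "left"): 44.75,
        ("acl", "right"): 44.70,
        ("healthy", "left"): 43.40,
        ("healthy", "right"): 45.35,
    }


@dataclass
class CohortSpec:
    """Study-condition parameters for the synthetic cohorts.

    The gait-cycle-time and stance-percentage cell means default to the
    group/limb descriptives of the emulated study population; cadence is
    1/GCT by definition, so the cadence contrast between cohorts follows
    from the GCT cells.  ``jerk_roughness_scale`` multiplies the
    band-limited (>6 Hz) acceleration noise on the affected limb of the
    post-ACL cohort only.
    """

    n_subjects_per_group: int = 6
    affected_side: str = "left"
    gct_mean: Dict[Tuple[str, str], float] = field(default_factory=_default_gct_means)
    stance_pct_mean: Dict[Tuple[str, str], float] = field(
        default_factory=_default_stance_means
    )
    gct_sd_within: float = 0.085       # s, stride-to-stride
    gct_sd_between: float = 0.030      # s, subject-to-subject
    stance_sd_within: float = 6.0      # % of GCT
    stance_sd_between: float = 2.0     # % of GCT
    n_strides: int = 4                 # complete IC->IC cycles per limb
    n_repetitions_per_subject: int = 10  # 5 left + 5 right sidesteps
    jerk_roughness_scale: float = 1.5  # multiplier on affected-limb HF accel
    base_hf_accel_sd: float = 0.03     # g, >6 Hz band noise on every limb
    noise_sd_accel: float = 0.04       # g, white measurement noise
    noise_sd_gyro: float = 4.0         # deg/s, white measurement noise
    squat_depth_g: float = 0.5
    squat_duration_s: float = 1.5
    squat_center_s: float = 1.2
    run_start_s: float = 2.4
    clock_offset_range_s: float = 0.5  # per-sensor offset ~ U(-r, r)
    clock_rate_error: float = 0.01     # per-sensor rate error ~ U(-e, e)
    time_jitter_sd_s: float = 0.001
    shank_yaw_range_deg: float = 15.0  # mounting yaw ~ U(-r, r) per shank
    sidestep_stride: Optional[int] = 2  # left-limb stride index of the cut
    sidestep_gyro_amp: float = 150.0   # deg/s transient on both shanks
    rate: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        scalars = [
            self.gct_sd_within, self.gct_sd_between, self.stance_sd_within,
            self.stance_sd_between, self.jerk_roughness_scale,
            self.base_hf_accel_sd, self.noise_sd_accel, self.noise_sd_gyro,
            self.squat_depth_g, self.squat_duration_s, self.squat_center_s,
            self.run_start_s, self.clock_offset_range_s, self.clock_rate_error,
            self.time_jitter_sd_s, self.shank_yaw_range_deg,
            self.sidestep_gyro_amp, self.rate,
        ] + list(self.gct_mean.values()) + list(self.stance_pct_mean.values())
        if not all(np.isfinite(v) for v in scalars):
            raise ValueError("CohortSpec contains non-finite values")
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")
        for v in self.gct_mean.values():
            if v <= 0:
                raise ValueError("gait cycle times must be positive")
        for v in self.stance_pct_mean.values():
            if not 0.0 < v < 100.0:
                raise ValueError("stance fraction must lie in (0, 100)%")
        if self.squat_duration_s <= 0 or self.rate <= 0:
            raise ValueError("durations and rate must be positive")
        if self.n_repetitions_per_subject < 1:
            raise ValueError("need at least one repetition per subject")
        if self.n_strides < 1:
            raise ValueError("need at least one stride per limb")


@dataclass
class SubjectData:
    subject_id: str
    cohort: str
    repetitions: List[Repetition]


@dataclass
class Dataset:
    spec: CohortSpec
    subjects: List[SubjectData]

    @property
    def n_repetitions(self) -> int:
        return sum(len(s.repetitions) for s in self.subjects)

    def iter_repetitions(self):
        for subj in self.subjects:
            yield from subj.repetitions


# ----------------------------------------------------------------------
# deterministic RNG plumbing

def _subject_seed(seed: int, subject_id: str) -> List[int]:
    return [seed & 0x7FFFFFFF, zlib.crc32(subject_id.encode())]


def _subject_rng(spec: CohortSpec, subject_id: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(_subject_seed(spec.seed, subject_id)))


def _trial_rng(spec: CohortSpec, subject_id: str, trial_index: int) -> np.random.Generator:
    entropy = _subject_seed(spec.seed, subject_id) + [trial_index + 1, 7]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class _SubjectEffects:
    gct_shift: float
    stance_shift: float
    roughness_mult: float
    directions: np.ndarray  # sidestep direction per trial


def _draw_subject_effects(spec: CohortSpec, subject_id: str) -> _SubjectEffects:
    rng = _subject_rng(spec, subject_id)
    gct_shift = rng.normal(0.0, spec.gct_sd_between)
    stance_shift = rng.normal(0.0, spec.stance_sd_between)
    roughness_mult = float(np.exp(rng.normal(0.0, 0.1)))
    n = spec.n_repetitions_per_subject
    dirs = np.array(["left", "right"])[np.arange(n) % 2]
    rng.shuffle(dirs)
    return _SubjectEffects(gct_shift, stance_shift, roughness_mult, dirs)


# ----------------------------------------------------------------------
# waveform primitives

def _gauss(t: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    """Sum of unit Gaussian lobes at ``centers`` with sd ``width``."""
    if len(centers) == 0:
        return np.zeros_like(t)
    d = (t[:, None] - np.asarray(centers)[None, :]) / width
    return np.exp(-0.5 * d**2).sum(axis=1)


def _smooth_window(t: np.ndarray, start: float, stop: float, tau: float = 0.1) -> np.ndarray:
    """Differentiable on/off envelope over [start, stop]."""
    rise = 1.0 / (1.0 + np.exp(-(t - start) / tau))
    fall = 1.0 / (1.0 + np.exp((t - stop) / tau))
    return rise * fall


@dataclass
class _Scenario:
    """Deterministic event layout and per-sensor continuous signal model."""

    spec: CohortSpec
    cohort: str
    direction: str
    ic: Dict[str, np.ndarray]
    tc: Dict[str, np.ndarray]
    gct: Dict[str, np.ndarray]
    stance_pct: Dict[str, np.ndarray]
    midswing: Dict[str, np.ndarray]
    sidestep_time: Optional[float]
    phases: Dict[str, float]
    duration: float

    def _envelope(self, tau: np.ndarray, limb: str) -> np.ndarray:
        start = self.ic[limb][0] - 0.25
        stop = self.ic[limb][-1] + 0.35
        return _smooth_window(tau, start, stop)

    def flexion(self, tau: np.ndarray, limb: str) -> np.ndarray:
        """Mediolateral (x) angular-rate stride template for one limb."""
        out = 320.0 * _gauss(tau, self.midswing[limb], 0.045)
        out -= 120.0 * _gauss(tau, self.ic[limb], 0.020)
        out -= 160.0 * _gauss(tau, self.tc[limb], 0.020)
        if self.sidestep_time is not None and self.spec.sidestep_gyro_amp:
            t0 = self.sidestep_time
            burst = np.sin(2 * np.pi * 9.0 * (tau - t0)) * _gauss(tau, np.array([t0]), 0.08)
            out += self.spec.sidestep_gyro_amp * burst
        return out

    def perp_gyro(self, tau: np.ndarray, limb: str) -> Tuple[np.ndarray, np.ndarray]:
        """Rigid leg-swing angular rate perpendicular to the flexion axis.

        Shared between the shank and thigh of one limb so that a hinge
        joint-axis estimator can match the two sensors' non-flexion
        angular-rate magnitudes.
        """
        env = self._envelope(tau, limb)
        p1, p2 = self.phases[limb + "_y"], self.phases[limb + "_z"]
        gy = 60.0 * np.sin(2 * np.pi * 2.0 * tau + p1) * env
        gz = 45.0 * np.sin(2 * np.pi * 1.4 * tau + p2) * env
        return gy, gz

    def squat_dip(self, tau: np.ndarray) -> np.ndarray:
        spec = self.spec
        t0 = spec.squat_center_s - spec.squat_duration_s / 2
        inside = (tau >= t0) & (tau <= t0 + spec.squat_duration_s)
        dip = np.zeros_like(tau)
        ph = (tau[inside] - t0) / spec.squat_duration_s
        dip[inside] = -spec.squat_depth_g * 0.5 * (1 - np.cos(2 * np.pi * ph))
        return dip

    def eval_sensor(self, sensor_id: str, tau: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Noise-free anatomical-frame accel (g) and gyro (deg/s)."""
        spec = self.spec
        limb = "left" if sensor_id.startswith("left") else "right"
        is_shank = sensor_id.endswith("shank")
        env = self._envelope(tau, limb)
        cadence = 1.0 / float(np.mean(self.gct[limb]))
        ph = self.phases[limb + "_y"]

        flex = self.flexion(tau, limb)
        gy, gz = self.perp_gyro(tau, limb)
        gx = flex if is_shank else 0.35 * flex
        gyro = np.column_stack([gx, gy, gz])

        impact_amp = 1.5 if is_shank else 0.8
        az = (
            1.0
            + self.squat_dip(tau)
            + impact_amp * _gauss(tau, self.ic[limb], 0.015)
            + 0.25 * np.sin(2 * np.pi * cadence * tau + ph) * env
        )
        ay = (
            0.30 * np.sin(2 * np.pi * cadence * tau + ph + 0.8) * env
            + 0.5 * _gauss(tau, self.tc[limb], 0.03)
        )
        ax = 0.15 * np.sin(2 * np.pi * cadence * tau + ph + 1.9) * env
        if self.sidestep_time is not None:
            sign = 1.0 if self.direction == "left" else -1.0
            ax = ax + sign * 1.2 * _gauss(tau, np.array([self.sidestep_time]), 0.10)
        # deceleration tail after the final contact
        t_end = self.ic[limb][-1] + 0.2
        tail = (tau > t_end) * np.exp(-np.clip(tau - t_end, 0, None) / 0.4)
        ay = ay - 0.5 * tail * np.sin(2 * np.pi * 3.0 * (tau - t_end))
        accel = np.column_stack([ax, ay, az])
        return accel, gyro


def _build_scenario(
    spec: CohortSpec,
    cohort: str,
    effects: _SubjectEffects,
    rng: np.random.Generator,
    direction: str,
) -> _Scenario:
    ic: Dict[str, np.ndarray] = {}
    tc: Dict[str, np.ndarray] = {}
    gct: Dict[str, np.ndarray] = {}
    stance: Dict[str, np.ndarray] = {}
    midswing: Dict[str, np.ndarray] = {}
    n_units = spec.n_strides + 1  # one extra IC closes the last cycle

    first_left_gct = spec.gct_mean[(cohort, "left")] + effects.gct_shift
    for limb in ("left", "right"):
        mu_gct = spec.gct_mean[(cohort, limb)] + effects.gct_shift
        mu_st = spec.stance_pct_mean[(cohort, limb)] + effects.stance_shift
        g = rng.normal(mu_gct, spec.gct_sd_within, n_units)
        g = np.clip(g, 0.30, 0.85)
        s = rng.normal(mu_st, spec.stance_sd_within, n_units)
        s = np.clip(s, 25.0, 75.0)
        start = spec.run_start_s + (0.0 if limb == "left" else first_left_gct / 2)
        contacts = start + np.concatenate([[0.0], np.cumsum(g[:-1])])
        ic[limb] = contacts
        gct[limb] = g
        stance[limb] = s
        tc[limb] = contacts + s / 100.0 * g
        midswing[limb] = (tc[limb][:-1] + contacts[1:]) / 2.0

    sidestep_time = None
    if spec.sidestep_stride is not None:
        k = min(spec.sidestep_stride, spec.n_strides - 1)
        sidestep_time = float(midswing["left"][k])

    phases = {
        "left_y": rng.uniform(0, 2 * np.pi),
        "left_z": rng.uniform(0, 2 * np.pi),
        "right_y": rng.uniform(0, 2 * np.pi),
        "right_z": rng.uniform(0, 2 * np.pi),
    }
    duration = max(ic["left"][-1], ic["right"][-1]) + 1.2
    return _Scenario(
        spec, cohort, direction, ic, tc, gct, stance, midswing,
        sidestep_time, phases, duration,
    )


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _highpass_noise(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    """Band-limited (>6 Hz) roughness noise, unit design sd scaled to ``sd``."""
    if sd <= 0 or n < 30:
        return np.zeros(n)
    white = rng.normal(0.0, 1.0, n)
    b, a = butter(2, 6.0 / (rate / 2), btype="highpass")
    hp = filtfilt(b, a, white)
    s = hp.std()
    return hp / s * sd if s > 0 else hp


def _cohort_of(subject_id: str) -> str:
    if subject_id.startswith("acl"):
        return "acl"
    if subject_id.startswith("healthy"):
        return "healthy"
    raise ValueError(f"cannot infer cohort from subject id {subject_id!r}")


def generate_repetition(
    spec: CohortSpec,
    subject_id: str,
    trial_index: int,
    direction: Optional[str] = None,
    cohort: Optional[str] = None,
) -> Repetition:
    """Generate one four-sensor repetition with ground truth attached.

    All randomness derives deterministically from ``spec.seed``, the
    subject id and the trial index, so the same call is bit-reproducible.
    """
    spec.validate()
    if trial_index >= spec.n_repetitions_per_subject:
        raise ValueError("trial_index beyond n_repetitions_per_subject")
    cohort = cohort or _cohort_of(subject_id)
    effects = _draw_subject_effects(spec, subject_id)
    if direction is None:
        direction = str(effects.directions[trial_index])
    rng = _trial_rng(spec, subject_id, trial_index)
    scen = _build_scenario(spec, cohort, effects, rng, direction)

    truth = GroundTruth(
        squat_time=spec.squat_center_s,
        ic={l: scen.ic[l].copy() for l in ("left", "right")},
        tc={l: scen.tc[l].copy() for l in ("left", "right")},
        gct={l: scen.gct[l].copy() for l in ("left", "right")},
        stance_pct={l: scen.stance_pct[l].copy() for l in ("left", "right")},
        sidestep_time=scen.sidestep_time,
    )
    if scen.sidestep_time is not None:
        for limb in ("left", "right"):
            lo = scen.sidestep_time - 0.25
            hi = scen.sidestep_time + 0.25
            hit = np.nonzero((scen.ic[limb][:-1] < hi) & (scen.ic[limb][1:] > lo))[0]
            truth.corrupted_strides[limb] = hit

    rough_scale = {"left": 1.0, "right": 1.0}
    if cohort == "acl":
        rough_scale[spec.affected_side] = spec.jerk_roughness_scale * effects.roughness_mult

    recordings: Dict[str, ImuRecording] = {}
    for sensor_id in SENSOR_IDS:
        limb = "left" if sensor_id.startswith("left") else "right"
        offset = rng.uniform(-spec.clock_offset_range_s, spec.clock_offset_range_s)
        eps = rng.uniform(-spec.clock_rate_error, spec.clock_rate_error)
        truth.clock_offset[sensor_id] = offset
        truth.clock_rate_error[sensor_id] = eps

        dt = 1.0 / spec.rate
        t_end = (1.0 + eps) * (scen.duration + offset)
        n = max(int(np.floor(t_end / dt)) + 1, 2)
        t = np.arange(n) * dt
        if spec.time_jitter_sd_s > 0:
            jit = np.clip(rng.normal(0, spec.time_jitter_sd_s, n), -0.3 * dt, 0.3 * dt)
            jit[0] = 0.0
            t = t + jit
            t = np.maximum.accumulate(t + np.arange(n) * 1e-12)
        tau = t / (1.0 + eps) - offset

        accel, gyro = scen.eval_sensor(sensor_id, tau)
        hf_sd = spec.base_hf_accel_sd * rough_scale[limb]
        for axis in range(3):
            accel[:, axis] += _highpass_noise(rng, n, spec.rate, hf_sd)
        if spec.noise_sd_accel > 0:
            accel += rng.normal(0, spec.noise_sd_accel, accel.shape)
        if spec.noise_sd_gyro > 0:
            gyro += rng.normal(0, spec.noise_sd_gyro, gyro.shape)

        if sensor_id.endswith("shank") and spec.shank_yaw_range_deg > 0:
            yaw = rng.uniform(-spec.shank_yaw_range_deg, spec.shank_yaw_range_deg)
        else:
            yaw = 0.0
        truth.shank_yaw_deg[sensor_id] = yaw
        if yaw != 0.0:
            # sensor frame yawed by +yaw relative to anatomy: measured
            # vectors are the anatomical ones rotated by -yaw
            R = _rot_z(-np.deg2rad(yaw))
            accel = accel @ R.T
            gyro = gyro @ R.T

        accel = np.clip(accel, -ACCEL_RANGE_G, ACCEL_RANGE_G)
        gyro = np.clip(gyro, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
        recordings[sensor_id] = ImuRecording(sensor_id, t, accel, gyro, spec.rate)

    rep = Repetition(subject_id, cohort, trial_index, direction, recordings, truth)
    rep.validate()
    return rep


def _null_spec(spec: CohortSpec) -> CohortSpec:
    """Variant with identical group distributions (no asymmetry at all)."""
    gct = float(np.mean(list(spec.gct_mean.values())))
    st = float(np.mean(list(spec.stance_pct_mean.values())))
    return replace(
        spec,
        gct_mean={k: gct for k in spec.gct_mean},
        stance_pct_mean={k: st for k in spec.stance_pct_mean},
        jerk_roughness_scale=1.0,
    )


# drop-outs emulating the study's six failed recordings: (cohort, subject
# index, trial index); 4 post-ACL and 2 healthy repetitions
_DROPOUTS = [
    ("acl", 0, 3), ("acl", 1, 7), ("acl", 3, 1), ("acl", 4, 9),
    ("healthy", 2, 5), ("healthy", 5, 0),
]


def generate_cohorts(
    spec: CohortSpec,
    null: bool = False,
    dropout: bool = False,
) -> Dataset:
    """Generate the balanced two-cohort dataset.

    Parameters
    ----------
    null : bool
        If True, both cohorts are drawn from identical distributions
        (group label independent of the signals by construction) — used
        for chance-level classifier checks.
    dropout : bool
        If True, remove six fixed repetitions (4 post-ACL, 2 healthy),
        mimicking recording failures, leaving 58 healthy + 56 post-ACL
        sets at the default cohort sizes.
    """
    spec.validate()
    gen_spec = _null_spec(spec) if null else spec
    drop = {(c, s, t) for (c, s, t) in _DROPOUTS} if dropout else set()
    subjects: List[SubjectData] = []
    for cohort in ("healthy", "acl"):
        for s in range(spec.n_subjects_per_group):
            sid = f"{cohort}_{s:02d}"
            reps = [
                generate_repetition(gen_spec, sid, trial, cohort=cohort)
                for trial in range(spec.n_repetitions_per_subject)
                if (cohort, s, trial) not in drop
            ]
            subjects.append(SubjectData(sid, cohort, reps))
    return Dataset(spec=gen_spec, subjects=subjects)
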