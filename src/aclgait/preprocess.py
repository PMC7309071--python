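"""Temporal alignment and frame normalization of raw IMU streams.

Three stages turn the four raw per-sensor streams of a repetition into
signals a gait or feature extractor can consume:

1. uniform resampling of each sensor onto an arithmetic time grid
   (sensor clocks drift and sample times jitter);
2. temporal synchronization across sensors using the deep-squat
   signature recorded at the start of every repetition (the minimum of
   the 1 Hz-low-passed vertical acceleration in the leading window, with
   sub-sample parabolic refinement);
3. rotation of each shank sensor about the vertical axis so that its
   x-axis coincides with the knee flexion (mediolateral) axis, using a
   hinge-joint gyroscope cost: the angular-rate magnitude perpendicular
   to the true joint axis must agree between the shank and thigh
   sensors of the same leg.  The cost is minimized by damped
   Gauss-Newton on the unit sphere with multiple axis seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import butter, filtfilt

from .core import AlignedRepetition, ImuRecording, MonotonicityError, Repetition, SENSOR_IDS

__all__ = [
    "resample_uniform",
    "detect_squat_sync",
    "estimate_flexion_axis",
    "align_shank_frame",
    "align_repetition",
    "SquatSyncError",
    "ConvergenceError",
    "SeelResult",
]


class SquatSyncError(RuntimeError):
    """No squat signature found in the synchronization window."""


class ConvergenceError(RuntimeError):
    """Axis optimization failed to converge within the iteration cap."""


def resample_uniform(rec: ImuRecording, target_rate: float) -> ImuRecording:
    """Resample a recording onto an arithmetic grid at ``target_rate``.

    The output grid starts at ``rec.t[0]`` and spans the input range with
    ``floor(span * rate) + 1`` samples; channels are piecewise-linearly
    interpolated.
    """
    rec.validate()  # raises MonotonicityError naming the offending index
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    span = rec.t[-1] - rec.t[0]
    n = int(np.floor(span * target_rate)) + 1
    grid = rec.t[0] + np.arange(n) / target_rate
    accel = np.column_stack([np.interp(grid, rec.t, rec.accel[:, k]) for k in range(3)])
    gyro = np.column_stack([np.interp(grid, rec.t, rec.gyro[:, k]) for k in range(3)])
    return ImuRecording(rec.sensor_id, grid, accel, gyro, target_rate)


def _parabolic_refine(y: np.ndarray, idx: int) -> float:
    """Sub-sample offset of an extremum via a 3-point parabola fit."""
    if idx <= 0 or idx >= len(y) - 1:
        return 0.0
    denom = y[idx - 1] - 2 * y[idx] + y[idx + 1]
    if abs(denom) < 1e-30:
        return 0.0
    return float(0.5 * (y[idx - 1] - y[idx + 1]) / denom)


def _squat_feature_time(
    rec: ImuRecording,
    window_s: float,
    cutoff_hz: float,
    min_depth_g: float,
) -> float:
    uni = rec if _is_uniform(rec) else resample_uniform(rec, rec.nominal_rate)
    rate = uni.nominal_rate
    n_win = min(int(window_s * rate) + 1, uni.n_samples)
    if n_win < 20:
        raise SquatSyncError("synchronization window too short")
    az = uni.accel[:n_win, 2]
    b, a = butter(4, cutoff_hz / (rate / 2), btype="lowpass")
    if len(az) <= 3 * max(len(a), len(b)):
        raise SquatSyncError("window shorter than filter warm-up")
    low = filtfilt(b, a, az)
    idx = int(np.argmin(low))
    depth = float(np.median(low) - low[idx])
    if depth < min_depth_g:
        raise SquatSyncError(
            f"squat feature score {depth:.3f} g below threshold {min_depth_g} g"
        )
    frac = _parabolic_refine(low, idx)
    return float(uni.t[0] + (idx + frac) / rate)


def _is_uniform(rec: ImuRecording, rtol: float = 1e-9) -> bool:
    dt = np.diff(rec.t)
    return bool(np.allclose(dt, dt[0], rtol=rtol, atol=1e-12))


def detect_squat_sync(
    recordings: Sequence[ImuRecording],
    window_s: float = 5.0,
    cutoff_hz: float = 1.0,
    min_depth_g: float = 0.15,
) -> np.ndarray:
    """Per-sensor time offsets aligning the squat signatures.

    The first recording is the reference (offset 0); subtracting
    ``offsets[i]`` from recording *i*'s timestamps brings its squat
    feature in coincidence with the reference's.
    """
    if len(recordings) < 2:
        raise ValueError("need at least two recordings to synchronize")
    times = [
        _squat_feature_time(rec, window_s, cutoff_hz, min_depth_g)
        for rec in recordings
    ]
    return np.asarray(times) - times[0]


# ----------------------------------------------------------------------
# hinge-axis estimation (gyroscope-only functional calibration)

@dataclass
class SeelResult:
    axis: np.ndarray          # estimated flexion axis in the shank frame
    rotation: np.ndarray      # yaw rotation mapping sensor -> anatomical
    yaw_deg: float            # rotation angle about the vertical axis
    cost: float
    n_iter: int
    converged: bool
    confident: bool
    anisotropy: float


def _tangent_basis(j: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(j[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(j, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(j, e1)
    return e1, e2


def estimate_flexion_axis(
    shank_gyro: np.ndarray,
    thigh_gyro: np.ndarray,
    thigh_axis: Sequence[float] = (1.0, 0.0, 0.0),
    max_iter: int = 200,
    tol: float = 1e-10,
    anisotropy_threshold: float = 3.0,
) -> SeelResult:
    """Estimate the knee flexion axis in the shank sensor frame.

    Minimizes ``sum_t (|w_shank(t) x j| - |w_thigh(t) x j_thigh|)^2``
    over unit vectors ``j`` by damped Gauss-Newton on the sphere,
    multi-started from the six signed coordinate axes.  The thigh axis
    is taken as known (the thigh sensor is the frame reference).
    """
    w1 = np.asarray(shank_gyro, float)
    w2 = np.asarray(thigh_gyro, float)
    if w1.shape != w2.shape or w1.ndim != 2 or w1.shape[1] != 3:
        raise ValueError("gyro arrays must be equal-shape (n, 3)")
    j2 = np.asarray(thigh_axis, float)
    j2 /= np.linalg.norm(j2)
    target = np.linalg.norm(np.cross(w2, j2), axis=1)

    # directional anisotropy of the shank rotation: flexion-dominant
    # motion concentrates angular rate along one axis
    power = (w1**2).sum(axis=1)
    scale = power.sum()
    if scale <= 0:
        raise ValueError("all-zero shank gyro")
    M = (w1.T @ w1) / scale
    ev = np.sort(np.linalg.eigvalsh(M))[::-1]
    anisotropy = float(ev[0] / max(ev[1], 1e-12))

    def cost_and_residual(j: np.ndarray):
        c = np.cross(w1, j)
        norm = np.linalg.norm(c, axis=1)
        r = norm - target
        return float((r**2).sum()), r, c, norm

    seeds = [np.eye(3)[k] * s for k in range(3) for s in (1.0, -1.0)]
    best: Optional[Tuple[float, np.ndarray, int, bool]] = None
    for j0 in seeds:
        j = j0.copy()
        lam = 1e-3
        cost, r, c, norm = cost_and_residual(j)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            safe = np.maximum(norm, 1e-12)[:, None]
            # d|w x j|/dj = ((w x j) / |w x j|) x ... via skew(w): row_i = (c_i/|c_i|)^T [w_i]_x
            u = c / safe
            J3 = np.cross(u, w1)  # (c/|c|)^T [w]_x  ==  (c/|c|) x w
            e1, e2 = _tangent_basis(j)
            J = np.column_stack([J3 @ e1, J3 @ e2])
            A = J.T @ J + lam * np.eye(2)
            g = J.T @ r
            try:
                step = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                break
            j_new = j + step[0] * e1 + step[1] * e2
            j_new /= np.linalg.norm(j_new)
            new_cost, r_new, c_new, norm_new = cost_and_residual(j_new)
            if new_cost < cost:
                improvement = cost - new_cost
                j, cost, r, c, norm = j_new, new_cost, r_new, c_new, norm_new
                lam = max(lam / 3, 1e-12)
                if improvement <= tol * max(cost, 1.0):
                    converged = True
                    break
            else:
                lam *= 10
                if lam > 1e8:
                    converged = True  # stuck in a (possibly flat) minimum
                    break
        if best is None or cost < best[0]:
            best = (cost, j, it, converged)

    cost, j, n_iter, converged = best
    if not converged:
        raise ConvergenceError(
            f"axis optimization did not converge in {max_iter} iterations "
            f"(final cost {cost:.6g})"
        )
    yaw = float(np.arctan2(j[1], j[0]))
    rotation = _rot_z(-yaw)
    confident = anisotropy >= anisotropy_threshold
    return SeelResult(j, rotation, -np.rad2deg(yaw), cost, n_iter, converged, confident, anisotropy)


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def align_shank_frame(
    shank_gyro: np.ndarray,
    thigh_gyro: np.ndarray,
    require_confident: bool = True,
    **kwargs,
) -> SeelResult:
    """Estimate the shank-to-anatomical yaw rotation and fix its sign.

    The sign convention is that the mid-swing angular rate about the
    rotated x-axis is positive: if the largest-magnitude mediolateral
    samples come out negative after rotation, the axis is flipped
    (180-degree yaw correction).
    """
    res = estimate_flexion_axis(shank_gyro, thigh_gyro, **kwargs)
    gx = np.asarray(shank_gyro, float) @ res.rotation.T[:, 0]
    strong = np.abs(gx) >= np.quantile(np.abs(gx), 0.98)
    if strong.any() and gx[strong].mean() < 0:
        yaw_deg = res.yaw_deg + 180.0
        yaw_deg = (yaw_deg + 180.0) % 360.0 - 180.0
        res = SeelResult(
            -res.axis, _rot_z(np.deg2rad(yaw_deg)), yaw_deg, res.cost,
            res.n_iter, res.converged, res.confident, res.anisotropy,
        )
    if require_confident and not res.confident:
        raise ConvergenceError(
            f"low-confidence flexion axis (anisotropy {res.anisotropy:.2f}, "
            f"final cost {res.cost:.6g})"
        )
    return res


def align_repetition(
    rep: Repetition,
    target_rate: float = 100.0,
    window_s: float = 5.0,
    min_depth_g: float = 0.15,
    rotate_shanks: bool = True,
) -> AlignedRepetition:
    """Full preprocessing of one repetition.

    Resamples every sensor to ``target_rate``, synchronizes them on the
    squat signature (left shank is the reference sensor), interpolates
    all four onto a common grid, and rotates each shank sensor's frame
    so its x-axis is the mediolateral/flexion axis.
    """
    rep.validate()
    order = list(SENSOR_IDS)  # left_shank first: the sync reference
    uni = {sid: resample_uniform(rep.recordings[sid], target_rate) for sid in order}
    offsets = detect_squat_sync([uni[s] for s in order], window_s=window_s,
                                min_depth_g=min_depth_g)
    offset_map = dict(zip(order, offsets))

    shifted = {}
    for sid in order:
        r = uni[sid]
        shifted[sid] = (r.t - offset_map[sid], r.accel, r.gyro)
    t0 = max(v[0][0] for v in shifted.values())
    t1 = min(v[0][-1] for v in shifted.values())
    if t1 <= t0:
        raise SquatSyncError("no overlapping time span after synchronization")
    n = int(np.floor((t1 - t0) * target_rate)) + 1
    grid = t0 + np.arange(n) / target_rate

    signals: Dict[str, Dict[str, np.ndarray]] = {}
    for sid in order:
        t, accel, gyro = shifted[sid]
        signals[sid] = {
            "accel": np.column_stack([np.interp(grid, t, accel[:, k]) for k in range(3)]),
            "gyro": np.column_stack([np.interp(grid, t, gyro[:, k]) for k in range(3)]),
        }

    rotations: Dict[str, np.ndarray] = {sid: np.eye(3) for sid in order}
    seel_meta = {}
    if rotate_shanks:
        for side in ("left", "right"):
            shank, thigh = f"{side}_shank", f"{side}_thigh"
            res = align_shank_frame(signals[shank]["gyro"], signals[thigh]["gyro"])
            rotations[shank] = res.rotation
            signals[shank]["gyro"] = signals[shank]["gyro"] @ res.rotation.T
            signals[shank]["accel"] = signals[shank]["accel"] @ res.rotation.T
            seel_meta[shank] = {
                "yaw_deg": res.yaw_deg,
                "cost": res.cost,
                "anisotropy": res.anisotropy,
            }

    return AlignedRepetition(
        t=grid,
        rate=target_rate,
        signals=signals,
        offsets=offset_map,
        rotations=rotations,
        meta={
            "subject_id": rep.subject_id,
            "cohort": rep.cohort,
            "trial_index": rep.trial_index,
            "direction": rep.direction,
            "seel": seel_meta,
        },
    )
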