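"""Gait event detection and temporal stride parameters.

Events are read off the mediolateral (x) angular rate of a shank sensor:
running gait shows one dominant positive lobe at mid-swing per stride,
flanked by negative lobes near terminal contact (before the swing) and
initial contact (after it).  The detector finds mid-swing peaks above an
adaptive threshold, then takes the last negative peak preceding each
mid-swing as terminal contact and the first negative peak following it
as initial contact.  Peak times are refined to sub-sample precision with
a three-point parabola.

Six temporal parameters are derived per complete initial-contact to
initial-contact cycle: gait cycle time (GCT), stance phase (STP), swing
phase (SWP), their percentages of the cycle (rSTP, rSWP) and cadence,
defined as 1/GCT.  A validity filter discards strides whose GCT or rSTP
fall outside configurable physiologic bounds — the run-up, braking and
sidestep transients produce such artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import STRIDE_COLUMNS, check_stride_invariants, empty_stride_table

__all__ = [
    "GaitEvents",
    "detect_gait_events",
    "compute_stride_table",
    "stride_table_for_limb",
]

# validity-filter bounds (config): strides outside are run-up/brake artifacts
GCT_BOUNDS_S = (0.2, 1.2)
RSTP_BOUNDS_PCT = (20.0, 80.0)

# mid-swing threshold: fraction of the 95th percentile of positive samples
MIDSWING_THRESHOLD_FRACTION = 0.6
REFRACTORY_S = 0.3


@dataclass
class GaitEvents:
    """Ordered event times (s) for one limb's series.

    ``midswing[k]`` lies between ``tc[k]`` (terminal contact of the
    stride being swung out of) and ``ic[k]`` (the next initial contact);
    entries are NaN where no flanking negative peak exists.
    """

    midswing: np.ndarray
    tc: np.ndarray
    ic: np.ndarray
    warning: Optional[str] = None

    @property
    def n(self) -> int:
        return len(self.midswing)


def _refine(t: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample parabolic refinement of peak sample indices."""
    out = np.empty(len(idx))
    dt = t[1] - t[0] if len(t) > 1 else 0.0
    for k, i in enumerate(idx):
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            frac = 0.5 * (y[i - 1] - y[i + 1]) / denom if abs(denom) > 1e-30 else 0.0
        else:
            frac = 0.0
        out[k] = t[i] + frac * dt
    return out


def detect_gait_events(
    gyro_x: np.ndarray,
    rate: float,
    t0: float = 0.0,
    threshold_fraction: float = MIDSWING_THRESHOLD_FRACTION,
    refractory_s: float = REFRACTORY_S,
) -> GaitEvents:
    """Detect mid-swing, terminal-contact and initial-contact events.

    Parameters
    ----------
    gyro_x : ndarray
        Uniformly sampled mediolateral shank angular rate (deg/s),
        frame-aligned so mid-swing is positive.
    rate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample; event times are absolute.
    """
    x = np.asarray(gyro_x, float)
    if x.ndim != 1:
        raise ValueError("gyro_x must be one-dimensional")
    t = t0 + np.arange(len(x)) / rate

    pos = x[x > 0]
    if pos.size == 0:
        return GaitEvents(np.array([]), np.array([]), np.array([]),
                          warning="no positive angular rate: no strides found")
    height = threshold_fraction * np.percentile(pos, 95)
    distance = max(int(refractory_s * rate), 1)
    ms_idx, _ = find_peaks(x, height=height, distance=distance)
    if ms_idx.size == 0:
        return GaitEvents(np.array([]), np.array([]), np.array([]),
                          warning="no mid-swing peaks above threshold")

    # negative peaks: local minima below zero, small prominence gate
    neg_idx, _ = find_peaks(-x, height=0.0, prominence=0.05 * height)
    ms_t = _refine(t, x, ms_idx)
    neg_t = _refine(t, -x, neg_idx)

    tc = np.full(ms_idx.size, np.nan)
    ic = np.full(ms_idx.size, np.nan)
    for k, m in enumerate(ms_t):
        before = neg_t[neg_t < m]
        after = neg_t[neg_t > m]
        if before.size:
            tc[k] = before[-1]
        if after.size:
            # first negative peak after mid-swing, but before the next mid-swing
            nxt = ms_t[k + 1] if k + 1 < ms_t.size else np.inf
            cand = after[after < nxt]
            if cand.size:
                ic[k] = cand[0]

    warning = None
    if ms_idx.size < 2:
        warning = "fewer than one complete stride detected"
    return GaitEvents(ms_t, tc, ic, warning)


def compute_stride_table(
    events: GaitEvents,
    limb: str,
    gct_bounds: tuple = GCT_BOUNDS_S,
    rstp_bounds: tuple = RSTP_BOUNDS_PCT,
    validity_filter: bool = True,
) -> pd.DataFrame:
    """Temporal parameters for every complete IC-to-IC cycle.

    A cycle spans the initial contact following mid-swing ``k`` to the
    one following mid-swing ``k+1``; its terminal contact is the
    negative peak preceding mid-swing ``k+1``.  Cycles with missing or
    mis-ordered events are dropped; the validity filter additionally
    removes strides with GCT or rSTP outside the configured bounds.
    """
    if events.n >= 2:
        if np.any(np.diff(events.midswing) <= 0):
            raise ValueError("mid-swing events are not strictly ordered")
    rows = []
    for k in range(events.n - 1):
        ic_k = events.ic[k]
        tc_next = events.tc[k + 1]
        ic_next = events.ic[k + 1]
        if not (np.isfinite(ic_k) and np.isfinite(tc_next) and np.isfinite(ic_next)):
            continue
        if not ic_k < tc_next < ic_next:
            continue
        gct = ic_next - ic_k
        stp = tc_next - ic_k
        swp = gct - stp
        rstp = 100.0 * stp / gct
        if validity_filter:
            if not gct_bounds[0] <= gct <= gct_bounds[1]:
                continue
            if not rstp_bounds[0] <= rstp <= rstp_bounds[1]:
                continue
        rows.append({
            "limb": limb,
            "initial_contact": ic_k,
            "terminal_contact": tc_next,
            "next_initial_contact": ic_next,
            "gct": gct,
            "stp": stp,
            "swp": swp,
            "rstp": rstp,
            "rswp": 100.0 - rstp,
            "cadence": 1.0 / gct,
        })
    if not rows:
        warnings.warn("no valid strides found", stacklevel=2)
        return empty_stride_table()
    table = pd.DataFrame(rows, columns=STRIDE_COLUMNS)
    check_stride_invariants(table)
    return table


def stride_table_for_limb(
    gyro_x: np.ndarray,
    rate: float,
    limb: str,
    t0: float = 0.0,
    **kwargs,
) -> pd.DataFrame:
    """Convenience wrapper: detect events and tabulate strides."""
    events = detect_gait_events(gyro_x, rate, t0=t0)
    return compute_stride_table(events, limb, **kwargs)
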