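"""Per-repetition time- and frequency-domain feature registry.

From each sensor's aligned tri-axial streams, derived signals are formed
(jerk by differentiating the acceleration, the acceleration magnitude,
and the gravity/body decomposition of the acceleration via a zero-phase
low-pass filter), and families of scalar features are computed:

* statistical features (mean, sd, skewness, kurtosis, RMS, min, max,
  peak-to-peak, coefficient of variation, IQR) on every scalar signal;
* per-triad features (pairwise Pearson correlations, per-axis signal
  energy, signal magnitude area) on the 3-axis signals;
* spectral features (dominant frequency, spectral centroid, spectral
  edge frequency, harmonic ratio, index of harmonicity) on the gyro,
  raw acceleration and jerk axes and the acceleration magnitude;
* movement-smoothness measures: log dimensionless jerk per acceleration
  axis, and sample entropy and spectral arc length (SPARC) per gyro and
  acceleration axis.

Feature names are stable and sensor-prefixed
(``left_shank__jerk_y__rms``); undefined values (e.g. spectral features
of an all-zero series) are NaN and explicitly listed in the vector's
``flagged`` set — never silently propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.signal import butter, periodogram, sosfiltfilt

from .core import AlignedRepetition, SENSOR_IDS

__all__ = [
    "decompose_gravity_body",
    "time_stats",
    "triad_stats",
    "spectral_features",
    "dimensionless_jerk",
    "log_dimensionless_jerk",
    "sample_entropy",
    "sparc",
    "FeatureVector",
    "FeatureRegistry",
    "default_registry",
    "extract_features",
]

AXES = ("x", "y", "z")

GRAVITY_CUTOFF_HZ = 0.3       # zero-phase 4th-order low-pass (config)
SEF_PERCENTILE = 0.95
HR_N_HARMONICS = 10
IOH_N_HARMONICS = 6
SPARC_FC_HZ = 10.0
SPARC_AMP_THRESHOLD = 0.05


def decompose_gravity_body(accel3: np.ndarray, rate: float,
                           cutoff_hz: float = GRAVITY_CUTOFF_HZ) -> Tuple[np.ndarray, np.ndarray]:
    """Split acceleration into gravity (low-pass) and body components.

    The gravity estimate is a zero-phase 4th-order Butterworth low-pass
    of each axis; the body component is the complement, so
    ``gravity + body == accel`` exactly.
    """
    a = np.asarray(accel3, float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("accel3 must have shape (n, 3)")
    sos = butter(4, cutoff_hz / (rate / 2), btype="lowpass", output="sos")
    padlen = 6 * sos.shape[0]
    if a.shape[0] <= padlen:
        raise ValueError(
            f"series of length {a.shape[0]} shorter than filter warm-up ({padlen + 1})"
        )
    gravity = np.column_stack([sosfiltfilt(sos, a[:, k]) for k in range(3)])
    return gravity, a - gravity


def time_stats(series: np.ndarray) -> Dict[str, float]:
    """Standard descriptive statistics of a scalar series.

    CV is sd/|mean|, undefined (NaN) when the mean is numerically zero.
    Kurtosis is the excess kurtosis (normal -> 0).
    """
    x = np.asarray(series, float)
    if x.size == 0:
        raise ValueError("empty series")
    if x.size < 4:
        raise ValueError("need at least 4 samples for kurtosis")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=0))
    cv = sd / abs(mean) if abs(mean) >= 1e-12 else np.nan
    return {
        "mean": mean,
        "sd": sd,
        "skewness": float(sps.skew(x)) if sd > 0 else 0.0,
        "kurtosis": float(sps.kurtosis(x)) if sd > 0 else 0.0,
        "rms": float(np.sqrt(np.mean(x**2))),
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "p2p": float(np.ptp(x)),
        "cv": cv,
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
    }


def triad_stats(signal3: np.ndarray) -> Dict[str, float]:
    """Pairwise correlations, per-axis energy and SMA of a 3-axis signal.

    Energy is the mean squared sample per axis; SMA is the mean over
    samples of |x|+|y|+|z|.  Correlations with a zero-variance axis are
    undefined (NaN).
    """
    s = np.asarray(signal3, float)
    if s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("signal3 must have shape (n, 3)")
    out: Dict[str, float] = {}
    sd = s.std(axis=0)
    for (i, j), name in zip(((0, 1), (0, 2), (1, 2)), ("corr_xy", "corr_xz", "corr_yz")):
        if sd[i] > 0 and sd[j] > 0:
            out[name] = float(np.corrcoef(s[:, i], s[:, j])[0, 1])
        else:
            out[name] = np.nan
    for k, ax in enumerate(AXES):
        out[f"energy_{ax}"] = float(np.mean(s[:, k] ** 2))
    out["sma"] = float(np.mean(np.abs(s).sum(axis=1)))
    return out


def _power_spectrum(series: np.ndarray, rate: float) -> Tuple[np.ndarray, np.ndarray]:
    f, p = periodogram(series, fs=rate, window="hann", detrend="linear")
    return f, p


def spectral_features(series: np.ndarray, rate: float) -> Dict[str, float]:
    """Frequency-domain descriptors from a one-sided power spectrum.

    * dominant frequency: argmax of the detrended, Hann-windowed
      periodogram (DC bin excluded);
    * spectral centroid: power-weighted mean frequency;
    * spectral edge frequency: frequency below which 95% of power lies;
    * harmonic ratio: even- over odd-harmonic power at the first 10
      multiples of the dominant frequency;
    * index of harmonicity: dominant-frequency power over the cumulative
      power of the first 6 harmonics.
    """
    x = np.asarray(series, float)
    if x.size < 64:
        raise ValueError("need at least 64 samples for spectral features")
    f, p = _power_spectrum(x, rate)
    keys = ["dominant_frequency", "spectral_centroid", "sef95",
            "harmonic_ratio", "ioh"]
    total = p[1:].sum()
    if not np.isfinite(total) or total <= 0:
        return {k: np.nan for k in keys}
    k_dom = 1 + int(np.argmax(p[1:]))
    f_dom = f[k_dom]
    centroid = float((f[1:] * p[1:]).sum() / total)
    cum = np.cumsum(p[1:]) / total
    sef = float(f[1:][int(np.searchsorted(cum, SEF_PERCENTILE))])

    df = f[1] - f[0]

    def harm_power(h: int) -> float:
        idx = int(round(h * f_dom / df))
        return float(p[idx]) if idx < p.size else 0.0

    even = sum(harm_power(h) for h in range(2, HR_N_HARMONICS + 1, 2))
    odd = sum(harm_power(h) for h in range(1, HR_N_HARMONICS + 1, 2))
    hr = even / odd if odd > 0 else np.nan
    cum6 = sum(harm_power(h) for h in range(1, IOH_N_HARMONICS + 1))
    ioh = float(p[k_dom]) / cum6 if cum6 > 0 else np.nan
    return {
        "dominant_frequency": float(f_dom),
        "spectral_centroid": centroid,
        "sef95": sef,
        "harmonic_ratio": hr,
        "ioh": ioh,
    }


def dimensionless_jerk(accel_axis: np.ndarray, rate: float) -> float:
    """Negative dimensionless integrated squared jerk of an acceleration
    profile: ``-(T^3 / peak^2) * \\int (da/dt)^2 dt``.

    Amplitude-scale invariant; more negative = rougher movement.
    """
    a = np.asarray(accel_axis, float)
    if a.size < 3:
        raise ValueError("need at least 3 samples")
    peak = float(np.max(np.abs(a)))
    if peak == 0:
        return np.nan
    dt = 1.0 / rate
    duration = (a.size - 1) * dt
    jerk = np.gradient(a, dt)
    integral = float(np.trapezoid(jerk**2, dx=dt))
    return -(duration**3 / peak**2) * integral


def log_dimensionless_jerk(accel_axis: np.ndarray, rate: float) -> float:
    """``-ln`` of the (positive) dimensionless jerk; the log variant."""
    dj = dimensionless_jerk(accel_axis, rate)
    if not np.isfinite(dj) or dj >= 0:
        return np.nan
    return -float(np.log(-dj))


def sample_entropy(series: np.ndarray, m: int = 2, r: Optional[float] = None) -> float:
    """Sample entropy ``-ln(A/B)`` under the Chebyshev metric.

    ``B`` counts pairs of length-``m`` templates within tolerance ``r``
    (self-matches excluded), ``A`` the same for length ``m+1``; both
    template sets range over the first ``N - m`` starting points.
    ``r`` defaults to 0.2 times the series standard deviation.
    """
    x = np.asarray(series, float)
    n = x.size
    if n < m + 2:
        raise ValueError("series too short for the template length")
    if r is None:
        r = 0.2 * float(np.std(x, ddof=0))
    if r < 0:
        raise ValueError("tolerance r must be non-negative")

    def _count(mm: int) -> int:
        n_templates = n - m  # both lengths range over the same starts
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)[:n_templates]
        count = 0
        chunk = 256
        for i0 in range(0, n_templates, chunk):
            blk = emb[i0:i0 + chunk]
            d = np.abs(blk[:, None, :] - emb[None, :, :]).max(axis=2)
            within = d <= r
            # count ordered pairs j > i only
            for ii in range(blk.shape[0]):
                count += int(within[ii, i0 + ii + 1:].sum())
        return count

    b = _count(m)
    if b == 0:
        return np.nan
    a = _count(m + 1)
    if a == 0:
        return np.nan
    return -float(np.log(a / b))


def sparc(series: np.ndarray, rate: float, fc: float = SPARC_FC_HZ,
          amp_threshold: float = SPARC_AMP_THRESHOLD, pad_level: int = 4) -> float:
    """Spectral arc length movement-smoothness measure.

    Negative arc length of the max-normalized magnitude spectrum over
    [0, fc], with the adaptive cutoff at the last frequency whose
    normalized magnitude exceeds ``amp_threshold``.  More negative means
    a less smooth movement; the value is amplitude-scale invariant.
    """
    x = np.asarray(series, float)
    if x.size < 64:
        raise ValueError("need at least 64 samples")
    nfft = int(2 ** (np.ceil(np.log2(x.size)) + pad_level))
    f = np.arange(nfft // 2 + 1) * rate / nfft
    mag = np.abs(np.fft.rfft(x, nfft))
    peak = mag.max()
    if peak <= 0:
        return np.nan
    sel = f <= fc
    f_sel, m_sel = f[sel], mag[sel] / peak
    above = np.nonzero(m_sel >= amp_threshold)[0]
    if above.size == 0:
        return np.nan
    f_sel = f_sel[: above[-1] + 1]
    m_sel = m_sel[: above[-1] + 1]
    if f_sel.size < 2:
        return np.nan
    f_range = f_sel[-1] - f_sel[0]
    if f_range <= 0:
        return np.nan
    df_n = np.diff(f_sel) / f_range
    dm = np.diff(m_sel)
    return -float(np.sum(np.sqrt(df_n**2 + dm**2)))


# ----------------------------------------------------------------------
# registry

@dataclass(frozen=True)
class FeatureSpec:
    name: str
    sensor: str
    signal: str
    family: str


@dataclass
class FeatureVector:
    """Named scalar features for one repetition.

    ``values`` is an ordered Series (index = registry names); names of
    undefined features (stored as NaN) are collected in ``flagged``.
    """

    values: pd.Series
    flagged: frozenset

    def __len__(self) -> int:
        return len(self.values)


TIME_STAT_KEYS = ["mean", "sd", "skewness", "kurtosis", "rms", "min", "max",
                  "p2p", "cv", "iqr"]
TRIAD_KEYS = ["corr_xy", "corr_xz", "corr_yz", "energy_x", "energy_y",
              "energy_z", "sma"]
SPECTRAL_KEYS = ["dominant_frequency", "spectral_centroid", "sef95",
                 "harmonic_ratio", "ioh"]

# scalar signals fed to time_stats: 3 gyro + 3 jerk + 3 body-accel +
# 3 gravity-accel axes + the acceleration magnitude
_TIME_SIGNALS = (
    [f"gyro_{a}" for a in AXES] + [f"jerk_{a}" for a in AXES]
    + [f"accel_body_{a}" for a in AXES] + [f"accel_grav_{a}" for a in AXES]
    + ["accel_mag"]
)
_TRIAD_SIGNALS = ["gyro", "jerk", "accel_body", "accel_grav"]
_SPECTRAL_SIGNALS = (
    [f"gyro_{a}" for a in AXES] + [f"accel_{a}" for a in AXES]
    + [f"jerk_{a}" for a in AXES] + ["accel_mag"]
)
_DLJ_SIGNALS = [f"accel_{a}" for a in AXES]
_SMOOTH_SIGNALS = [f"gyro_{a}" for a in AXES] + [f"accel_{a}" for a in AXES]


@dataclass
class FeatureRegistry:
    """Ordered feature schema: which feature of which signal of which sensor.

    The per-repetition vector is the concatenation over sensors with
    sensor-prefixed names; a single-sensor registry is available via the
    ``sensors`` argument.
    """

    specs: List[FeatureSpec]

    @property
    def names(self) -> List[str]:
        return [s.name for s in self.specs]

    def __len__(self) -> int:
        return len(self.specs)

    def manifest(self) -> List[dict]:
        return [vars(s) for s in self.specs]


def default_registry(sensors: Sequence[str] = SENSOR_IDS) -> FeatureRegistry:
    specs: List[FeatureSpec] = []

    def add(sensor: str, signal: str, feature: str, family: str) -> None:
        specs.append(FeatureSpec(f"{sensor}__{signal}__{feature}", sensor, signal, family))

    for sensor in sensors:
        for sig in _TIME_SIGNALS:
            for k in TIME_STAT_KEYS:
                add(sensor, sig, k, "time")
        for sig in _TRIAD_SIGNALS:
            for k in TRIAD_KEYS:
                add(sensor, sig, k, "triad")
        for sig in _SPECTRAL_SIGNALS:
            for k in SPECTRAL_KEYS:
                add(sensor, sig, k, "spectral")
        for sig in _DLJ_SIGNALS:
            add(sensor, sig, "ldj", "smoothness")
        for sig in _SMOOTH_SIGNALS:
            add(sensor, sig, "sampen", "smoothness")
            add(sensor, sig, "sparc", "smoothness")
    return FeatureRegistry(specs)


def _derive_signals(accel: np.ndarray, gyro: np.ndarray, rate: float) -> Dict[str, np.ndarray]:
    jerk = np.gradient(accel, 1.0 / rate, axis=0)
    grav, body = decompose_gravity_body(accel, rate)
    sig: Dict[str, np.ndarray] = {
        "gyro": gyro, "jerk": jerk, "accel": accel,
        "accel_body": body, "accel_grav": grav,
        "accel_mag": np.linalg.norm(accel, axis=1),
    }
    for base in ("gyro", "jerk", "accel", "accel_body", "accel_grav"):
        for k, a in enumerate(AXES):
            sig[f"{base}_{a}"] = sig[base][:, k]
    return sig


def extract_features(
    rep: AlignedRepetition,
    registry: Optional[FeatureRegistry] = None,
) -> FeatureVector:
    """Compute the registry's feature vector for one aligned repetition.

    Any undefined feature is stored as NaN and its name recorded in the
    result's ``flagged`` set; the vector length always equals the
    registry length.
    """
    registry = registry or default_registry()
    values: Dict[str, float] = {}
    cache: Dict[Tuple[str, str, str], Dict[str, float]] = {}

    sensors = sorted({s.sensor for s in registry.specs})
    signals = {
        sensor: _derive_signals(rep.accel(sensor), rep.gyro(sensor), rep.rate)
        for sensor in sensors
    }

    def family_values(sensor: str, signal: str, family: str) -> Dict[str, float]:
        key = (sensor, signal, family)
        if key in cache:
            return cache[key]
        data = signals[sensor][signal]
        try:
            if family == "time":
                out = time_stats(data)
            elif family == "triad":
                out = triad_stats(data)
            elif family == "spectral":
                out = spectral_features(data, rep.rate)
            elif family == "smoothness":
                out = {
                    "ldj": log_dimensionless_jerk(data, rep.rate),
                    "sampen": sample_entropy(data),
                    "sparc": sparc(data, rep.rate),
                }
            else:  # pragma: no cover
                raise ValueError(f"unknown family {family}")
        except ValueError:
            keys = {"time": TIME_STAT_KEYS, "triad": TRIAD_KEYS,
                    "spectral": SPECTRAL_KEYS,
                    "smoothness": ["ldj", "sampen", "sparc"]}[family]
            out = {k: np.nan for k in keys}
        cache[key] = out
        return out

    for spec in registry.specs:
        feature_key = spec.name.split("__")[-1]
        values[spec.name] = family_values(spec.sensor, spec.signal, spec.family).get(
            feature_key, np.nan
        )

    series = pd.Series(values, index=registry.names, dtype=float)
    flagged = frozenset(series.index[~np.isfinite(series.to_numpy())])
    return FeatureVector(series, flagged)
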