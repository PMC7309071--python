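"""Feature extractors against independent brute-force oracles."""

import numpy as np
import pytest

from aclgait import features, preprocess, synth
from aclgait.core import AlignedRepetition, SENSOR_IDS
from conftest import make_spec


class TestGravityBodyDecomposition:
    def test_constant_acceleration(self):
        a = np.tile([0.0, 0.0, 1.0], (500, 1))
        grav, body = features.decompose_gravity_body(a, 100.0)
        assert np.allclose(grav, a, atol=1e-9)
        assert np.allclose(body, 0.0, atol=1e-9)

    def test_sine_passes_to_body(self):
        # the 0.3 Hz filter's impulse response spans seconds, so judge
        # only the central window of a long record
        t = np.arange(0, 20, 0.01)
        a = np.tile([0.0, 0.0, 1.0], (t.size, 1))
        a[:, 1] += 0.5 * np.sin(2 * np.pi * 5.0 * t)
        grav, body = features.decompose_gravity_body(a, 100.0)
        mid = slice(800, 1200)
        assert np.allclose(grav[mid, 2], 1.0, atol=0.01)
        assert np.allclose(grav[mid, 1], 0.0, atol=0.01)
        target = 0.5 * np.sin(2 * np.pi * 5.0 * t[mid])
        assert np.max(np.abs(body[mid, 1] - target)) < 0.02 * 0.5 + 0.01

    def test_complementary_sum(self, rng):
        a = rng.normal(0, 1, (400, 3))
        grav, body = features.decompose_gravity_body(a, 100.0)
        assert np.allclose(grav + body, a, atol=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            features.decompose_gravity_body(np.zeros((10, 3)), 100.0)


class TestTimeStats:
    def test_constant_series(self):
        s = features.time_stats(np.array([1.0, 1, 1, 1]))
        assert s["mean"] == 1 and s["sd"] == 0 and s["p2p"] == 0
        assert s["rms"] == 1 and s["skewness"] == 0 and s["kurtosis"] == 0

    def test_worked_example(self):
        s = features.time_stats(np.array([-2.0, -1, 1, 2]))
        assert s["mean"] == 0
        assert s["rms"] == pytest.approx(1.5811, abs=1e-4)
        assert s["p2p"] == 4
        brute_iqr = np.percentile([-2, -1, 1, 2], 75) - np.percentile([-2, -1, 1, 2], 25)
        assert s["iqr"] == pytest.approx(brute_iqr)
        assert np.isnan(s["cv"])  # zero mean -> flagged

    def test_normal_sample_moments(self, rng):
        x = rng.standard_normal(100_000)
        s = features.time_stats(x)
        assert abs(s["skewness"]) < 0.05
        assert abs(s["kurtosis"]) < 0.05

    def test_brute_force_agreement(self, rng):
        x = rng.normal(2.0, 3.0, 257)
        s = features.time_stats(x)
        m = x.mean()
        sd = x.std()
        assert s["mean"] == pytest.approx(m, abs=1e-12)
        assert s["sd"] == pytest.approx(sd, abs=1e-12)
        assert s["cv"] == pytest.approx(sd / abs(m), abs=1e-12)
        assert s["skewness"] == pytest.approx(np.mean((x - m) ** 3) / sd**3, abs=1e-9)
        assert s["kurtosis"] == pytest.approx(np.mean((x - m) ** 4) / sd**4 - 3, abs=1e-9)

    def test_empty_and_short_rejected(self):
        with pytest.raises(ValueError):
            features.time_stats(np.array([]))
        with pytest.raises(ValueError):
            features.time_stats(np.array([1.0, 2.0]))


class TestTriadStats:
    def test_identical_axes_correlate(self, rng):
        x = rng.normal(0, 1, 100)
        s = features.triad_stats(np.column_stack([x, x, rng.normal(0, 1, 100)]))
        assert s["corr_xy"] == pytest.approx(1.0)

    def test_energy_and_sma_example(self):
        sig = np.column_stack([np.array([1.0, -1, 1, -1]), np.zeros(4), np.zeros(4)])
        s = features.triad_stats(sig)
        assert s["energy_x"] == 1.0
        assert s["sma"] == 1.0

    def test_brute_force_agreement(self, rng):
        sig = rng.normal(0, 2, (64, 3))
        s = features.triad_stats(sig)
        x, y, z = sig.T
        for name, (u, v) in [("corr_xy", (x, y)), ("corr_xz", (x, z)), ("corr_yz", (y, z))]:
            num = np.mean((u - u.mean()) * (v - v.mean()))
            assert s[name] == pytest.approx(num / (u.std() * v.std()), abs=1e-12)
        assert s["energy_y"] == pytest.approx(np.mean(y**2), abs=1e-12)
        assert s["sma"] == pytest.approx(np.mean(np.abs(x) + np.abs(y) + np.abs(z)), abs=1e-12)

    def test_zero_variance_axis_flagged(self):
        sig = np.column_stack([np.ones(16), np.arange(16.0), np.arange(16.0)])
        s = features.triad_stats(sig)
        assert np.isnan(s["corr_xy"]) and np.isnan(s["corr_xz"])
        assert np.isfinite(s["corr_yz"])


def _oracle_spectrum(x, rate):
    """Independent Hann-windowed, linearly detrended power spectrum.

    Uses the periodic Hann window convention (the one spectral
    estimators use for non-averaged periodograms).
    """
    n = len(x)
    t = np.arange(n)
    coef = np.polyfit(t, x, 1)
    xd = x - np.polyval(coef, t)
    w = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))  # periodic Hann
    spec = np.abs(np.fft.rfft(xd * w)) ** 2
    f = np.fft.rfftfreq(n, 1 / rate)
    return f, spec


class TestSpectralFeatures:
    def test_pure_sine(self):
        t = np.arange(0, 10, 0.01)
        s = features.spectral_features(np.sin(2 * np.pi * 2.0 * t), 100.0)
        assert s["dominant_frequency"] == pytest.approx(2.0, abs=0.1)
        assert s["spectral_centroid"] == pytest.approx(2.0, abs=0.1)
        assert s["ioh"] == pytest.approx(1.0, abs=0.05)

    def test_harmonic_ratio_against_oracle(self):
        t = np.arange(0, 8, 0.01)
        x = np.sin(2 * np.pi * 2.0 * t) + 0.8 * np.sin(2 * np.pi * 4.0 * t)
        s = features.spectral_features(x, 100.0)
        f, p = _oracle_spectrum(x, 100.0)
        df = f[1] - f[0]
        k_dom = 1 + int(np.argmax(p[1:]))
        f_dom = f[k_dom]

        def hp(h):
            i = int(round(h * f_dom / df))
            return p[i] if i < p.size else 0.0

        hr = sum(hp(h) for h in range(2, 11, 2)) / sum(hp(h) for h in range(1, 11, 2))
        assert s["harmonic_ratio"] == pytest.approx(hr, abs=1e-9)
        assert hr > 0.1  # the 4 Hz harmonic carries real power

    def test_white_noise_sef_near_flat_limit(self, rng):
        x = rng.standard_normal(2**14)
        s = features.spectral_features(x, 100.0)
        assert s["sef95"] == pytest.approx(0.95 * 50.0, rel=0.05)

    def test_all_zero_flagged(self):
        s = features.spectral_features(np.zeros(256), 100.0)
        assert all(np.isnan(v) for v in s.values())


def _min_jerk_accel(T=1.0, n=2001):
    # acceleration of the minimum-jerk position profile on [0, T]
    t = np.linspace(0, T, n)
    tau = t / T
    a = (60 * tau - 180 * tau**2 + 120 * tau**3) / T**2
    return t, a


class TestDimensionlessJerk:
    def test_scale_invariance(self, rng):
        x = rng.normal(0, 1, 300)
        v1 = features.dimensionless_jerk(x, 100.0)
        v2 = features.dimensionless_jerk(7.3 * x, 100.0)
        assert v1 == pytest.approx(v2, rel=1e-12)
        l1 = features.log_dimensionless_jerk(x, 100.0)
        l2 = features.log_dimensionless_jerk(7.3 * x, 100.0)
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_minimum_jerk_profile_closed_form(self):
        """On the minimum-jerk acceleration profile the dimensionless
        jerk matches a dense numeric evaluation of the analytic jerk
        polynomial within 1%."""
        T = 1.2
        t, a = _min_jerk_accel(T=T, n=4001)
        rate = 1.0 / (t[1] - t[0])
        got = features.dimensionless_jerk(a, rate)
        tf = np.linspace(0, T, 400_001)
        tau = tf / T
        jerk = (60 - 360 * tau + 360 * tau**2) / T**3
        integral = np.trapezoid(jerk**2, tf)
        peak = np.max(np.abs(a))
        expected = -(T**3 / peak**2) * integral
        assert got == pytest.approx(expected, rel=0.01)

    def test_roughened_profile_strictly_worse(self, rng):
        t = np.arange(0, 3, 0.01)
        smooth = np.exp(-0.5 * ((t - 1.5) / 0.3) ** 2)
        rough = smooth + 0.05 * np.sin(2 * np.pi * 12 * t)
        assert features.dimensionless_jerk(rough, 100.0) < features.dimensionless_jerk(smooth, 100.0)

    def test_zero_input_flagged(self):
        assert np.isnan(features.dimensionless_jerk(np.zeros(100), 100.0))


def _sampen_brute(x, m, r):
    """Exhaustive O(N^2) template-count sample entropy."""
    n = len(x)
    nt = n - m

    def count(mm):
        c = 0
        for i in range(nt):
            for j in range(i + 1, nt):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return np.nan
    return -np.log(a / b)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert features.sample_entropy(np.ones(50)) == 0.0

    def test_ramp_with_tight_tolerance_undefined(self):
        # strictly increasing integers, r=0.5: no template matches at all
        x = np.arange(1.0, 21.0)
        assert np.isnan(features.sample_entropy(x, m=2, r=0.5))
        assert np.isnan(_sampen_brute(x, 2, 0.5))

    @pytest.mark.parametrize("n,m", [(60, 2), (80, 3)])
    def test_matches_brute_force_exactly(self, rng, n, m):
        x = rng.normal(0, 1, n)
        r = 0.3
        got = features.sample_entropy(x, m=m, r=r)
        expected = _sampen_brute(x, m, r)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_periodic_lower_than_shuffled(self, rng):
        x = np.tile(np.sin(np.linspace(0, 2 * np.pi, 25)), 8)
        y = x.copy()
        rng.shuffle(y)
        assert features.sample_entropy(x) < features.sample_entropy(y)


class TestSparc:
    def test_scale_invariance(self, rng):
        t = np.arange(0, 3, 0.01)
        x = np.exp(-0.5 * ((t - 1.5) / 0.4) ** 2)
        assert features.sparc(x, 100.0) == pytest.approx(features.sparc(4.2 * x, 100.0),
                                                         rel=1e-12)

    def test_ripple_strictly_more_negative(self):
        t = np.arange(0, 3, 0.01)
        pulse = np.exp(-0.5 * ((t - 1.5) / 0.4) ** 2)
        rippled = pulse + 0.08 * np.sin(2 * np.pi * 8.0 * t)
        assert features.sparc(rippled, 100.0) < features.sparc(pulse, 100.0)

    def test_sinusoid_matches_direct_arc_length(self):
        """SPARC of a sinusoid equals a direct numeric arc-length
        evaluation of its normalized magnitude spectrum."""
        t = np.arange(0, 4, 0.01)
        x = np.sin(2 * np.pi * 3.0 * t)
        rate, fc, th, pad = 100.0, 10.0, 0.05, 4
        nfft = int(2 ** (np.ceil(np.log2(len(x))) + pad))
        f = np.arange(nfft // 2 + 1) * rate / nfft
        mag = np.abs(np.fft.rfft(x, nfft))
        mag /= mag.max()
        sel = f <= fc
        f_sel, m_sel = f[sel], mag[sel]
        last = np.nonzero(m_sel >= th)[0][-1]
        f_sel, m_sel = f_sel[: last + 1], m_sel[: last + 1]
        arc = -np.sum(np.sqrt((np.diff(f_sel) / (f_sel[-1] - f_sel[0])) ** 2
                              + np.diff(m_sel) ** 2))
        assert features.sparc(x, rate) == pytest.approx(arc, abs=1e-9)

    def test_all_zero_flagged(self):
        assert np.isnan(features.sparc(np.zeros(128), 100.0))


def _zero_aligned_rep(n=700, rate=100.0):
    z = {"accel": np.zeros((n, 3)), "gyro": np.zeros((n, 3))}
    return AlignedRepetition(
        t=np.arange(n) / rate, rate=rate,
        signals={s: {k: v.copy() for k, v in z.items()} for s in SENSOR_IDS},
        offsets={s: 0.0 for s in SENSOR_IDS},
        rotations={s: np.eye(3) for s in SENSOR_IDS},
    )


class TestRegistry:
    def test_registry_size_and_stability(self):
        reg = features.default_registry()
        # 223 per sensor: 13 signals x 10 time stats + 4 triads x 7
        # + 10 signals x 5 spectral + 3 LDJ + 6 signals x 2 smoothness
        assert len(reg) == 4 * 223
        assert len(set(reg.names)) == len(reg)
        assert reg.names == features.default_registry().names

    def test_single_sensor_registry(self):
        reg = features.default_registry(sensors=("left_shank",))
        assert len(reg) == 223
        assert all(s.sensor == "left_shank" for s in reg.specs)

    def test_zero_input_flags(self):
        fv = features.extract_features(_zero_aligned_rep())
        vals = fv.values
        # location/scale features of a zero signal are zero
        assert vals["left_shank__gyro_x__mean"] == 0.0
        assert vals["left_shank__gyro_x__sd"] == 0.0
        assert vals["left_shank__accel_mag__rms"] == 0.0
        # spectral content undefined -> flagged, vector length unchanged
        assert "left_shank__gyro_x__dominant_frequency" in fv.flagged
        assert "left_shank__accel_x__sparc" in fv.flagged
        assert len(fv) == len(features.default_registry())

    def test_identical_repetitions_identical_vectors(self):
        spec = make_spec(seed=9, n_strides=2)
        rep = synth.generate_repetition(spec, "acl_00", 0)
        ar = preprocess.align_repetition(rep)
        reg = features.default_registry(sensors=("left_shank",))
        v1 = features.extract_features(ar, reg).values
        v2 = features.extract_features(ar, reg).values
        assert v1.equals(v2)
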