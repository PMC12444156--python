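import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from armkin import (
    Path3D,
    PeakParams,
    ScalarProfile,
    SparcParams,
    SynthSpec,
    count_velocity_peaks,
    generate_reach,
    log_dimensionless_jerk,
    sparc,
    speed_profile,
    velocity_ratio,
    zero_crossings_accel,
)


def _profile(t, v):
    return ScalarProfile(times=np.asarray(t, float), values=np.asarray(v, float))


def dense_sparc_oracle(values, fs, fc=20.0, amp_th=0.05):
    """Independent high-resolution spectral arc length (10x zero-padding).

    Straightforward re-statement of the definition: oversampled DFT magnitude
    normalized by its DC value, adaptive amplitude cutoff within [0, fc], arc
    length on the band-normalized frequency axis.
    """
    n = int(2 ** (math.ceil(math.log2(len(values))) + 10))
    spectrum = np.abs(np.fft.fft(values, n))
    spectrum = spectrum / spectrum[0]
    freqs = np.arange(n) * fs / n
    keep = freqs <= fc
    f, m = freqs[keep], spectrum[keep]
    idx = np.flatnonzero(m >= amp_th)
    f, m = f[idx[0] : idx[-1] + 1], m[idx[0] : idx[-1] + 1]
    df = np.diff(f) / (f[-1] - f[0])
    return -float(np.sum(np.hypot(df, np.diff(m))))


class TestVelocityRatio:
    def test_constant_profile(self):
        assert velocity_ratio(_profile(np.arange(4) / 4, [7.0] * 4)) == pytest.approx(1.0)

    def test_triangular(self):
        assert velocity_ratio(_profile([0.0, 0.5, 1.0], [0.0, 100.0, 0.0])) == pytest.approx(1 / 3)

    def test_min_jerk_eight_fifteenths(self, min_jerk_speed):
        assert velocity_ratio(min_jerk_speed) == pytest.approx(8 / 15, rel=0.005)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            velocity_ratio(_profile(np.arange(3) / 3, [0.0, 0.0, 0.0]))


class TestCountVelocityPeaks:
    def test_min_jerk_single_peak(self, min_jerk_speed):
        assert count_velocity_peaks(min_jerk_speed) == 1

    def test_two_sequential_submovements(self):
        # Two 0.5 s minimum-jerk submovements with onsets 0.5 s apart: speed
        # returns to ~0 between them, so both peaks pass all three conditions.
        from armkin import split_segments

        spec = SynthSpec(amplitude=150.0, duration=0.5, rate=200.0, n_submovements=2, submovement_offsets=(0.0, 0.5))
        rec, _ = generate_reach(spec)
        seg = split_segments(rec)[0]
        sp = speed_profile(
            Path3D(times=rec.timestamps[seg.start : seg.stop], points=rec.positions["RWR"][seg.start : seg.stop])
        )
        assert count_velocity_peaks(sp) == 2

    def test_small_ripple_rejected_by_amplitude(self):
        t = np.arange(400) / 200.0
        v = 200.0 * np.exp(-(((t - 1.0) / 0.3) ** 2))
        ripple = 10.0 * np.exp(-(((t - 1.6) / 0.02) ** 2))  # rises 10 mm/s < delta
        assert count_velocity_peaks(_profile(t, v + ripple)) == 1
        tall = 50.0 * np.exp(-(((t - 1.6) / 0.02) ** 2))  # rises > delta
        assert count_velocity_peaks(_profile(t, v + tall)) == 2

    def test_refractory_interval_merges_close_peaks(self):
        t = np.arange(300) / 1000.0  # 1 kHz, peaks 100 ms apart < tau
        v = 100 * np.exp(-(((t - 0.1) / 0.02) ** 2)) + 100 * np.exp(-(((t - 0.2) / 0.02) ** 2))
        assert count_velocity_peaks(_profile(t, v), PeakParams(delta=20, tau=0.150)) == 1
        assert count_velocity_peaks(_profile(t, v), PeakParams(delta=20, tau=0.050)) == 2

    def test_plateau_counts_once(self):
        v = [0.0, 50.0, 50.0, 50.0, 0.0]
        assert count_velocity_peaks(_profile(np.arange(5) / 5.0, v)) == 1

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            count_velocity_peaks(_profile([0.0, 1.0], [0.0, 1.0]))

    @given(st.lists(st.floats(0, 1000), min_size=3, max_size=50))
    def test_zero_thresholds_match_raw_maxima_count(self, values):
        t = np.arange(len(values)) / 100.0
        params = PeakParams(delta=1e-12, tau=0.0)
        got = count_velocity_peaks(_profile(t, values), params)
        # brute force on the plateau-collapsed series
        w = [values[0]]
        for v in values[1:]:
            if v != w[-1]:
                w.append(v)
        brute = sum(1 for i in range(1, len(w) - 1) if w[i - 1] < w[i] > w[i + 1])
        assert got == brute

    def test_cross_check_scipy_find_peaks(self):
        from scipy.signal import find_peaks

        rng = np.random.default_rng(11)
        v = np.abs(rng.normal(size=200)).cumsum() % 97.0
        t = np.arange(200) / 100.0
        got = count_velocity_peaks(_profile(t, v), PeakParams(delta=1e-12, tau=0.0))
        assert got == len(find_peaks(v)[0])


class TestZeroCrossings:
    def test_sign_pattern(self):
        assert zero_crossings_accel(_profile([0, 1, 2], [1.0, -1.0, 1.0])) == 2

    def test_constant_positive(self):
        assert zero_crossings_accel(_profile(np.arange(5.0), np.full(5, 2.0))) == 0

    def test_exact_zero_between_signs_counts_once(self):
        assert zero_crossings_accel(_profile(np.arange(3.0), [1.0, 0.0, -1.0])) == 1

    def test_touch_without_cross_counts_zero(self):
        assert zero_crossings_accel(_profile(np.arange(3.0), [1.0, 0.0, 1.0])) == 0

    def test_amplitude_scaling_invariance(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=100)
        t = np.arange(100.0)
        assert zero_crossings_accel(_profile(t, v)) == zero_crossings_accel(_profile(t, 17.3 * v))

    def test_min_jerk_tangential_accel_crosses_once(self, min_jerk_speed):
        from armkin import differentiate

        tacc = differentiate(min_jerk_speed, 1)
        interior = _profile(tacc.times[1:-1], tacc.values[1:-1])
        assert zero_crossings_accel(interior) == 1

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            zero_crossings_accel(ScalarProfile(times=np.array([0.0]), values=np.array([1.0])))


class TestLogDimensionlessJerk:
    def _reach_path(self, D=300.0, T=1.0, rate=200.0):
        spec = SynthSpec(amplitude=D, duration=T, rate=rate)
        rec, _ = generate_reach(spec)
        n = round(T * rate)
        return Path3D(times=rec.timestamps[:n], points=rec.positions["RWR"][:n])

    def test_min_jerk_analytic_value(self):
        assert log_dimensionless_jerk(self._reach_path()) == pytest.approx(-math.log(720), abs=0.05)

    def test_spatial_scale_invariance(self):
        p = self._reach_path()
        scaled = Path3D(times=p.times, points=p.points * 4.2)
        assert log_dimensionless_jerk(scaled) == pytest.approx(log_dimensionless_jerk(p), abs=1e-6)

    def test_time_scale_invariance(self):
        # same sample grid in normalized time, twice the duration
        a = log_dimensionless_jerk(self._reach_path(T=1.0, rate=200.0))
        b = log_dimensionless_jerk(self._reach_path(T=2.0, rate=100.0))
        assert b == pytest.approx(a, abs=1e-3)

    def test_zero_path_length_errors(self):
        t = np.arange(10) / 10.0
        with pytest.raises(ValueError, match="path length"):
            log_dimensionless_jerk(Path3D(times=t, points=np.ones((10, 3))))


class TestSparc:
    def test_amplitude_scale_invariance_exact(self, min_jerk_speed):
        a = sparc(min_jerk_speed)
        b = sparc(ScalarProfile(times=min_jerk_speed.times, values=3.7 * min_jerk_speed.values))
        assert b == pytest.approx(a, abs=1e-12)

    def test_bounded_above_by_minus_one(self, min_jerk_speed):
        rng = np.random.default_rng(4)
        profiles = [min_jerk_speed.values, np.abs(rng.normal(size=256)) + 1.0, np.hanning(128) + 0.01]
        for v in profiles:
            p = _profile(np.arange(len(v)) / 200.0, v)
            assert sparc(p) <= -1 + 1e-6

    def test_agrees_with_dense_grid_oracle(self, min_jerk_speed):
        got = sparc(min_jerk_speed)
        want = dense_sparc_oracle(min_jerk_speed.values, fs=200.0)
        assert got == pytest.approx(want, abs=0.01)

    def test_zero_mean_signal_errors(self):
        t = np.arange(64) / 64.0
        with pytest.raises(ValueError, match="V\\(0\\)"):
            sparc(_profile(t, np.tile([1.0, -1.0], 32)))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sparc(_profile(np.arange(5) / 5.0, np.ones(5)))

    def test_non_uniform_input_resampled(self, min_jerk_speed):
        rng = np.random.default_rng(9)
        jitter = rng.uniform(-0.001, 0.001, len(min_jerk_speed))
        jitter[0] = jitter[-1] = 0.0
        p = _profile(min_jerk_speed.times + jitter, min_jerk_speed.values)
        assert sparc(p, SparcParams(resample_rate=200.0)) == pytest.approx(sparc(min_jerk_speed), abs=0.05)


class TestSmoothnessDegradation:
    def test_monotone_in_submovement_count(self):
        """More temporally separated submovements: NPV up, SPARC down."""
        trials = 20
        ok_npv = ok_sparc = 0
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            gap = rng.uniform(0.55, 0.85)
            amp = rng.uniform(80.0, 120.0)
            npvs, sparcs = [], []
            for k in (1, 2, 3):
                spec = SynthSpec(
                    amplitude=amp,
                    duration=1.0,
                    rate=200.0,
                    n_submovements=k,
                    submovement_offsets=tuple(j * gap for j in range(k)),
                    noise_sd=0.05,
                    seed=seed,
                )
                rec, _ = generate_reach(spec)
                n = round((gap * (k - 1) + 1.0) * 200)
                sp = speed_profile(Path3D(times=rec.timestamps[:n], points=rec.positions["RWR"][:n]))
                npvs.append(count_velocity_peaks(sp))
                sparcs.append(sparc(sp))
            ok_npv += npvs[0] <= npvs[1] <= npvs[2]
            ok_sparc += sparcs[0] >= sparcs[1] >= sparcs[2]
        assert ok_npv >= 0.95 * trials
        assert ok_sparc >= 0.95 * trials
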