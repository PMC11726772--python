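"""Signal equations and voxel-level fitting."""

import numpy as np
import pytest

from radrelax import signal_models as sm


class TestSatRecovery:
    def test_perfect_saturation_starts_at_zero(self):
        assert sm.sat_recovery_signal(0.0, 1.0, 1.0, 0.5) == 0.0

    def test_asymptote_is_offset_plus_steady_state(self):
        for eff in (0.3, 0.9, 1.0):
            v = sm.sat_recovery_signal(100 * 0.7, 2.5, eff, 0.7, offset=0.4)
            assert v == pytest.approx(2.9, rel=1e-10)

    def test_value_at_one_time_constant(self):
        # direct evaluation of the closed form at t = T1eff
        assert sm.sat_recovery_signal(0.4, 1.0, 1.0, 0.4) == pytest.approx(
            1.0 - np.exp(-1.0), rel=1e-12)

    def test_monotone_nondecreasing_on_dense_grid(self):
        t = np.linspace(0, 10, 1000)
        for eff in (0.05, 0.5, 1.0):
            s = sm.sat_recovery_signal(t, 1.3, eff, 0.8, offset=-0.2)
            assert np.all(np.diff(s) >= 0)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sm.sat_recovery_signal(1.0, 1.0, 1.0, -0.1)
        with pytest.raises(ValueError):
            sm.sat_recovery_signal(1.0, 1.0, 1.5, 1.0)


class TestFlipAngleCorrection:
    def test_zero_flip_angle_is_identity(self):
        assert sm.correct_t1eff_to_t1(1.0, 0.0, 3e-3) == pytest.approx(1.0, abs=0)

    def test_four_degree_worked_example(self):
        # independent arithmetic: 1 / (1/1.0 + ln(cos 4 deg)/0.003)
        expected = 1.0 / (1.0 + np.log(np.cos(np.deg2rad(4.0))) / 3e-3)
        got = sm.correct_t1eff_to_t1(1.0, 4.0, 3e-3)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(5.3469, rel=1e-4)
        assert got > 1.0  # correction always lengthens T1eff

    def test_instability_raises_with_rate(self):
        # 1/0.1 + ln(cos 60)/0.003 < 0
        with pytest.raises(sm.CorrectionInstabilityError) as err:
            sm.correct_t1eff_to_t1(0.1, 60.0, 3e-3)
        assert err.value.rate < 0

    def test_roundtrip_through_apparent_rate(self):
        # exact inverse of R1eff = R1 - ln(cos a)/tau
        for t1 in np.geomspace(0.05, 5.0, 20):
            r1eff = sm.apparent_rate(t1, 4.0, 3e-3)
            back = sm.correct_t1eff_to_t1(1.0 / r1eff, 4.0, 3e-3)
            assert back == pytest.approx(t1, rel=1e-12)


class TestSpinLockNormalization:
    tsl = np.arange(0.0, 32.0, 4.0)

    def test_constant_signal_infinite_t1_gives_ones(self):
        ser = sm.SpinLockSeries(self.tsl, np.full(8, 3.3), t1_reference=np.inf)
        assert np.allclose(sm.normalize_spinlock(ser), 1.0)

    def test_pure_monoexp_preserved_with_infinite_t1(self):
        sig = 2.0 * np.exp(-self.tsl / 50.0)
        ser = sm.SpinLockSeries(self.tsl, sig, t1_reference=np.inf)
        assert np.allclose(sm.normalize_spinlock(ser), np.exp(-self.tsl / 50.0),
                           rtol=1e-12)

    def test_first_point_exactly_one(self):
        rng = np.random.default_rng(0)
        sig = np.abs(rng.normal(1.0, 0.2, 8)) + 0.1
        ser = sm.SpinLockSeries(self.tsl, sig, t1_reference=1.4)
        proto = _proto()
        assert sm.normalize_spinlock(ser, proto)[0] == 1.0

    def test_inverts_readout_recovery_model(self):
        # forward frame model -> normalization recovers exp(-tsl/T1rho)
        proto = _proto()
        t_read = proto.prep_period * proto.spoke_time
        f = sm.t1_recovery_fraction(1.4, t_read)
        sig = sm.spinlock_frame_signal(self.tsl, 50.0, m0=2.0, recovery_fraction=f)
        ser = sm.SpinLockSeries(self.tsl, sig, t1_reference=1.4)
        norm = sm.normalize_spinlock(ser, proto)
        assert np.allclose(norm, np.exp(-self.tsl / 50.0), rtol=1e-12)

    def test_zero_reference_signal_raises(self):
        sig = np.exp(-self.tsl / 50.0)
        sig[0] = 0.0
        ser = sm.SpinLockSeries(self.tsl, sig)
        with pytest.raises(ZeroDivisionError):
            sm.normalize_spinlock(ser)


def _proto():
    from radrelax import t1rho_protocol
    return t1rho_protocol(matrix=16, spokes_per_frame=64)


class TestMonoexpFit:
    def test_noiseless_recovery(self):
        x = np.array([0.0, 10.0, 20.0, 30.0])
        A, tau = sm.fit_monoexp(x, np.exp(-x / 15.0))
        assert tau == pytest.approx(15.0, rel=1e-8)
        assert A == pytest.approx(1.0, rel=1e-8)

    def test_te_grid_t2_roundtrip(self):
        # forward-simulate on the 2D TE grid, then refit
        x = np.array([0.05, 2.3, 4.5, 14.0])
        A, tau = sm.fit_monoexp(x, np.exp(-x / 31.0))
        assert tau == pytest.approx(31.0, rel=1e-6)

    def test_no_decay_is_censored(self):
        A, tau = sm.fit_monoexp(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        assert np.isnan(tau)

    def test_nonfinite_input_raises(self):
        with pytest.raises(ValueError):
            sm.fit_monoexp(np.array([0.0, 1.0]), np.array([1.0, np.nan]))


class TestLookLockerFit:
    times = (np.arange(32) + 0.5) * 1024 / 32 * 3e-3

    def test_simulate_then_fit_roundtrip(self):
        sig = sm.sat_recovery_signal(self.times, 1.0, 0.95, 0.4)
        ss, eff, t1eff, off, phase = sm.fit_looklocker(
            sm.LookLockerCurve(self.times, sig))
        assert t1eff == pytest.approx(0.4, rel=1e-3)
        assert eff == pytest.approx(0.95, rel=1e-3)
        assert phase == 0.0

    def test_exact_recovery_across_time_constant_grid(self):
        for t1eff in np.geomspace(0.05, 5.0, 20):
            sig = sm.sat_recovery_signal(self.times, 2.0, 0.9, t1eff)
            _, eff, fitted, _, _ = sm.fit_looklocker(
                sm.LookLockerCurve(self.times, sig))
            assert fitted == pytest.approx(t1eff, rel=1e-6)
            assert eff == pytest.approx(0.9, rel=1e-6)

    def test_all_zero_curve_returns_nan(self):
        out = sm.fit_looklocker(sm.LookLockerCurve(self.times, np.zeros(32)))
        assert all(np.isnan(v) for v in out)

    def test_complex_input_recovers_global_phase(self):
        sig = sm.sat_recovery_signal(self.times, 1.0, 0.95, 0.4) * np.exp(0.7j)
        ss, eff, t1eff, off, phase = sm.fit_looklocker(
            sm.LookLockerCurve(self.times, sig))
        assert t1eff == pytest.approx(0.4, rel=1e-3)
        assert phase == pytest.approx(0.7, abs=1e-6)

    def test_median_within_2pct_under_noise(self):
        # Monte-Carlo: 1% noise, 100 replicates, fixed seed
        rng = np.random.default_rng(1234)
        truth = 0.4
        clean = sm.sat_recovery_signal(self.times, 1.0, 0.95, truth)
        fits = []
        for _ in range(100):
            sig = clean + rng.normal(0, 0.01, clean.shape)
            fits.append(sm.fit_looklocker(sm.LookLockerCurve(self.times, sig))[2])
        assert np.median(fits) == pytest.approx(truth, rel=0.02)


class TestLogSlopeEstimators:
    tsl = np.arange(0.0, 32.0, 4.0)

    def test_monoexp_closed_form(self):
        s = np.exp(-self.tsl / 50.0)
        assert sm.t1rho_asymptotic(self.tsl, s) == pytest.approx(50.0, rel=1e-12)
        assert sm.t1rho_slow(self.tsl, s) == pytest.approx(50.0, rel=1e-12)

    def test_biexp_against_brute_force(self):
        s = 0.6 * np.exp(-self.tsl / 10.0) + 0.4 * np.exp(-self.tsl / 100.0)
        # oracle: direct evaluation over the first two points
        expect_a = -4.0 / np.log(s[1] / s[0])
        assert sm.t1rho_asymptotic(self.tsl, s) == pytest.approx(expect_a, rel=1e-12)
        # oracle: normal-equations regression on points 3..8
        xs, ys = self.tsl[2:], np.log(s[2:])
        slope = (np.sum((xs - xs.mean()) * (ys - ys.mean()))
                 / np.sum((xs - xs.mean()) ** 2))
        assert sm.t1rho_slow(self.tsl, s) == pytest.approx(-1.0 / slope, rel=1e-12)

    def test_degenerate_slopes_are_nan(self):
        assert np.isnan(sm.t1rho_asymptotic(self.tsl, np.ones(8)))
        assert np.isnan(sm.t1rho_slow(self.tsl, np.ones(8)))
        neg = np.exp(-self.tsl / 50.0)
        neg[1] = -0.1
        assert np.isnan(sm.t1rho_asymptotic(self.tsl, neg))

    def test_all_three_estimators_agree_on_monoexp(self):
        s = np.exp(-self.tsl / 42.0)
        a = sm.t1rho_asymptotic(self.tsl, s)
        sl = sm.t1rho_slow(self.tsl, s)
        _, tau = sm.fit_monoexp(self.tsl, s)
        assert a == pytest.approx(42.0, rel=1e-9)
        assert sl == pytest.approx(42.0, rel=1e-9)
        assert tau == pytest.approx(42.0, rel=1e-9)
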