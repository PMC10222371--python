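"""Model inversions (Methods I/II) and the Kalman displacement/velocity fusion."""

import dataclasses

import numpy as np
import pytest

import swaycom as sc
from swaycom.estimators import (
    KalmanConfig,
    build_kalman_matrices,
    estimate_method1,
    estimate_method2,
    kalman_fuse,
    method2_matrix,
)
from swaycom.series import ForcePlateSeries, HeadAcceleration, SupportMotion

FS = 100.0


def _zero_plate(n=4000, fz=70 * 9.81):
    t = np.arange(n) / FS
    z = np.zeros(n)
    return ForcePlateSeries(t=t, R_x=z.copy(), R_y=z.copy(), F_z=np.full(n, fz),
                            N_x=z.copy(), N_y=z.copy())


class TestMethod1:
    def test_zero_inputs_give_zero_com(self, subject, params, inertias):
        plate = _zero_plate()
        sup = SupportMotion.stationary(plate.t)
        est = estimate_method1("ap", plate, sup, params, inertias, subject)
        assert np.allclose(est.disp, 0.0) and np.allclose(est.acc, 0.0)

    def test_static_lean_equilibrium(self, subject, params, inertias):
        # constant moment N_y = m_b*g*0.010 balances a 10 mm COM offset
        plate = _zero_plate()
        plate.N_y[:] = params.m_b * subject.g * 0.010
        sup = SupportMotion.stationary(plate.t)
        est = estimate_method1("ap", plate, sup, params, inertias, subject)
        assert np.allclose(est.disp, 0.010)
        assert np.allclose(est.acc, 0.0)

    @pytest.mark.parametrize("motion,plane", [("ankle_AP", "ap"), ("ankle_ML", "ml")])
    def test_single_pendulum_roundtrip(self, subject, params, inertias, motion, plane):
        spec = sc.MotionSpec(motion=motion, seed=3)
        bundle, truth = sc.simulate_trial(spec, subject, model="single")
        est = estimate_method1(plane, bundle.plate, bundle.support, params, inertias, subject)
        assert sc.rmse_windowed(est.disp, truth.com, FS) < 1e-6
        assert sc.rmse_windowed(est.acc, truth.com_acc, FS) < 1e-6

    def test_length_mismatch_rejected(self, subject, params, inertias):
        plate = _zero_plate()
        sup = SupportMotion.stationary(plate.t[:-10])
        with pytest.raises(ValueError):
            estimate_method1("ap", plate, sup, params, inertias, subject)


class TestMethod2:
    def test_zero_inputs_give_zero_outputs(self, subject, params, inertias):
        plate = _zero_plate()
        sup = SupportMotion.stationary(plate.t)
        head = HeadAcceleration(t=plate.t, acc_x=np.zeros(plate.n), acc_y=np.zeros(plate.n))
        est = estimate_method2("ap", plate, head, sup, params, inertias, subject)
        for series in (est.disp, est.acc, est.acc_lower, est.acc_upper):
            assert np.allclose(series, 0.0)

    @pytest.mark.parametrize(
        "motion,plane",
        [("quiet", "ap"), ("ankle_AP", "ap"), ("ankle_ML", "ml"),
         ("hip_AP", "ap"), ("sway_AP", "ap"), ("sway_ML", "ml")],
    )
    def test_double_pendulum_roundtrip(self, subject, params, inertias, motion, plane):
        bundle, truth = sc.simulate_trial(sc.MotionSpec(motion=motion, seed=5), subject)
        est = estimate_method2(plane, bundle.plate, bundle.head, bundle.support,
                               params, inertias, subject)
        assert sc.rmse_windowed(est.disp, truth.com, FS) < 1e-6
        assert sc.rmse_windowed(est.acc, truth.com_acc, FS) < 1e-6
        assert sc.rmse_windowed(est.acc_lower, truth.seg_lower_acc, FS) < 1e-6
        assert sc.rmse_windowed(est.acc_upper, truth.seg_upper_acc, FS) < 1e-6

    def test_agrees_with_method1_for_consistent_parameters(self, subject, params):
        # with l_b and J_b recomputed from the segment rows the two
        # inversions describe the same generative model, so on in-phase
        # (single-pendulum) data they must coincide; the tabulated
        # coefficients are rounded, which is why this needs the
        # self-consistent set
        p = params
        l_b = (p.m_1 * p.l_1 + p.m_2 * (p.L_1 + p.l_2)) / p.m_b
        iner0 = sc.composite_inertias(p)
        K_s = iner0.J_x1 * p.l_1 + iner0.J_x2 * (p.L_1 + p.l_2)
        J_b = K_s - p.m_b * (p.L_f + l_b) * l_b  # so C_sag * l_b == K_s
        p_cons = dataclasses.replace(p, l_b=l_b, J_b=J_b)
        iner = sc.composite_inertias(p_cons)
        spec = sc.MotionSpec(motion="ankle_AP", seed=9)
        truth = sc.make_trajectories(spec)
        plate, head, sup = sc.inverse_dynamics_linear(truth, p_cons, subject, model="single")
        est1 = estimate_method1("ap", plate, sup, p_cons, iner, subject)
        est2 = estimate_method2("ap", plate, head, sup, p_cons, iner, subject)
        assert np.max(np.abs(est1.disp - est2.disp)) < 1e-9

    def test_singular_matrix_rejected(self, subject, params, inertias):
        # m_1 = 0 with the head lever degenerate (L_2 = l_2) collapses the
        # force and head rows onto one direction
        p = dataclasses.replace(params, m_1=0.0, L_2=params.l_2)
        iner = sc.composite_inertias(p)
        plate = _zero_plate()
        sup = SupportMotion.stationary(plate.t)
        head = HeadAcceleration(t=plate.t, acc_x=np.zeros(plate.n), acc_y=np.zeros(plate.n))
        with pytest.raises(ValueError, match="ill-conditioned"):
            estimate_method2("ap", plate, head, sup, p, iner, subject)

    def test_matrix_structure(self, subject, params, inertias):
        A = method2_matrix("ap", params, inertias, subject)
        assert A[0, 0] == params.m_1 and A[0, 1] == params.m_2 and A[0, 2] == 0.0
        assert A[1, 2] == -params.m_b * subject.g
        assert A[2, 1] == pytest.approx(params.L_2 / params.l_2)


class TestKalman:
    def test_matrices_at_100hz(self):
        A, b, c = build_kalman_matrices(0.01)
        assert np.array_equal(A, [[1.0, 0.01], [0.0, 1.0]])
        assert np.allclose(b, [5e-5, 0.01])
        assert np.array_equal(c, [1.0, 0.0])

    def test_matrices_unit_step(self):
        _, b, _ = build_kalman_matrices(1.0)
        assert np.allclose(b, [0.5, 1.0])

    def test_matrix_shape_invariants(self):
        for dt in (1e-3, 0.02, 2.5):
            A, _, _ = build_kalman_matrices(dt)
            assert A[0, 0] == 1.0 and A[1, 1] == 1.0 and A[1, 0] == 0.0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            KalmanConfig(dt=0.01, Q_v=0.0)
        with pytest.raises(ValueError):
            KalmanConfig(dt=0.01, Q_w=np.array([[1.0, 2.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            KalmanConfig(dt=-0.01)

    def test_zero_inputs_zero_outputs(self):
        cfg = KalmanConfig(dt=0.01)
        d, v = kalman_fuse(np.zeros(500), np.zeros(500), cfg)
        assert np.allclose(d, 0.0) and np.allclose(v, 0.0)

    def test_constant_acceleration_tracking(self):
        # consistent noise-free (y, u) under constant acceleration: the
        # filter locks on within 2 s
        t = np.arange(1000) / 100.0
        a = 0.05
        x = 0.5 * a * t**2
        v = a * t
        d, vel = kalman_fuse(x, np.full_like(t, a), KalmanConfig(dt=0.01))
        w = t >= 2.0
        assert np.max(np.abs(d[w] - x[w])) < 1e-3 * np.max(x)
        assert np.max(np.abs(vel[w] - v[w])) < 1e-3 * np.max(v)

    def test_velocity_beats_differentiated_noisy_displacement(self):
        rng = np.random.default_rng(0)
        t = np.arange(4000) / 100.0
        w0 = 2 * np.pi * 0.5
        x = 0.02 * np.sin(w0 * t)
        v = 0.02 * w0 * np.cos(w0 * t)
        a = -0.02 * w0**2 * np.sin(w0 * t)
        y = x + rng.normal(0.0, 1e-3, t.size)       # 1 mm noise
        u = a + rng.normal(0.0, 1e-2, t.size)       # 10 mm/s^2 noise
        _, vel = kalman_fuse(y, u, KalmanConfig(dt=0.01))
        w = slice(200, None)
        kf = np.sqrt(np.mean((vel[w] - v[w]) ** 2))
        dv = sc.differentiate(y, 100.0)
        naive = np.sqrt(np.mean((dv[w] - v[w]) ** 2))
        assert naive / kf >= 2.0

    def test_noise_free_lag_within_two_samples(self):
        t = np.arange(4000) / 100.0
        x = 0.02 * np.sin(2 * np.pi * 0.5 * t)
        v = np.gradient(x, 0.01)
        a = np.gradient(v, 0.01)
        _, vel = kalman_fuse(x, a, KalmanConfig(dt=0.01))
        corr = [np.corrcoef(vel[200:3800], v[200 - k:3800 - k])[0, 1] for k in range(-3, 4)]
        assert abs(int(np.argmax(corr)) - 3) <= 2

    def test_covariance_stays_symmetric_psd(self):
        rng = np.random.default_rng(1)
        n = 2000
        _, _, states = kalman_fuse(rng.normal(size=n) * 1e-3, rng.normal(size=n) * 1e-2,
                                   KalmanConfig(dt=0.01), return_states=True)
        for s in states[::7]:
            assert np.allclose(s.P, s.P.T)
            assert np.min(np.linalg.eigvalsh(s.P)) >= -1e-12
            assert 0.0 < s.G[0] < 1.0

    def test_non_finite_inputs_flagged_not_silent(self):
        y = np.zeros(300)
        u = np.zeros(300)
        y[100] = np.nan
        d, v = kalman_fuse(y + 0.001, u, KalmanConfig(dt=0.01))
        assert np.isnan(d[100]) and np.isnan(v[100])
        assert np.all(np.isfinite(d[101:]))
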