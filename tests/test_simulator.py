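"""Trajectory generation, linear inverse dynamics and the nonlinear oracle."""

import numpy as np
import pytest

import swaycom as sc
from swaycom.nonlinear import inverse_dynamics_nonlinear
from swaycom.series import GroundTruth, SupportMotion

FS = 100.0


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestSwayWaveform:
    def test_exactly_twenty_harmonics(self):
        disp, _, _ = sc.sway_waveform(40.0, FS, 0.02, seed=3)
        spec = np.abs(np.fft.rfft(disp)) / disp.size
        freqs = np.fft.rfftfreq(disp.size, 1 / FS)
        hot = freqs[spec > 1e-9]
        expected = 0.05 * np.arange(1, 21)
        assert hot.size == 20
        assert np.allclose(np.sort(hot), expected, atol=1e-9)

    def test_rms_scaling_and_zero_amplitude(self):
        disp, _, _ = sc.sway_waveform(40.0, FS, 0.02, seed=3)
        assert _rms(disp) == pytest.approx(0.02, rel=0.15)
        z, zv, za = sc.sway_waveform(40.0, FS, 0.0, seed=3)
        assert not np.any(z) and not np.any(zv) and not np.any(za)

    def test_seed_contract(self):
        a1 = sc.sway_waveform(40.0, FS, 0.02, seed=3)
        a2 = sc.sway_waveform(40.0, FS, 0.02, seed=3)
        b = sc.sway_waveform(40.0, FS, 0.02, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a1, a2))
        assert not np.array_equal(a1[0], b[0])
        # same spectrum magnitudes, different phases
        sa = np.abs(np.fft.rfft(a1[0]))
        sb = np.abs(np.fft.rfft(b[0]))
        assert np.allclose(sa, sb, atol=1e-6)

    def test_acceleration_is_analytic_derivative(self):
        disp, vel, acc = sc.sway_waveform(40.0, FS, 0.02, seed=1)
        num = np.gradient(vel, 1 / FS)
        assert np.allclose(num[2:-2], acc[2:-2], atol=5e-3 * np.max(np.abs(acc)))


class TestTrajectories:
    def test_ankle_peak_frequency(self):
        truth = sc.make_trajectories(sc.MotionSpec(motion="ankle_AP", seed=1))
        spec = np.abs(np.fft.rfft(truth.theta_lower))
        freqs = np.fft.rfftfreq(truth.t.size, 1 / FS)
        assert freqs[np.argmax(spec)] == pytest.approx(0.25, abs=0.02)

    def test_hip_counter_phase(self):
        truth = sc.make_trajectories(sc.MotionSpec(motion="hip_AP", seed=1))
        r = np.corrcoef(truth.theta_lower, truth.theta_upper)[0, 1]
        assert r < -0.9

    def test_quiet_rms_near_target_and_reproducible(self):
        t1 = sc.make_trajectories(sc.MotionSpec(motion="quiet", seed=6))
        t2 = sc.make_trajectories(sc.MotionSpec(motion="quiet", seed=6))
        assert np.array_equal(t1.theta_lower, t2.theta_lower)
        assert _rms(t1.theta_lower) == pytest.approx(0.003, rel=0.2)

    def test_angles_windowed_to_zero_at_ends(self):
        truth = sc.make_trajectories(sc.MotionSpec(motion="ankle_AP", seed=1))
        assert truth.theta_lower[0] == 0.0 and abs(truth.theta_lower[-1]) < 1e-4

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="unknown motion"):
            sc.MotionSpec(motion="jumping")
        with pytest.raises(ValueError, match="integral"):
            sc.MotionSpec(motion="quiet", duration=40.005)
        with pytest.raises(ValueError, match="small-angle"):
            sc.MotionSpec(motion="ankle_AP", amplitude=0.2)

    def test_ground_truth_kinematically_consistent(self, subject, params):
        # twice-differentiated COM displacement reproduces the generated
        # COM acceleration to discretisation accuracy
        truth = sc.make_trajectories(sc.MotionSpec(motion="hip_AP", seed=2))
        sc.inverse_dynamics_linear(truth, params, subject)
        num = np.gradient(np.gradient(truth.com, 1 / FS), 1 / FS)
        w = slice(5, -5)
        # second-order accuracy: relative error ~ (2*pi*f*dt)^2 at the
        # dominant 1 Hz component
        assert np.allclose(num[w], truth.com_acc[w], atol=8e-3 * np.max(np.abs(truth.com_acc)))


class TestLinearInverseDynamics:
    def test_zero_trajectories_fixed_surface(self, subject, params):
        t = np.arange(4000) / FS
        z = np.zeros_like(t)
        truth = GroundTruth(plane="ap", model="double", t=t,
                            theta_lower=z.copy(), theta_upper=z.copy(),
                            theta_lower_d=z.copy(), theta_upper_d=z.copy(),
                            theta_lower_dd=z.copy(), theta_upper_dd=z.copy(),
                            support=SupportMotion.stationary(t))
        plate, head, _ = sc.inverse_dynamics_linear(truth, params, subject)
        assert np.allclose(plate.R_x, 0) and np.allclose(plate.N_y, 0)
        assert np.allclose(plate.F_z, subject.mass * subject.g)
        assert np.allclose(head.acc_x, 0)

    def test_static_lean_moment(self, subject, params):
        t = np.arange(1000) / FS
        z = np.zeros_like(t)
        th = np.full_like(t, 0.01)
        truth = GroundTruth(plane="ap", model="single", t=t,
                            theta_lower=th, theta_upper=th.copy(),
                            theta_lower_d=z.copy(), theta_upper_d=z.copy(),
                            theta_lower_dd=z.copy(), theta_upper_dd=z.copy(),
                            support=SupportMotion.stationary(t))
        plate, _, _ = sc.inverse_dynamics_linear(truth, params, subject, model="single")
        assert np.allclose(plate.N_y, params.m_b * subject.g * truth.com)


class TestNonlinearOracle:
    def test_rest_reaction(self, subject, params):
        t = np.arange(500) / FS
        z = np.zeros_like(t)
        th = np.full_like(t, 0.015)
        truth = GroundTruth(plane="ap", model="double", t=t,
                            theta_lower=th, theta_upper=th.copy(),
                            theta_lower_d=z.copy(), theta_upper_d=z.copy(),
                            theta_lower_dd=z.copy(), theta_upper_dd=z.copy(),
                            support=SupportMotion.stationary(t))
        plate, imu, _ = inverse_dynamics_nonlinear(truth, params, subject)
        assert np.allclose(plate.R_x, 0.0, atol=1e-12)
        assert np.allclose(plate.F_z, subject.mass * subject.g)
        # static moment equals the exact COM moment (trig, not small-angle)
        assert np.allclose(plate.N_y, params.m_b * subject.g * truth.com)
        # IMU at rest reads gravity
        assert np.allclose(np.linalg.norm(imu.acc, axis=1), subject.g)

    @pytest.mark.parametrize("motion,plane", [("hip_AP", "ap"), ("ankle_ML", "ml")])
    def test_momentum_audit(self, subject, params, motion, plane):
        # independent check: reaction force must equal the derivative of
        # total linear momentum computed from positions alone (kinematics
        # re-derived here, not taken from the oracle)
        truth = sc.make_trajectories(sc.MotionSpec(motion=motion, seed=7, background_rms=0.0))
        plate, _, _ = inverse_dynamics_nonlinear(truth, params, subject)
        p = params
        th1, th2 = truth.theta_lower, truth.theta_upper
        if plane == "ap":
            x1 = p.l_1 * np.sin(th1)
            x2 = p.L_1 * np.sin(th1) + p.l_2 * np.sin(th2)
            masses_pos = [(p.m_1, x1), (p.m_2, x2)]
            R = plate.R_x
        else:
            masses_pos = [
                (2 * p.m_l, p.l_l * np.sin(th1)),
                (p.m_p, p.L_l * np.sin(th1)),
                (p.m_u, p.L_l * np.sin(th1) + p.l_u * np.sin(th2)),
            ]
            R = plate.R_y
        dt = 1 / FS
        mom = sum(m * np.gradient(x, dt) for m, x in masses_pos)
        dmom = np.gradient(mom, dt)
        w = slice(200, -200)
        scale = max(1.0, np.max(np.abs(R)))
        assert np.max(np.abs((-R - dmom)[w])) < 5e-3 * scale + 0.05

    def test_small_angle_convergence_quadratic(self, subject, params, inertias):
        # nonlinear reaction converges to the linear one as amplitude
        # shrinks; halving the amplitude cuts the discrepancy by > 4x
        devs = {}
        for deg in (1.0, 0.5):
            spec = sc.MotionSpec(motion="ankle_AP", amplitude=np.deg2rad(deg),
                                 seed=3, background_rms=0.0)
            t_lin = sc.make_trajectories(spec)
            plate_lin, _, _ = sc.inverse_dynamics_linear(t_lin, params, subject, inertias)
            t_non = sc.make_trajectories(spec)
            plate_non, _, _ = inverse_dynamics_nonlinear(t_non, params, subject)
            devs[deg] = _rms(plate_non.N_y[500:3500] - plate_lin.N_y[500:3500])
        assert devs[0.5] < devs[1.0] / 4.0


class TestNoise:
    def test_all_zero_spec_is_identity(self, subject):
        bundle, _ = sc.simulate_trial(sc.MotionSpec(motion="quiet", seed=1), subject)
        plate, head, _, sup = sc.add_noise(sc.NoiseSpec(), plate=bundle.plate,
                                           head=bundle.head, support=bundle.support)
        assert np.array_equal(plate.R_x, bundle.plate.R_x)
        assert np.array_equal(head.acc_x, bundle.head.acc_x)
        assert np.array_equal(sup.acc_x, bundle.support.acc_x)

    def test_seeded_noise_bit_identical(self, subject):
        bundle, _ = sc.simulate_trial(sc.MotionSpec(motion="quiet", seed=1), subject)
        spec = sc.NoiseSpec.realistic(seed=9)
        a = sc.add_noise(spec, plate=bundle.plate, head=bundle.head)
        b = sc.add_noise(spec, plate=bundle.plate, head=bundle.head)
        assert np.array_equal(a[0].N_y, b[0].N_y)
        assert np.array_equal(a[1].acc_x, b[1].acc_x)

    def test_sync_offset_delays_head_stream(self, subject):
        bundle, _ = sc.simulate_trial(sc.MotionSpec(motion="ankle_AP", seed=1), subject)
        _, head, _, _ = sc.add_noise(sc.NoiseSpec(sync_offset_s=0.02), head=bundle.head)
        # a 20 ms delay at 100 Hz is two whole samples
        assert np.allclose(head.acc_x[500:3500], bundle.head.acc_x[498:3498])
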