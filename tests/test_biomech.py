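"""Plant oracles: Hill-muscle closed forms, spindle/GTO behavior, passive
arm mechanics, geometry calibration."""

import numpy as np
import pytest

from reachloop.biomech import (ArmParams, GTOParams, MuscleParams, PlanarArm,
                               SpindleParams)


@pytest.fixture(scope="module")
def arm():
    return PlanarArm()


class TestMuscleTension:
    def test_steady_state_closed_form(self, arm):
        # hold posture and drive fixed; simulated tension must approach
        # T_ss = K_SE (g I + K_PE dx) / (K_SE + K_PE)
        q = np.array(arm.arm.rest_q) + [0.1, -0.15]
        drive = np.full(6, 0.4)
        y = arm.initial_state(q=q)
        for _ in range(3000):
            y = arm.advance(y, 1e-3, drive)
            y[0:2] = q          # clamp the posture
            y[2:4] = 0.0
        mp = arm.muscles
        dx = arm.geometry.muscle_lengths(q) - arm.rest_lengths
        T_ss = mp.k_se * (mp.gain * drive + mp.k_pe * dx) / (mp.k_se + mp.k_pe)
        assert np.allclose(y[4:10], T_ss, rtol=1e-3, atol=1e-6)

    def test_zero_input_at_rest_zero_tension(self, arm):
        assert np.allclose(arm.steady_tension(np.zeros(6)), 0.0, atol=1e-12)

    def test_tension_monotone_in_drive(self, arm):
        T1 = arm.steady_tension(np.full(6, 0.2))
        T2 = arm.steady_tension(np.full(6, 0.8))
        assert np.all(T2 > T1)


class TestBagFibersAndSpindle:
    def test_bag_steady_state_closed_form(self, arm):
        sp = arm.spindles
        q = np.array(arm.arm.rest_q) + [0.0, -0.2]
        y = arm.initial_state(q=q)
        L = arm.geometry.muscle_lengths(q)
        expect = sp.k_se_s * sp.k_pe_s / (sp.k_se_s + sp.k_pe_s) \
            * (L - arm.rest_s)
        assert np.allclose(y[10:16], expect)

    def test_dynamic_bag_transient_exceeds_static_value(self, arm):
        # ramp stretch: the heavily damped dynamic bag builds more tension
        # than its own static value at the same length
        q0 = np.array(arm.arm.rest_q)
        y = arm.initial_state(q=q0)
        sp = arm.spindles
        rate = 0.5  # rad/s on the elbow
        for k in range(800):
            y = arm.advance(y, 1e-3, np.zeros(6))
            y[0:2] = q0 + [0.0, -rate * (k + 1) * 1e-3]
            y[2:4] = [0.0, -rate]
        L = arm.geometry.muscle_lengths(y[0:2])
        static_value = sp.k_se_d * sp.k_pe_d / (sp.k_se_d + sp.k_pe_d) \
            * (L - arm.rest_d)
        stretched = arm.geometry.moment_arms(y[0:2])[:, 1] < 0  # lengthening (q2 falls)
        assert np.all(y[16:22][stretched] > static_value[stretched])

    def test_spindle_outputs_zero_at_full_rest(self, arm):
        y = arm.initial_state()
        y[10:22] = 0.0
        ia, ib, ii = arm.afferents(y)
        assert np.allclose(ia, 0) and np.allclose(ii, 0) and np.allclose(ib, 0)

    def test_ii_monotone_in_static_length(self, arm):
        # sweep elbow angle; II of the elbow flexor must rise with its length
        iis = []
        lens = []
        for q2 in np.linspace(np.deg2rad(60), np.deg2rad(140), 9):
            q = np.array([0.0, q2])
            _, _, ii = arm.steady_afferents(q)
            iis.append(ii[2])
            lens.append(arm.geometry.muscle_lengths(q)[2])
        order = np.argsort(lens)
        assert np.all(np.diff(np.array(iis)[order]) > 0)

    def test_pure_static_fraction(self):
        arm2 = PlanarArm(spindles=SpindleParams(f_s_ia=1.0))
        y = arm2.initial_state()
        y[16:22] = 999.0   # dynamic bag tension must not matter
        ia1, _, _ = arm2.afferents(y)
        y[16:22] = 0.0
        ia2, _, _ = arm2.afferents(y)
        assert np.allclose(ia1, ia2)


class TestGTO:
    def test_rectification(self, arm):
        g = arm.gto
        y = arm.initial_state()
        y[4:10] = -5.0     # negative tension: rate must be zero
        dy = arm.rhs(y, np.zeros(6))
        assert np.allclose(dy[22:28], (0.0 - y[22:28]) / g.tau_ib)

    def test_log_scale_value(self, arm):
        g = arm.gto
        y = arm.initial_state()
        y[4:10] = g.t0
        y[22:28] = 0.0
        dy = arm.rhs(y, np.zeros(6))
        assert np.allclose(dy[22:28] * g.tau_ib, g.g_ib * np.log(2.0))

    def test_first_order_step_response(self, arm):
        g = arm.gto
        r_target = g.g_ib * np.log(2.0)
        ib = 0.0
        dt = 1e-4
        for _ in range(int(g.tau_ib / dt)):
            ib += dt * (r_target - ib) / g.tau_ib
        assert ib == pytest.approx(r_target * (1 - np.e ** -1), rel=1e-3)


class TestArmDynamics:
    def test_zero_tension_zero_velocity_zero_accel(self, arm):
        for q in ([0.0, np.pi / 2], [0.5, 1.0], [-0.2, 2.0]):
            y = arm.initial_state(q=q)
            y[4:22] = 0.0
            dy = arm.rhs(y, np.zeros(6))
            assert np.allclose(dy[2:4], 0.0, atol=1e-12)

    def test_passive_energy_dissipation(self, arm):
        # released with velocity and no drive: kinetic + parallel-elastic
        # energy decreases along the whole trajectory
        y = arm.initial_state(q=np.array(arm.arm.rest_q) + [0.2, -0.2])
        y[2:4] = [1.0, -1.0]
        energies = []
        for _ in range(8000):
            y = arm.advance(y, 1e-3, np.zeros(6))
            energies.append(arm.energy(y) + arm.elastic_energy(y))
        e = np.array(energies)
        # viscous friction dissipates monotonically; the weak parallel
        # elasticity drains the rest over seconds
        assert e[-1] < 0.1 * e[0]
        assert np.all(np.diff(e) < 1e-6)

    def test_passive_fixed_point_at_rest(self, arm):
        # the rest posture is the unforced plant's fixed point: starting
        # there it stays; starting perturbed it contracts toward it (the
        # softest elastic direction makes full convergence very slow)
        y = arm.initial_state()
        for _ in range(3000):
            y = arm.advance(y, 1e-3, np.zeros(6))
        assert np.allclose(y[0:2], arm.arm.rest_q, atol=1e-6)
        dq0 = np.array([0.15, -0.2])
        y = arm.initial_state(q=np.array(arm.arm.rest_q) + dq0)
        for _ in range(60_000):
            y = arm.advance(y, 1e-3, np.zeros(6))
        dq1 = y[0:2] - np.asarray(arm.arm.rest_q)
        assert np.all(np.abs(dq1) < 0.5 * np.abs(dq0))
        assert np.allclose(y[2:4], 0.0, atol=1e-2)

    def test_antagonist_cocontraction_near_zero_torque(self, arm):
        q0 = np.asarray(arm.arm.rest_q)
        dldq = arm.geometry.moment_arms(q0)
        T = np.full(6, 20.0)
        torque = -(T[:, None] * dldq).sum(axis=0)
        passive = 20.0 * np.abs(dldq).sum() / 2
        assert np.all(np.abs(torque) < 0.15 * passive)


class TestGeometryAndCalibration:
    def test_rest_lengths_exact(self, arm):
        L = arm.geometry.muscle_lengths(np.asarray(arm.arm.rest_q))
        assert np.allclose(L, arm.rest_lengths)
        # pulley lengths agree with attachment chords at the rest posture
        assert np.allclose(L, arm.geometry.chord_lengths(
            np.asarray(arm.arm.rest_q)))

    def test_elbow_flexion_shortens_flexor_lengthens_extensor(self, arm):
        q0 = np.asarray(arm.arm.rest_q)
        L0 = arm.geometry.muscle_lengths(q0)
        L1 = arm.geometry.muscle_lengths(q0 + [0.0, 0.3])
        assert L1[2] < L0[2]        # elbow flexor
        assert L1[5] > L0[5]        # elbow extensor

    def test_moment_arm_signs_stable_over_workspace(self, arm):
        signs0 = np.sign(arm.geometry.moment_arms(np.asarray(arm.arm.rest_q)))
        for q1 in np.linspace(np.deg2rad(-20), np.deg2rad(110), 7):
            for q2 in np.linspace(np.deg2rad(10), np.deg2rad(150), 7):
                d = arm.geometry.moment_arms([q1, q2])
                assert np.all((np.sign(d) == signs0) | (signs0 == 0))

    def test_contraction_sign_pattern_for_peripheral_target(self, arm):
        # a target up-left of the center must require contraction of the
        # flexor group and lengthening of the extensors
        q_t = arm.inverse_kinematics((0.3 - 0.1 / np.sqrt(2),
                                      0.3 + 0.1 / np.sqrt(2)))
        L0 = arm.rest_lengths
        Lt = arm.geometry.muscle_lengths(q_t)
        rel = (L0 - Lt) / L0
        assert rel[1] > 0 and rel[4] < 0     # shoulder flexor vs extensor

    def test_bag_rest_lengths_are_scaled_muscle_rest(self, arm):
        assert np.allclose(arm.rest_s, arm.spindles.l0_s * arm.rest_lengths)
        assert np.allclose(arm.rest_d, arm.spindles.l0_d * arm.rest_lengths)

    def test_release_from_perturbation_returns_toward_rest(self, arm):
        q0 = np.asarray(arm.arm.rest_q)
        q_pert = arm.inverse_kinematics(arm.hand_position(q0) + [0.01, 0.0])
        y = arm.initial_state(q=q_pert)
        d0 = np.linalg.norm(arm.hand_position(y[0:2]) - arm.hand_position(q0))
        for _ in range(12_000):
            y = arm.advance(y, 1e-3, np.zeros(6))
        d1 = np.linalg.norm(arm.hand_position(y[0:2]) - arm.hand_position(q0))
        assert d1 < 0.6 * d0

    def test_ik_roundtrip(self, arm):
        for xy in ([0.25, 0.35], [0.4, 0.2], [0.1, 0.4]):
            q = arm.inverse_kinematics(xy)
            assert np.allclose(arm.hand_position(q), xy, atol=1e-10)

    def test_unreachable_target_raises(self, arm):
        with pytest.raises(ValueError):
            arm.inverse_kinematics((2.0, 2.0))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            ArmParams(m1=-1.0)
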