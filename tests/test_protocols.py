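"""Protocol contracts: target encoding, schedules, stimulation fields."""

import numpy as np
import pytest

from reachloop import network as net
from reachloop import protocols as proto
from reachloop.engine import Engine, IntegratorConfig


class TestTargetToSP:
    def test_rest_target_equals_rest_sa(self, static_network):
        sp = proto.target_to_sp(
            np.asarray(static_network.plant.arm.rest_q), static_network)
        # SA thresholds are calibrated so rest activity is exactly 1/2
        assert np.allclose(sp, 0.5, atol=1e-9)

    def test_flexor_shortening_target_lowers_its_sp_component(
            self, static_network):
        # elbow flexion shortens the elbow flexor (muscle 2); by the II
        # length monotonicity its SP component drops below the rest value
        q = np.asarray(static_network.plant.arm.rest_q) + [0.0, 0.4]
        sp = proto.target_to_sp(q, static_network)
        assert sp[2] < 0.5
        assert sp[5] > 0.5    # antagonist stretched

    def test_distinct_targets_distinct_patterns(self, static_network):
        rng = np.random.default_rng(0)
        qs = proto.sample_joint_targets(6, rng, static_network.plant)
        sps = [proto.target_to_sp(q, static_network) for q in qs]
        for i in range(len(sps)):
            for j in range(i + 1, len(sps)):
                assert not np.allclose(sps[i], sps[j], atol=1e-4)

    def test_degenerate_target_rejected(self, static_network):
        with pytest.raises(ValueError):
            # pulls a muscle length through zero
            proto.target_to_sp([40.0, 40.0], static_network)


class TestSchedules:
    def test_onsets_strictly_increasing(self):
        s = proto.TargetSchedule()
        s.add(0.0, np.zeros(6), (0.3, 0.3))
        with pytest.raises(ValueError):
            s.add(0.0, np.zeros(6), (0.3, 0.3))

    def test_center_out_visits_each_target_six_times(self, center_out_static):
        _, res = center_out_static
        counts = np.bincount([k for k, _, _ in res.reach_slices],
                             minlength=8)
        assert (counts == 6).all()
        assert len(res.reach_slices) == 48

    def test_sampled_targets_within_ranges(self, plant):
        rng = np.random.default_rng(5)
        for q in proto.sample_joint_targets(20, rng, plant):
            assert proto.SHOULDER_RANGE[0] <= q[0] <= proto.SHOULDER_RANGE[1]
            assert proto.ELBOW_RANGE[0] <= q[1] <= proto.ELBOW_RANGE[1]


class TestDualErrorContract:
    def _spa_pair(self, eng, sp_shift):
        sp = eng.act[net.SP].copy()
        sp[0] += sp_shift
        sched = proto.TargetSchedule()
        sched.add(0.0, sp, (0.3, 0.3))
        eng.run(0.5, schedule=sched, freeze_plant_for=0.5)
        return (eng.act[net.SPA.start + 0], eng.act[net.SPA.start + 6])

    def test_balanced_error_balanced_pair(self, static_engine):
        static_engine.set_noise(False)
        static_engine.run(0.5, freeze_plant_for=0.5)
        a, b = (static_engine.act[net.SPA.start],
                static_engine.act[net.SPA.start + 6])
        assert a == pytest.approx(b, abs=0.02)

    def test_positive_error_activates_one_side(self, static_engine):
        static_engine.set_noise(False)
        lo, hi = self._spa_pair(static_engine, +0.3)
        # SP raised above SA: the "lengthen" unit (dual, index 6+i) rises,
        # the "shorten" unit is suppressed
        assert hi > lo

    def test_swapping_inputs_swaps_the_pair(self, static_engine):
        static_engine.set_noise(False)
        lo1, hi1 = self._spa_pair(static_engine, +0.3)
        static_engine.reset(sp=np.full(6, 0.5))
        lo2, hi2 = self._spa_pair(static_engine, -0.3)
        assert np.sign(hi1 - lo1) == -np.sign(hi2 - lo2)
        assert hi1 == pytest.approx(lo2, abs=0.05)


@pytest.fixture(scope="module")
def stim_engine():
    nw = net.build("static", seed=1)
    return Engine(nw, IntegratorConfig(seed=1))


class TestSpinalStimulation:

    def test_single_site_field_convergent(self, stim_engine):
        f = proto.spinal_stimulation(stim_engine, (0,))
        assert f.vectors.shape == (25, 2)
        assert np.allclose(np.linalg.norm(f.vectors, axis=1), 1.0, atol=1e-9)
        fp = f.fixed_point()
        assert 0.15 <= fp[0] <= 0.45 and 0.15 <= fp[1] <= 0.45

    def test_antagonist_fields_differ(self, stim_engine):
        from reachloop.analysis import wrap_angle
        f0 = proto.spinal_stimulation(stim_engine, (0,))
        f3 = proto.spinal_stimulation(stim_engine, (3,))
        diff = np.abs(wrap_angle(f0.angles() - f3.angles()))
        assert np.rad2deg(diff.mean()) > 2.0

    def test_out_of_workspace_grid_points_skipped(self, stim_engine):
        grid = np.array([[0.3, 0.3], [5.0, 5.0]])
        f = proto.spinal_stimulation(stim_engine, (0,), grid=grid)
        assert len(f.grid) == 1


def test_mass_change_preserves_rest_posture(plant):
    # no gravity: scaling the masses leaves the rest fixed point unchanged
    q0 = np.asarray(plant.arm.rest_q)
    y = plant.initial_state()
    plant.arm.m1 = plant.arm.m2 = 0.8
    plant._pack()
    try:
        dy = plant.rhs(y, np.zeros(6))
        assert np.allclose(dy[2:4], 0.0, atol=1e-10)
    finally:
        plant.arm.m1 = plant.arm.m2 = 1.0
        plant._pack()


def test_reach_metrics_trivial_cases(center_out_static):
    from reachloop.analysis import reach_metrics
    _, res = center_out_static
    out = reach_metrics(res.trace, res.reach_slices, res.targets)
    assert len(out) == 48
    errs = [o["error"] for o in out]
    assert all(e < 0.10 for e in errs)    # every reach succeeds


class TestDriftAndMass:
    def test_static_pd_drift_negligible_and_reaching_intact(self):
        # frozen weights: continued reaching leaves the PDs essentially
        # unchanged and the error in the few-cm range
        nw = net.build("static", seed=1)
        eng = Engine(nw, IntegratorConfig(seed=1))
        eng.reset(sp=proto.target_to_sp(np.asarray(nw.plant.arm.rest_q), nw))
        out = proto.pd_drift_protocol(eng, n_reaches=20)
        assert out["pd_change_deg"].mean() < 2.0
        assert out["mean_error"] < 0.06

    def test_mass_change_center_out_errors_stay_small(self):
        nw = net.build("static", seed=1)
        eng = Engine(nw, IntegratorConfig(seed=1))
        eng.reset(sp=proto.target_to_sp(np.asarray(nw.plant.arm.rest_q), nw))
        res = proto.mass_change_protocol(eng, n_reps=1)
        for mass, r in res.items():
            assert r.mean_error < 0.06, f"mass {mass}"
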