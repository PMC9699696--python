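"""Integration contracts: determinism, delays, bounds, dt convergence."""

import numpy as np
import pytest

from reachloop import network as net
from reachloop import protocols as proto
from reachloop.engine import Engine, IntegratorConfig


def _fresh_engine(seed=1, dt=0.001, configuration="static"):
    nw = net.build(configuration, seed=seed)
    eng = Engine(nw, IntegratorConfig(seed=seed, dt=dt))
    rest_sp = proto.target_to_sp(np.asarray(nw.plant.arm.rest_q), nw)
    eng.reset(sp=rest_sp)
    return eng


class TestDeterminism:
    def test_same_seed_identical_traces(self):
        traces = []
        for _ in range(2):
            eng = _fresh_engine(seed=3)
            eng.set_noise(True)
            traces.append(eng.run(2.0))
        assert np.array_equal(traces[0].activities, traces[1].activities)
        assert np.array_equal(traces[0].plant, traces[1].plant)

    def test_zero_noise_matches_deterministic_path(self):
        # sigma = 0 for every unit must reproduce the noise-off trajectory
        # exactly (degenerate Langevin; clipping aside, same updates)
        nw = net.build("static", seed=3)
        nw.noise[:] = 0.0
        eng1 = Engine(nw, IntegratorConfig(seed=3))
        rest_sp = proto.target_to_sp(np.asarray(nw.plant.arm.rest_q), nw)
        eng1.reset(sp=rest_sp)
        eng1.set_noise(True)       # noise "on" but amplitude zero
        tr1 = eng1.run(1.0)

        eng2 = _fresh_engine(seed=3)
        eng2.set_noise(False)
        tr2 = eng2.run(1.0)
        assert np.allclose(tr1.activities, tr2.activities)

    def test_schedule_determinism(self):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(11)
            outs.append(proto.sample_joint_targets(
                5, rng, _fresh_engine().plant))
        assert np.allclose(np.array(outs[0]), np.array(outs[1]))


class TestDelays:
    def test_downstream_response_lags_by_transmission_delay(self):
        # step SP; SPA units receive SP through a 5 ms edge, so their drift
        # away from baseline must start 5 ms (+- dt and one time constant)
        # after the step, not before
        eng = _fresh_engine()
        eng.set_noise(False)
        eng.run(1.0)
        sp_step = eng.act[net.SP].copy()
        sp_step[0] += 0.2
        sched = proto.TargetSchedule()
        sched.add(0.0, sp_step, (0.3, 0.3))
        tr = eng.run(0.05, schedule=sched, record_every=0.001)
        spa = tr.activities[:, net.SPA.start + 6]   # dual of muscle 0
        base = spa[0]
        dev = np.abs(spa - base)
        onset = np.argmax(dev > 20 * (dev[1] + 1e-15))
        delay_steps = round(eng.network.params.delay_local / eng.cfg.dt)
        assert delay_steps <= onset <= delay_steps + 10

    def test_dt_exceeding_min_delay_rejected(self):
        nw = net.build("static", seed=0)
        with pytest.raises(ValueError):
            Engine(nw, IntegratorConfig(dt=0.01))   # min delay is 5 ms

    def test_delay_buffer_read(self):
        eng = _fresh_engine()
        eng.set_noise(False)
        eng.run(0.2)
        buf = eng.state.buffer
        assert buf.read(net.SA.start, 0.0) == eng.act[net.SA.start]
        with pytest.raises(ValueError):
            buf.read(0, 10.0)


class TestBoundsAndSanity:
    def test_activities_bounded_under_noise(self):
        eng = _fresh_engine(seed=7)
        eng.set_noise(True)
        tr = eng.run(3.0)
        sig = np.ones(net.N_UNITS, bool)
        sig[net.A] = False
        sig[net.SP] = False
        assert tr.activities[:, sig].min() >= 0.0
        assert tr.activities[:, sig].max() <= 1.0
        assert tr.activities[:, net.A].min() >= 0.0

    def test_zero_duration_returns_initial_state_only(self):
        eng = _fresh_engine()
        tr = eng.run(0.0)
        assert len(tr) == 1
        assert np.allclose(tr.activities[0], eng.act)

    def test_dt_convergence_of_reach_endpoint(self):
        # halving the neural step changes a 5 s deterministic reach's final
        # hand position by well under a millimeter
        ends = []
        for dt in (0.001, 0.0005):
            eng = _fresh_engine(dt=dt)
            eng.set_noise(False)
            sp, q = proto.sp_for_hand((0.25, 0.35), eng.network)
            sched = proto.TargetSchedule()
            sched.add(0.0, sp, (0.25, 0.35), q)
            tr = eng.run(5.0, schedule=sched)
            ends.append(tr.hand[-1])
        assert np.linalg.norm(ends[0] - ends[1]) < 1e-3

    def test_static_single_target_reach_under_10cm(self):
        # a 40 s presentation ends well within the success criterion
        eng = _fresh_engine(seed=2)
        eng.set_noise(False)
        q = np.deg2rad([40.0, 60.0])
        sp = proto.target_to_sp(q, eng.network)
        hx = eng.plant.hand_position(q)
        sched = proto.TargetSchedule()
        sched.add(0.0, sp, hx, q)
        tr = eng.run(40.0, schedule=sched, record_every=0.05)
        d = np.linalg.norm(tr.hand - hx, axis=1)
        assert d[len(d) // 2:].mean() < 0.10


class TestTraceIO:
    def test_hdf5_roundtrip(self, tmp_path):
        eng = _fresh_engine()
        tr = eng.run(0.2)
        path = tmp_path / "trace.h5"
        tr.save(path)
        back = type(tr).load(path)
        assert np.allclose(back.activities, tr.activities)
        assert np.allclose(back.plant, tr.plant)

    def test_csv_export(self, tmp_path):
        eng = _fresh_engine()
        tr = eng.run(0.1)
        path = tmp_path / "trace.csv"
        tr.save(path, fmt="csv")
        import pandas as pd
        df = pd.read_csv(path)
        assert "hand_x" in df.columns and "u73" in df.columns
        assert len(df) == len(tr)

    def test_weight_recording_cadence(self):
        nw = net.build("spinal_learning", seed=4)
        eng = Engine(nw, IntegratorConfig(seed=4))
        tr = eng.run(1.0, weight_record_every=0.25)
        assert tr.weights is not None
        assert tr.weights.shape == (4, len(eng.ew))
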