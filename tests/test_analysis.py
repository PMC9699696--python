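"""Analysis oracles on synthetic fixtures with known ground truth."""

import numpy as np
import pytest

from reachloop import analysis as ana
from reachloop import fixtures as fx


class TestPDVectors:
    def test_recovers_generating_angle(self):
        f = fx.make_fixture("cosine_tuned_rates", seed=0, pd_deg=(30.0, -60.0))
        pd_vec = ana.pd_vectors(f["rates"], f["labels"], f["targets"],
                                f["center"])
        got = np.rad2deg(np.arctan2(pd_vec[:, 1], pd_vec[:, 0]))
        assert np.allclose(got, [30.0, -60.0], atol=1.0)

    def test_flat_rates_give_zero_vector(self):
        f = fx.make_fixture("cosine_tuned_rates", seed=0, depth=0.0)
        pd_vec = ana.pd_vectors(f["rates"], f["labels"], f["targets"],
                                f["center"])
        assert np.allclose(pd_vec, 0.0, atol=1e-12)

    def test_rank_deficient_targets_rejected(self):
        rates = np.ones((4, 2))
        labels = np.array([0, 1, 0, 1])
        targets = np.array([[0.3, 0.3], [0.3, 0.3]])  # no spatial spread
        with pytest.raises(ValueError):
            ana.pd_vectors(rates, labels, targets, (0.3, 0.3))


class TestTuningTest:
    def test_strong_tuning_significant(self):
        f = fx.make_fixture("cosine_tuned_rates", seed=1, pd_deg=(45.0,),
                            noise=0.02)
        p = ana.tuning_test(f["rates"], f["labels"], f["targets"],
                            f["center"], n_shuffles=2000, rng=0)
        assert p[0] < 0.001

    def test_untuned_rates_not_significant(self):
        rng = np.random.default_rng(2)
        f = fx.make_fixture("cosine_tuned_rates", seed=2, depth=0.0)
        rates = 0.5 + 0.1 * rng.standard_normal(f["rates"].shape)
        p = ana.tuning_test(rates, f["labels"], f["targets"], f["center"],
                            n_shuffles=500, rng=0)
        assert p[0] > 0.01

    def test_constant_rates_never_exceed_shuffles(self):
        f = fx.make_fixture("cosine_tuned_rates", seed=0, depth=0.0)
        p = ana.tuning_test(f["rates"], f["labels"], f["targets"],
                            f["center"], n_shuffles=200, rng=0)
        assert p[0] == 1.0   # PD length 0 ties every shuffle


class TestMainAxisAndBimodality:
    def test_axial_identification(self):
        pd_vec = np.array([[np.cos(0.4), np.sin(0.4)],
                           [-np.cos(0.4), -np.sin(0.4)]])
        assert ana.main_axis(pd_vec) == pytest.approx(np.rad2deg(0.4), abs=1e-6)

    def test_single_vector(self):
        v = np.array([[np.cos(np.pi / 6), np.sin(np.pi / 6)]])
        assert ana.main_axis(v) == pytest.approx(30.0, abs=1e-9)

    def test_rotating_all_by_180_invariant(self):
        rng = np.random.default_rng(3)
        pd_vec = rng.standard_normal((10, 2))
        assert ana.main_axis(pd_vec) == pytest.approx(
            ana.main_axis(-pd_vec), abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            ana.main_axis(np.zeros((5, 2)))

    def test_identical_angles_reach_maximal_r(self):
        phi = np.full(12, 0.7)
        r, _ = ana.bimodality_test(phi, n_null=1000, rng=0)
        assert r == pytest.approx(12.0)

    def test_axial_pair_also_maximal(self):
        # angles at phi and phi+pi are the same axial direction
        phi = np.array([0.7] * 6 + [0.7 + np.pi] * 6)
        r, p = ana.bimodality_test(phi, n_null=5000, rng=0)
        assert r == pytest.approx(12.0)
        assert p < 0.001

    def test_uniform_angles_not_significant(self):
        rng = np.random.default_rng(4)
        phi = rng.uniform(0, 2 * np.pi, 200)
        r, p = ana.bimodality_test(phi, n_null=2000, rng=0)
        assert p > 0.01


class TestJPCA:
    def test_pure_rotation_captured_by_plane_one(self):
        f = fx.make_fixture("rotational_traces", seed=0)
        res = ana.jpca(f["traces"], f["dt"])
        assert res.variance_fractions[0] > 0.99

    def test_skew_antisymmetric_and_exact_decomposition(self):
        f = fx.make_fixture("rotational_traces", seed=1, noise=0.05)
        res = ana.jpca(f["traces"], f["dt"])
        assert np.allclose(res.m_skew, -res.m_skew.T, atol=1e-12)
        m_symm = res.m_hat - res.m_skew
        assert np.allclose(m_symm, m_symm.T, atol=1e-12)

    def test_variance_fractions_sorted_and_bounded(self):
        f = fx.make_fixture("rotational_traces", seed=2, noise=0.2)
        res = ana.jpca(f["traces"], f["dt"])
        v = res.variance_fractions
        assert np.all(np.diff(v) <= 1e-12)
        assert np.all(v >= 0) and v.sum() <= 1.0 + 1e-9

    def test_recovers_rotation_frequency(self):
        f = fx.make_fixture("rotational_traces", seed=3)
        res = ana.jpca(f["traces"], f["dt"])
        assert res.frequencies[0] == pytest.approx(f["omega"], rel=0.05)


class TestGamma:
    def test_additive_fields_give_zero(self):
        fields = fx.make_fixture("toy_direction_fields", seed=0)
        g = ana.field_angle_difference(fields[(0, 1)], fields[(0,)],
                                       fields[(1,)])
        assert g == pytest.approx(0.0, abs=1e-9)

    def test_self_difference_zero(self):
        fields = fx.make_fixture("toy_direction_fields", seed=0)
        f = fields[(0,)]
        # gamma(F, F): compare a field against the sum of two half-copies
        import dataclasses
        half = dataclasses.replace(f, vectors=0.5 * f.vectors)
        assert ana.field_angle_difference(f, half, half) \
            == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_grids_rejected(self):
        fields = fx.make_fixture("toy_direction_fields", seed=0)
        import dataclasses
        other = dataclasses.replace(fields[(1,)],
                                    grid=fields[(1,)].grid + 0.05)
        with pytest.raises(ValueError):
            ana.field_angle_difference(fields[(0, 1)], fields[(0,)], other)

    def test_minimal_rotation_convention(self):
        assert ana.wrap_angle(np.deg2rad(350)) \
            == pytest.approx(np.deg2rad(-10))
        assert ana.wrap_angle(np.deg2rad(-190)) \
            == pytest.approx(np.deg2rad(170))


class TestPredictPD:
    def test_perfect_prediction_r2_one(self):
        v_bars = np.array([[np.cos(a), np.sin(a)]
                           for a in np.linspace(0, 2 * np.pi, 6, False)])
        w = np.vstack([np.eye(6), -np.eye(6)])
        pd_true = w @ v_bars
        res = ana.predict_pd(pd_true, v_bars, w)
        assert res.r2 == pytest.approx(1.0)
        assert np.allclose(res.residuals_deg, 0.0, atol=1e-9)

    def test_one_to_one_weights_reproduce_muscle_vectors(self):
        v_bars = np.random.default_rng(0).standard_normal((6, 2))
        w = np.vstack([np.eye(6), -np.eye(6)])
        res = ana.predict_pd(w @ v_bars, v_bars, w)
        assert np.allclose(res.predicted[:6], v_bars)
        assert np.allclose(res.predicted[6:], -v_bars)


class TestScriptedLearningSignals:
    def test_known_causal_lag_recovered(self):
        # the scripted pair's Hebbian drive must be strongest (and of the
        # documented sign) near the built-in lag
        from reachloop.plasticity import DerivativeEstimator
        f = fx.make_fixture("scripted_learning_signals", seed=0)
        c, e, dt, lag = f["c"], f["e"], f["dt"], f["lag_steps"]
        est_c = DerivativeEstimator(1)
        est_e = DerivativeEstimator(1)
        c_d = np.zeros(len(c))
        e_dd = np.zeros(len(e))
        for t in range(len(c)):
            c_d[t] = est_c.update(np.array([c[t]]), dt)[0][0]
            e_dd[t] = est_e.update(np.array([e[t]]), dt)[1][0]
        burn = 2000
        corr = {}
        for L in (10, lag, 5 * lag):
            corr[L] = -np.mean(e_dd[burn:] * c_d[burn - L:len(c) - L])
        assert corr[lag] > corr[10]
        assert corr[lag] > 0
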