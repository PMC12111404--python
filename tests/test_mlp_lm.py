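"""MLP forward pass, analytic Jacobian, and Levenberg-Marquardt training."""

import numpy as np
import pytest

from dephenolize import (
    ExperimentTable,
    MLPParams,
    MLPSurrogate,
    evaluate_fit,
    mlp_forward,
    train_lm,
)
from dephenolize.lm import levenberg_marquardt
from dephenolize.mlp import mlp_jacobian


def tiny_params():
    return MLPParams(
        w_ih=np.array([[1.0, 0.0, 0.0]]), b_h=np.zeros(1),
        w_ho=np.array([1.0]), b_o=0.0,
    )


class TestForward:
    def test_zero_network_outputs_zero(self):
        p = MLPParams(w_ih=np.zeros((4, 3)), b_h=np.zeros(4),
                      w_ho=np.zeros(4), b_o=0.0)
        assert mlp_forward(p, np.array([1.0, -2.0, 0.3])) == 0.0

    def test_single_neuron_hand_value(self):
        # f(x) = tanh(x1) at x1=0.5
        out = mlp_forward(tiny_params(), np.array([0.5, 9.0, -9.0]))
        assert out == pytest.approx(0.46211715726, abs=1e-10)

    def test_odd_symmetry_with_zero_biases(self, rng):
        p = MLPParams(w_ih=rng.normal(size=(5, 3)), b_h=np.zeros(5),
                      w_ho=rng.normal(size=5), b_o=0.0)
        x = rng.normal(size=3)
        assert mlp_forward(p, -x) == pytest.approx(-mlp_forward(p, x), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mlp_forward(tiny_params(), np.ones((2, 4)))

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ValueError):
            MLPParams(w_ih=np.array([[np.nan, 0, 0]]), b_h=np.zeros(1),
                      w_ho=np.ones(1), b_o=0.0)


class TestJacobian:
    @pytest.mark.parametrize("n_hidden", [1, 3, 7])
    def test_matches_central_differences(self, n_hidden, rng):
        p = MLPParams.init_random(n_hidden, rng)
        x = rng.normal(size=(6, 3))
        theta = p.pack()
        jac = mlp_jacobian(p, x)
        eps = 1e-6
        fd = np.empty_like(jac)
        for j in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[j] += eps
            tm[j] -= eps
            fp = mlp_forward(MLPParams.unpack(tp, n_hidden), x)
            fm = mlp_forward(MLPParams.unpack(tm, n_hidden), x)
            fd[:, j] = (fp - fm) / (2 * eps)
        np.testing.assert_allclose(jac, fd, rtol=1e-6, atol=1e-8)

    def test_pack_unpack_round_trip(self, rng):
        p = MLPParams.init_random(4, rng)
        q = MLPParams.unpack(p.pack(), 4)
        np.testing.assert_array_equal(p.w_ih, q.w_ih)
        np.testing.assert_array_equal(p.b_h, q.b_h)
        np.testing.assert_array_equal(p.w_ho, q.w_ho)
        assert p.b_o == q.b_o


class TestLevenbergMarquardt:
    def test_monotone_sse_path(self, noisy_table):
        res = MLPSurrogate(noisy_table).fit(5, seed=3)
        assert np.all(np.diff(res.sse_path) <= 0)

    def test_quadratic_exact_in_one_step(self):
        # linear residual: LM is Gauss-Newton and lands on the lsq solution
        a = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.5]])
        b = np.array([1.0, -1.0, 2.0])
        res = levenberg_marquardt(
            lambda t: a @ t - b, lambda t: a, np.zeros(2)
        )
        expect, *_ = np.linalg.lstsq(a, b, rcond=None)
        np.testing.assert_allclose(res.theta, expect, atol=1e-8)

    def test_matches_scipy_on_rosenbrock_residuals(self):
        # independent check against the established MINPACK-style solver
        from scipy.optimize import least_squares

        def resid(t):
            return np.array([10 * (t[1] - t[0] ** 2), 1 - t[0]])

        def jac(t):
            return np.array([[-20 * t[0], 10.0], [-1.0, 0.0]])

        mine = levenberg_marquardt(resid, jac, np.array([-1.2, 1.0]),
                                   max_iter=500)
        ref = least_squares(resid, np.array([-1.2, 1.0]), jac=jac, method="lm")
        np.testing.assert_allclose(mine.theta, ref.x, atol=1e-6)


class TestTraining:
    def test_linear_surface_learned_by_two_neurons(self):
        rng = np.random.default_rng(1)
        x = rng.uniform([70, 10, 5], [90, 60, 25], size=(33, 3))
        table = ExperimentTable.from_arrays(x, 2.0 * x[:, 0])
        best = MLPSurrogate(table).fit_best(2, n_inits=5, seed=0)
        assert best.r2 >= 0.999

    def test_noiseless_default_table_interpolated(self, noiseless_fit):
        assert noiseless_fit.r2 >= 0.99

    def test_deterministic_per_seed(self, noisy_table):
        m = MLPSurrogate(noisy_table)
        r1 = m.fit(4, seed=11)
        r2 = m.fit(4, seed=11)
        np.testing.assert_array_equal(r1.params.pack(), r2.params.pack())

    def test_train_lm_facade(self, noisy_table):
        res = train_lm(noisy_table, 3, seed=5)
        assert -np.inf < res.r2 <= 1.0
        assert res.mae >= 0

    def test_rescaled_inputs_same_predictions(self, noisy_table):
        # standardization makes the fit invariant to affine input rescaling
        df = noisy_table.df.copy()
        df["etoh_pct"] = df["etoh_pct"] * 10 + 3
        df["time_min"] = df["time_min"] * 0.5 - 1
        scaled = ExperimentTable(df=df)
        r1 = MLPSurrogate(noisy_table).fit(5, seed=2)
        r2 = MLPSurrogate(scaled).fit(5, seed=2)
        x = noisy_table.x[:7]
        x_scaled = x.copy()
        x_scaled[:, 0] = x_scaled[:, 0] * 10 + 3
        x_scaled[:, 2] = x_scaled[:, 2] * 0.5 - 1
        np.testing.assert_allclose(
            r1.predict(x), r2.predict(x_scaled), rtol=1e-8, atol=1e-8
        )

    def test_small_table_rejected(self):
        t = ExperimentTable.from_arrays(np.ones((3, 3)) + np.eye(3), np.arange(3.0))
        with pytest.raises(ValueError, match="at least 4"):
            MLPSurrogate(t)

    def test_constant_output_rejected(self):
        rng = np.random.default_rng(0)
        t = ExperimentTable.from_arrays(rng.uniform(size=(6, 3)), np.full(6, 7.0))
        with pytest.raises(ValueError):
            MLPSurrogate(t)


class TestEvaluateFit:
    def test_metrics_on_held_out_table(self, noiseless_fit, noiseless_spec, bounds):
        from dephenolize import generate_design, simulate_experiments

        other = simulate_experiments(
            noiseless_spec, generate_design(bounds, 20, seed=99), seed=99
        )
        r2, mae = evaluate_fit(noiseless_fit, other)
        assert r2 > 0.9
        assert mae >= 0

    def test_shifted_predictions_mae(self, noiseless_table):
        # a predictor offset by +c from truth has MAE exactly c
        class Shifted:
            def __init__(self, base, c):
                self.base, self.c = base, c

            def predict(self, x):
                return np.asarray(self.base.predict(x)) + self.c

        base = MLPSurrogate(noiseless_table).fit_best(10, n_inits=10, seed=8)
        pred = Shifted(base, 5.0).predict(noiseless_table.x)
        mae = float(np.mean(np.abs(noiseless_table.y - pred)))
        assert mae == pytest.approx(5.0, abs=1e-6)


class TestTopologySelection:
    def test_linear_surface_plateaus_immediately(self):
        rng = np.random.default_rng(4)
        x = rng.uniform([70, 10, 5], [90, 60, 25], size=(33, 3))
        table = ExperimentTable.from_arrays(x, 2.0 * x[:, 0])
        scan = MLPSurrogate(table).select_topology(
            (1, 2, 3), n_repeats=2, n_inits=3, seed=0
        )
        assert scan.selected in (1, 2)
        assert scan.plateau

    def test_single_candidate_selected_unconditionally(self, noisy_table):
        scan = MLPSurrogate(noisy_table).select_topology(
            (10,), n_repeats=1, n_inits=2, seed=0
        )
        assert scan.selected == 10

    def test_sizes_must_increase(self, noisy_table):
        with pytest.raises(ValueError):
            MLPSurrogate(noisy_table).select_topology((3, 2), n_repeats=1, n_inits=1)
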