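"""Ground-truth surface, experiment designs, and simulation."""

import numpy as np
import pytest

from dephenolize import (
    ExtractionCondition,
    ProcessBounds,
    SurfaceSpec,
    evaluate_surface,
    generate_design,
    make_default_spec,
    simulate_experiments,
    true_main_effects,
    true_optimum,
)

TRUE_OPT = np.array([84.0, 60.0, 15.0])
TRUE_MAX = 1887.76


class TestDefaultSpec:
    def test_calibrated_scale(self, default_spec):
        # y0 solves y0 * 60/(60+25) = 1887.76
        assert default_spec.y0 == pytest.approx(1887.76 * 85 / 60, abs=1e-9)
        assert default_spec.y0 == pytest.approx(2674.33, abs=0.01)

    def test_peak_value_and_location(self, default_spec):
        assert evaluate_surface(
            default_spec, ExtractionCondition(84, 60, 15)
        ) == pytest.approx(TRUE_MAX, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SurfaceSpec(y0=-1, e_star=84, sigma_e=15, k_r=25, t_star=15,
                        sigma_t=20, noise_sd=40)
        with pytest.raises(ValueError):
            SurfaceSpec(y0=1, e_star=84, sigma_e=0, k_r=25, t_star=15,
                        sigma_t=20, noise_sd=40)
        with pytest.raises(ValueError):
            SurfaceSpec(y0=1, e_star=84, sigma_e=15, k_r=25, t_star=15,
                        sigma_t=20, noise_sd=-1)


class TestEvaluateSurface:
    def test_unimodal_in_etoh(self, default_spec):
        peak = evaluate_surface(default_spec, np.array([84.0, 60.0, 15.0]))
        off = evaluate_surface(default_spec, np.array([70.0, 60.0, 15.0]))
        assert off < peak

    def test_monotone_in_sl(self, default_spec):
        sl = np.linspace(1, 60, 50)
        x = np.column_stack([np.full(50, 84.0), sl, np.full(50, 15.0)])
        y = evaluate_surface(default_spec, x)
        assert np.all(np.diff(y) > 0)

    def test_vanishes_as_sl_to_zero(self, default_spec):
        tiny = evaluate_surface(default_spec, np.array([84.0, 1e-9, 15.0]))
        assert tiny == pytest.approx(0.0, abs=1e-4)

    def test_nonpositive_sl_rejected(self, default_spec):
        with pytest.raises(ValueError):
            evaluate_surface(default_spec, np.array([84.0, 0.0, 15.0]))


class TestGenerateDesign:
    def test_lhs_stratifies_each_axis(self, bounds):
        design = generate_design(bounds, 33, seed=1)
        x = np.array([c.as_array() for c in design])
        for ax, (lo, hi) in enumerate(bounds.ranges()):
            bins = np.floor((x[:, ax] - lo) / (hi - lo) * 33).astype(int)
            bins = np.clip(bins, 0, 32)
            assert len(set(bins)) == 33  # one point per stratum

    def test_grid_n8_gives_box_corners(self, bounds):
        design = generate_design(bounds, 8, scheme="grid", seed=0)
        pts = sorted(tuple(c.as_array()) for c in design)
        lo, hi = bounds.lower, bounds.upper
        expect = sorted(
            (e, s, t)
            for e in (lo[0], hi[0])
            for s in (lo[1], hi[1])
            for t in (lo[2], hi[2])
        )
        assert pts == expect

    def test_within_bounds(self, bounds):
        for scheme in ("latin_hypercube", "grid"):
            for c in generate_design(bounds, 20, scheme=scheme, seed=3):
                assert bounds.contains(c.as_array())

    def test_deterministic_per_seed(self, bounds):
        d1 = generate_design(bounds, 33, seed=5)
        d2 = generate_design(bounds, 33, seed=5)
        assert d1 == d2

    def test_too_small_rejected(self, bounds):
        with pytest.raises(ValueError):
            generate_design(bounds, 3, seed=0)


class TestSimulateExperiments:
    def test_noiseless_equals_surface(self, noiseless_spec, bounds):
        design = generate_design(bounds, 10, seed=2)
        table = simulate_experiments(noiseless_spec, design, seed=2)
        expect = evaluate_surface(noiseless_spec, table.x)
        np.testing.assert_allclose(table.y, expect, rtol=0, atol=0)

    def test_noise_mean_within_clt_bound(self, default_spec, bounds):
        design = generate_design(bounds, 33, seed=7)
        table = simulate_experiments(default_spec, design, seed=7)
        resid = table.y - evaluate_surface(default_spec, table.x)
        assert abs(resid.mean()) < 3 * default_spec.noise_sd / np.sqrt(33)

    def test_bit_identical_per_seed(self, default_spec, bounds):
        design = generate_design(bounds, 33, seed=7)
        t1 = simulate_experiments(default_spec, design, seed=7)
        t2 = simulate_experiments(default_spec, design, seed=7)
        assert t1.df.equals(t2.df)

    def test_different_seeds_differ(self, default_spec, bounds):
        design = generate_design(bounds, 33, seed=7)
        t1 = simulate_experiments(default_spec, design, seed=1)
        t2 = simulate_experiments(default_spec, design, seed=2)
        assert not np.array_equal(t1.y, t2.y)


class TestTrueOptimum:
    def test_default_location_and_value(self, default_spec, bounds):
        cond, val = true_optimum(default_spec, bounds)
        np.testing.assert_allclose(cond.as_array(), TRUE_OPT, atol=1e-4)
        assert val == pytest.approx(TRUE_MAX, abs=1e-6)

    def test_exterior_ridge_clips_to_bound(self, default_spec, bounds):
        shifted = SurfaceSpec(**{**default_spec.to_dict(), "t_star": 40.0})
        cond, _ = true_optimum(shifted, bounds)
        assert cond.time == pytest.approx(bounds.time_range[1], abs=1e-6)


class TestTrueMainEffects:
    def test_default_ordering_sl_dominates(self, default_spec, bounds):
        me = true_main_effects(default_spec, bounds, n_mc=20000, seed=0)
        assert me.order == ("sl", "etoh", "time")
        assert not me.degenerate

    def test_ordering_stable_across_seeds(self, default_spec, bounds):
        hits = sum(
            true_main_effects(default_spec, bounds, n_mc=20000, seed=s).order
            == ("sl", "etoh", "time")
            for s in range(10)
        )
        assert hits >= 9

    def test_shares_sum_at_most_100(self, default_spec, bounds):
        me = true_main_effects(default_spec, bounds, n_mc=50000, seed=1)
        assert sum(me.shares.values()) <= 100.0 + 2.0  # MC slack

    def test_matches_separable_quadrature_oracle(self, default_spec, bounds):
        # independent oracle: for y = y0*g_e(e)*g_s(s)*g_t(t) with uniform
        # inputs, Var(E[y|x_i]) = y0^2 * Var(g_i) * prod_{j!=i} E[g_j]^2
        from scipy.integrate import quad

        s = default_spec
        gs = [
            lambda e: np.exp(-((e - s.e_star) ** 2) / (2 * s.sigma_e**2)),
            lambda r: r / (r + s.k_r),
            lambda t: np.exp(-((t - s.t_star) ** 2) / (2 * s.sigma_t**2)),
        ]
        moments = []
        for g, (lo, hi) in zip(gs, bounds.ranges()):
            m1 = quad(g, lo, hi)[0] / (hi - lo)
            m2 = quad(lambda v: g(v) ** 2, lo, hi)[0] / (hi - lo)
            moments.append((m1, m2))
        total_var = s.y0**2 * (
            np.prod([m2 for _, m2 in moments]) - np.prod([m1 for m1, _ in moments]) ** 2
        )
        expected = {}
        for i, name in enumerate(("etoh", "sl", "time")):
            m1, m2 = moments[i]
            other = np.prod([moments[j][0] for j in range(3) if j != i]) ** 2
            expected[name] = 100 * s.y0**2 * (m2 - m1**2) * other / total_var
        me = true_main_effects(s, bounds, n_mc=100000, seed=3)
        for name in expected:
            assert me.shares[name] == pytest.approx(expected[name], abs=2.0)

    def test_single_active_input(self, bounds):
        lone = SurfaceSpec(y0=100, e_star=84, sigma_e=5, k_r=1e-9, t_star=15,
                           sigma_t=1e6, noise_sd=0)
        me = true_main_effects(lone, bounds, n_mc=20000, seed=0)
        assert me.shares["etoh"] == pytest.approx(100.0, abs=2.0)

    def test_constant_surface_flagged_degenerate(self, bounds):
        flat = SurfaceSpec(y0=100, e_star=84, sigma_e=1e9, k_r=1e-12, t_star=15,
                           sigma_t=1e9, noise_sd=0)
        me = true_main_effects(flat, bounds, n_mc=20000, seed=0)
        assert me.degenerate
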