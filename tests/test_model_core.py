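"""Core model: switching function, flow, kick, map, closed forms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import flowkick as fk
from flowkick.model import _flow_signed


class TestOmega:
    @pytest.mark.parametrize(
        "xi, a, expected",
        [(0.0, 0.08, 0.0), (0.08, 0.08, 0.5), (0.16, 0.08, 0.8), (1.0, 0.5, 0.8)],
    )
    def test_values(self, xi, a, expected):
        assert fk.omega(xi, a) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("xi, a", [(-0.1, 0.08), (0.1, 0.0), (0.1, -1.0)])
    def test_domain_errors(self, xi, a):
        with pytest.raises(ValueError):
            fk.omega(xi, a)

    @given(st.floats(0.0, 10.0), st.floats(1e-6, 10.0))
    def test_strictly_increasing_and_bounded(self, xi, d):
        lo, hi = fk.omega(xi, 0.08), fk.omega(xi + max(d, 1e-6), 0.08)
        assert 0.0 <= lo < hi < 1.0


class TestRHS:
    def test_underlying_equilibria_are_critical(self, params):
        # desert, grass-only, forest-only and forest-grass states of the ODE
        for state in [(0, 0), (1, 0), (0, 1), (1 - params.alpha, 1)]:
            assert np.allclose(fk.rhs(np.array(state, float), params), 0.0, atol=1e-15)

    def test_x_axis_invariant_with_forced_tree_growth(self, params):
        v = fk.rhs(np.array([0.0, 0.5]), params)
        assert v[0] == 0.0 and v[1] > 0.0


class TestFlow:
    def test_zero_duration_is_identity(self, params):
        s = np.array([0.3, 0.7])
        assert np.array_equal(fk.flow(s, 0.0, params), s)

    def test_negative_duration_rejected(self, params):
        with pytest.raises(ValueError):
            fk.flow(np.array([0.1, 0.1]), -1.0, params)

    def test_tree_component_is_logistic(self, params):
        for y0 in (0.05, 0.3, 0.9, 1.0):
            for t in (0.4, 1.7, 3.0):
                got = fk.flow(np.array([0.0, y0]), t, params)
                e = np.exp(params.delta * t)
                assert got[1] == pytest.approx(y0 * e / (1 + y0 * (e - 1)), abs=1e-12)
                assert got[0] == 0.0

    def test_grass_logistic_on_treeless_axis(self, params):
        for x0 in (0.1, 0.5, 1.2):
            for t in (0.5, 2.0):
                got = fk.flow(np.array([x0, 0.0]), t, params)
                e = np.exp(t)
                assert got[0] == pytest.approx(x0 * e / (1 + x0 * (e - 1)), abs=1e-12)

    def test_matches_adaptive_rk45(self, params):
        # quadrature route vs independent ODE integrator
        rng_states = [(0.8, 0.2), (0.05, 0.95), (1.1, 1.05), (0.4, 0.6)]
        for s0 in rng_states:
            for t in (0.7, 2.3, 4.0):
                a = fk.flow(np.array(s0), t, params)
                b = fk.flow_rk45(np.array(s0), t, params, rtol=1e-12, atol=1e-12)
                assert np.max(np.abs(a - b)) < 1e-9

    def test_backward_forward_roundtrip(self, params):
        s = np.array([0.4, 0.5])
        fwd = fk.flow(s, 1.3, params)
        back = _flow_signed(fwd, -1.3, params)
        assert np.max(np.abs(back - s)) < 1e-12


class TestKickAndMap:
    def test_zero_kick_is_identity(self, params):
        r = fk.DisturbanceRegime(0.0, 0.0, 1.0)
        s = np.array([0.5, 0.6])
        assert np.array_equal(fk.kick(s, r, params), s)

    def test_no_grass_means_no_tree_mortality(self, params):
        r = fk.DisturbanceRegime(0.4, 0.9, 1.0)
        s = np.array([0.0, 0.8])
        assert np.array_equal(fk.kick(s, r, params), s)

    def test_kick_formula(self, params):
        r = fk.DisturbanceRegime(0.25, 0.6, 2.0)
        got = fk.kick(np.array([1.0, 1.0]), r, params)
        assert got[0] == pytest.approx(0.75, abs=1e-15)
        assert got[1] == pytest.approx(1 - 0.6 * fk.omega(0.25, 0.08), abs=1e-15)

    @pytest.mark.parametrize("k1,k2,tau", [(0.1, 0.2, 0.5), (0.7, 0.9, 3.0)])
    def test_axis_states_are_always_fixed(self, k1, k2, tau, params):
        r = fk.DisturbanceRegime(k1, k2, tau)
        assert np.allclose(fk.flow_kick_map(np.array([0.0, 1.0]), r, params), [0, 1], atol=1e-14)
        assert np.allclose(fk.flow_kick_map(np.array([0.0, 0.0]), r, params), 0.0, atol=1e-14)

    def test_grassland_fixed_point_formula(self, params):
        r = fk.DisturbanceRegime(0.3, 0.5, 1.5)
        xg = fk.grass_only_x(r)
        out = fk.flow_kick_map(np.array([xg, 0.0]), r, params)
        assert out[0] == pytest.approx(xg, abs=1e-13) and out[1] == 0.0

    def test_grass_component_nonincreasing_in_k1(self, params):
        s = np.array([0.5, 0.4])
        vals = [
            fk.flow_kick_map(s, fk.DisturbanceRegime(k1, 0.3, 1.5), params)[0]
            for k1 in np.linspace(0.0, 0.9, 10)
        ]
        assert np.all(np.diff(vals) <= 1e-15)

    @given(
        st.floats(0.0, 1.5),
        st.floats(0.0, 1.5),
        st.floats(0.0, 0.95),
        st.floats(0.0, 0.95),
        st.floats(0.05, 4.0),
    )
    def test_first_quadrant_invariance(self, x, y, k1, k2, tau):
        r = fk.DisturbanceRegime(k1, k2, tau)
        out = fk.flow_kick_map(np.array([x, y]), r)
        assert out[0] >= 0.0 and out[1] >= 0.0


class TestClosedForms:
    def test_tree_closed_form_on_y_axis(self, regime_vi, params):
        ys = np.linspace(0.0, 1.2, 13)
        numeric = fk.flow_kick_map(np.stack([np.zeros(13), ys], axis=-1), regime_vi, params)
        analytic = fk.closed_form_V(np.zeros(13), ys, regime_vi, params)
        assert np.max(np.abs(analytic - numeric[:, 1])) < 1e-8

    def test_tree_closed_form_at_fixed_points(self, census_vi, regime_vi, params):
        # the grass substitution xi = k1 x/(1-k1) is exact wherever the grass
        # coordinate is fixed under the map: there V must return y itself
        for fp in census_vi:
            v = fk.closed_form_V(fp.x, fp.y, regime_vi, params)
            assert v == pytest.approx(fp.y, abs=1e-8)

    def test_tree_closed_form_partial_at_grassland(self, regime_vi, params):
        # dV/dy at (x_g, 0) has the explicit form e^{dt}(1 - k2 w(xi_g))
        xg = fk.grass_only_x(regime_vi)
        xi = regime_vi.k1 * xg / (1 - regime_vi.k1)
        expected = np.exp(params.delta * regime_vi.tau) * (
            1 - regime_vi.k2 * fk.omega(xi, params.a)
        )
        h = 1e-7
        fd = (
            fk.closed_form_V(xg, h, regime_vi, params)
            - fk.closed_form_V(xg, 0.0, regime_vi, params)
        ) / h
        assert fd == pytest.approx(expected, rel=1e-6)
        J = fk.map_jacobian(np.array([xg, 0.0]), regime_vi, params)
        assert J[1, 1] == pytest.approx(expected, abs=1e-6)

    def test_grass_closed_form_on_forest_line(self, regime_vi, params):
        xs = np.linspace(0.0, 0.15, 10)
        analytic = fk.closed_form_U_forest_line(xs, regime_vi, params)
        numeric = np.array(
            [
                fk.kick(fk.flow(np.array([x, 1.0]), regime_vi.tau, params), regime_vi, params)[0]
                for x in xs
            ]
        )
        assert np.max(np.abs(analytic - numeric)) < 1e-8

    def test_grass_closed_form_slope_at_forest(self, regime_vi, params):
        expected = (1 - regime_vi.k1) * np.exp((1 - params.alpha) * regime_vi.tau)
        h = 1e-8
        fd = fk.closed_form_U_forest_line(h, regime_vi, params) / h
        assert fd == pytest.approx(expected, rel=1e-6)

    def test_degenerate_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            fk.closed_form_U_forest_line(0.1, fk.DisturbanceRegime(0.2, 0.2, 1.0), fk.ModelParams(alpha=1.0))


class TestNondimensionalization:
    def test_equal_growth_rates_give_unit_delta(self):
        dim = fk.DimensionalParams(gamma_G=2.0, gamma_T=2.0, K_G=5.0, K_T=3.0, gamma_TG=0.1)
        _, delta, _ = fk.nondimensionalize(dim, tau_years=1.0)
        assert delta == 1.0

    def test_alpha_substitution(self):
        dim = fk.DimensionalParams(gamma_G=1.0, gamma_T=0.6, K_G=2.0, K_T=1.0, gamma_TG=0.8)
        alpha, delta, tau = fk.nondimensionalize(dim, tau_years=2.0)
        assert alpha == pytest.approx(0.8) and delta == pytest.approx(0.6)
        assert tau == pytest.approx(2.0)

    def test_roundtrip(self):
        dim = fk.DimensionalParams(gamma_G=1.7, gamma_T=0.9, K_G=4.0, K_T=2.5, gamma_TG=0.3)
        alpha, delta, tau = fk.nondimensionalize(dim, tau_years=1.4)
        dim2, tau_years = fk.dimensionalize(alpha, delta, tau, dim.gamma_G, dim.K_G, dim.K_T)
        assert dim2 == dim and tau_years == pytest.approx(1.4)


class TestTrajectoryAndLogisticLimit:
    def test_simulate_consistency(self, regime_vi, params):
        traj = fk.simulate(np.array([0.8, 0.2]), regime_vi, params, n_kicks=10)
        assert len(traj.records) == 10
        s = traj.start
        for n, pre, post in traj.records:
            assert np.allclose(pre, fk.flow(s, regime_vi.tau, params), atol=1e-13)
            assert np.allclose(post, fk.kick(pre, regime_vi, params), atol=1e-15)
            s = post
        df = traj.to_frame()
        assert list(df.columns) == ["n", "t", "x_pre", "y_pre", "x_post", "y_post"]

    def test_decoupled_grass_matches_scalar_logistic_recursion(self):
        # with alpha = 0 the grass dynamics ignore the trees entirely and the
        # grass sequence obeys the 1D logistic flow-kick recursion exactly
        params = fk.ModelParams(alpha=0.0)
        r = fk.DisturbanceRegime(0.3, 0.5, 1.0)
        traj = fk.simulate(np.array([0.9, 0.4]), r, params, n_kicks=15)
        x = 0.9
        e = np.exp(r.tau)
        for _, pre, post in traj.records:
            x_pre = x * e / (1 + x * (e - 1))
            assert pre[0] == pytest.approx(x_pre, abs=1e-12)
            x = (1 - r.k1) * x_pre
            assert post[0] == pytest.approx(x, abs=1e-12)
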