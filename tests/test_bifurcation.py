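"""Analytic transcritical loci, continuation, folds, and region taxonomy."""

import numpy as np
import pytest

import flowkick as fk
from flowkick.bifurcation import _k2_required


class TestAnalyticCurves:
    def test_grass_existence_values(self):
        assert fk.grass_existence_k1(1e-12) == pytest.approx(0.0, abs=1e-11)
        assert fk.grass_existence_k1(2.0) == pytest.approx(0.864664716763387, abs=1e-12)

    def test_grassland_point_vanishes_on_existence_curve(self):
        tau = 1.3
        k1 = float(fk.grass_existence_k1(tau))
        assert fk.grass_only_x(fk.DisturbanceRegime(k1, 0.1, tau)) == pytest.approx(0.0, abs=1e-12)

    def test_forest_transcritical_values(self, params):
        assert fk.forest_transcritical_k1(2.0, params) == pytest.approx(
            1 - np.exp(-0.4), abs=1e-12
        )
        # vanishes as the inhibition approaches neutrality
        assert fk.forest_transcritical_k1(3.0, fk.ModelParams(alpha=0.999999)) < 1e-5
        with pytest.raises(ValueError):
            fk.forest_transcritical_k1(1.0, fk.ModelParams(alpha=1.2))

    def test_grassland_transcritical_preconditions(self, params):
        with pytest.raises(ValueError):
            fk.grassland_transcritical_k2(0.95, 1.0, params)  # beyond existence
        # tiny k1 burns almost no grass: required k2 exceeds 1 -> none
        assert fk.grassland_transcritical_k2(1e-4, 1.0, params) is None

    @pytest.mark.parametrize("k1,tau", [(0.2, 0.8), (0.3, 0.6), (0.15, 0.4)])
    def test_unit_eigenvalue_on_grassland_locus(self, k1, tau, params):
        k2 = fk.grassland_transcritical_k2(k1, tau, params)
        assert k2 is not None
        r = fk.DisturbanceRegime(k1, k2, tau)
        xg = fk.grass_only_x(r)
        J = fk.map_jacobian(np.array([xg, 0.0]), r, params)
        eigs = np.linalg.eigvals(J)
        assert np.min(np.abs(eigs - 1.0)) <= 1e-6

    @pytest.mark.parametrize("tau", [0.7, 1.5, 3.0])
    def test_unit_eigenvalue_on_forest_locus(self, tau, params):
        k1 = float(fk.forest_transcritical_k1(tau, params))
        r = fk.DisturbanceRegime(k1, 0.5, tau)
        J = fk.map_jacobian(np.array([0.0, 1.0]), r, params)
        eigs = np.linalg.eigvals(J)
        assert np.min(np.abs(eigs - 1.0)) <= 1e-6

    def test_eigenvalue_one_implies_locus(self, params):
        # converse direction: scan k2 for a unit grassland eigenvalue and
        # compare with the analytic expression
        k1, tau = 0.25, 0.9
        r0 = fk.DisturbanceRegime(k1, 0.0, tau)
        xg = fk.grass_only_x(r0)
        from scipy.optimize import brentq

        def lam(k2):
            J = fk.map_jacobian(np.array([xg, 0.0]), fk.DisturbanceRegime(k1, k2, tau), params)
            return np.real(np.linalg.eigvals(J)).max() - 1.0

        k2_star = brentq(lam, 0.01, 0.99, xtol=1e-12)
        assert k2_star == pytest.approx(fk.grassland_transcritical_k2(k1, tau, params), abs=1e-8)


class TestCriticalK2:
    def test_threshold_value_and_determinism(self, params):
        ck = fk.critical_k2(params)
        assert round(ck.k2, 3) == 0.349
        assert ck.restart_spread <= 1e-4
        assert fk.critical_k2(params).k2 == ck.k2

    def test_no_locus_below_threshold(self, params):
        # below the minimum, the required k2 exceeds the level everywhere
        ck = fk.critical_k2(params)
        level = ck.k2 - 1e-3
        fracs = np.linspace(0.02, 0.98, 40)
        taus = np.linspace(0.05, 6.0, 60)
        req = np.array([[_k2_required(f, t, params) for t in taus] for f in fracs])
        assert req.min() > level


class TestContinuation:
    def test_forest_branch_is_flat(self, params):
        r = fk.DisturbanceRegime(0.3, 0.4, 1.2)
        seed = fk.newton_fixed_point(np.array([0.0, 1.0]), r, params)
        br = fk.continue_branch(seed, r, params, free_param="k2", param_range=(0.05, 0.9))
        states = br.states_array()
        assert states.shape[0] > 10
        assert np.max(np.abs(states - np.array([0.0, 1.0]))) < 1e-8

    def test_fold_of_high_grass_branch(self, params):
        fold = fk.fold_in_tau(0.2, 0.6, params)
        assert fold.param == pytest.approx(1.49, abs=0.01)
        assert fold.certified
        assert abs(fold.eigenvalue - 1.0) < 1e-5
        assert abs(fold.normal_form) > 1e-3

    def test_stability_swaps_across_forest_transcritical(self, params):
        # the coexistence branch in k1 crosses (0, 1) at the analytic locus
        # and exchanges stability with the forest state there
        tau, k2 = 2.0, 0.2
        k1_star = float(fk.forest_transcritical_k1(tau, params))
        r = fk.DisturbanceRegime(0.15, k2, tau)
        census = fk.enumerate_fixed_points(r, params)
        seed = [fp for fp in census if fp.kind == "coexistence"][0]
        br = fk.continue_branch(seed, r, params, free_param="k1", param_range=(0.01, 0.9))
        ps = br.params_array()
        xs = br.states_array()[:, 0]
        # where the branch meets x = 0 is the analytic transcritical level
        cross = np.flatnonzero(xs[:-1] * xs[1:] < 0)
        assert cross.size >= 1
        i = cross[0]
        p_cross = ps[i] + (ps[i + 1] - ps[i]) * xs[i] / (xs[i] - xs[i + 1])
        assert p_cross == pytest.approx(k1_star, abs=2e-3)
        stab = [p.stability for p in br.points]
        assert len(set(stab)) > 1  # stability changes along the branch


class TestRegions:
    def test_savanna_savanna_bistability(self, regime_vi, params):
        rl = fk.classify_region(regime_vi, params)
        assert rl.label == "VI"
        assert rl.stable_set == ("coexistence", "coexistence")

    @pytest.mark.parametrize("k1,tau", [(0.1, 0.5), (0.3, 1.5), (0.6, 2.5), (0.9, 3.5)])
    def test_weak_tree_mortality_is_never_bistable(self, k1, tau, params):
        rl = fk.classify_region(fk.DisturbanceRegime(k1, 0.2, tau), params)
        assert len(rl.stable_set) == 1
        assert rl.label in ("I", "II", "III")

    def test_harsh_regime_is_region_one(self, params):
        tau = 1.0
        k1 = 0.95
        assert k1 > 1 - np.exp(-tau)
        assert k1 > float(fk.forest_transcritical_k1(tau, params))
        rl = fk.classify_region(fk.DisturbanceRegime(k1, 0.5, tau), params)
        assert rl.label == "I" and rl.stable_set == ("forest_only",)

    def test_stability_diagram_weak_k2_has_single_stable_state(self, params):
        grid = fk.stability_diagram(
            0.2,
            np.linspace(0.1, 0.9, 6),
            np.linspace(0.3, 3.5, 6),
            params,
            grid_n=12,
            with_limit_points=False,
        )
        assert all(len(s) == 1 for s in grid.stable_sets.ravel())
        assert not grid.failures

    def test_stability_diagram_strong_k2_shows_three_bistable_regions(self, params):
        grid = fk.stability_diagram(
            0.6,
            np.linspace(0.1, 0.4, 7),
            np.linspace(0.9, 2.0, 6),
            params,
            grid_n=12,
            with_limit_points=False,
        )
        labels = set(grid.labels.ravel())
        assert {"V", "VI", "VII"} <= labels

    def test_limit_point_curve_at_strong_k2(self, params):
        curve = fk.limit_point_curve(0.6, params, tau_values=[2.0])
        assert curve.points.shape[0] >= 2  # folds on both sides of the branch
        assert np.all((curve.points[:, 0] > 0) & (curve.points[:, 0] < 1))
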