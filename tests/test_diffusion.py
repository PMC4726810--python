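import math

import numpy as np
import pytest

from kinwalk.params import ModelParams, ParameterError
from kinwalk import diffusion as dfn
from kinwalk import neck


class TestAssembly:
    def test_default_problem_has_eight_absorbers(self, params):
        prob = dfn.assemble_problem(params)
        pts = prob.absorbing_points()
        assert set(pts) == set(range(1, 9))
        # tilted diagonals sit closer to the origin than the raw sites
        assert math.hypot(*pts[6]) < math.hypot(8.0, 6.4)
        assert math.hypot(*pts[7]) == pytest.approx(8.0)

    def test_tilt_off_uses_geometric_diagonals(self, params):
        prob = dfn.assemble_problem(params.with_variants(allow_tilted_binding=False))
        pts = prob.absorbing_points()
        assert pts[6] == pytest.approx((8.0, 6.4))

    def test_occupied_site_becomes_reflector(self, params):
        prob = dfn.assemble_problem(params, blocked={7: "occupied"})
        assert 7 not in prob.absorbing_points()
        circles = prob.reflector_circles()
        assert len(circles) == 1
        assert circles[0][1:] == (8.0, 0.0, 5.0)

    def test_excluded_site_has_no_reflector(self, params):
        prob = dfn.assemble_problem(params, blocked={7: "excluded"})
        assert 7 not in prob.absorbing_points()
        assert prob.reflector_circles() == []

    def test_invalid_blocked_state_rejected(self, params):
        with pytest.raises(ParameterError):
            dfn.assemble_problem(params, blocked={7: "bogus"})
        with pytest.raises(ParameterError):
            dfn.assemble_problem(params, blocked={12: "occupied"})


class TestSplitting:
    def test_probability_conservation(self, default_solution):
        assert sum(default_solution.p_b.values()) == pytest.approx(1.0, abs=1e-6)

    def test_left_right_mirror_symmetry(self, default_solution):
        pb = default_solution.p_b
        assert pb[4] == pytest.approx(pb[5], rel=1e-6)
        assert pb[6] == pytest.approx(pb[8], rel=1e-6)
        assert pb[1] == pytest.approx(pb[3], rel=1e-6)

    def test_forward_dominates(self, default_solution):
        bp = dfn.binding_probabilities(default_solution)
        assert bp.p_b[7] > 0.8
        assert bp.p_fw > bp.p_sd > bp.p_bw

    def test_grid_convergence(self, default_solution, default_solution_fine):
        # halving the production grid step changes each main P_b by < 2%
        for site in (7, 6, 4):
            a = default_solution.p_b[site]
            b = default_solution_fine.p_b[site]
            assert abs(a - b) / b < 0.02

    def test_direction_aggregates(self, default_solution):
        bp = dfn.binding_probabilities(default_solution)
        assert bp.p_fw == pytest.approx(sum(bp.p_b[i] for i in (6, 7, 8)))
        assert bp.p_sd == pytest.approx(bp.p_b[4] + bp.p_b[5])
        assert bp.p_bw == pytest.approx(sum(bp.p_b[i] for i in (1, 2, 3)))


class TestTransient:
    def test_mass_conservation_and_early_stop(self, params):
        prob = dfn.assemble_problem(params)
        sol = dfn.solve_fokker_planck(prob, t_final=0.05, grid_step=0.25,
                                      time_step=2e-5, stop_mass=1e-6)
        total = sol.residual_mass + np.array(
            [sum(f[:k + 1].sum() * 2e-5 for f in sol.absorbed_flux.values())
             for k in range(len(sol.times))])
        assert np.abs(total - 1.0).max() < 1e-4
        assert sol.residual_mass[-1] < 1e-6 or sol.times[-1] >= 0.05 - 1e-9

    def test_transient_approaches_stationary_split(self, params,
                                                   default_solution_coarse):
        prob = dfn.assemble_problem(params)
        sol = dfn.solve_fokker_planck(prob, t_final=0.08, grid_step=0.25,
                                      time_step=2e-5, stop_mass=1e-6)
        bp_t = dfn.binding_probabilities(sol)
        bp_s = dfn.binding_probabilities(default_solution_coarse)
        assert bp_t.p_b[7] == pytest.approx(bp_s.p_b[7], abs=2e-3)

    def test_free_diffusion_matches_heat_kernel(self, params, monkeypatch):
        # with the neck force switched off the density must follow the
        # closed-form Gaussian kernel until it feels the walls
        def no_force(pts, cargo, par):
            n = len(np.atleast_2d(pts))
            return np.zeros(n), np.zeros(n), np.zeros(n, dtype=int)
        monkeypatch.setattr(neck, "head_force_field", no_force)
        monkeypatch.setattr(dfn, "_FACE_CACHE", {})
        # drop the absorbers so mass only spreads
        prob = dfn.assemble_problem(
            params, blocked={i: "excluded" for i in range(1, 9)},
            init_position=(0.0, 0.0))
        t_end = 5e-5  # ms; sqrt(2Dt) ~ 2.8 nm stays clear of the walls
        sol = dfn.solve_fokker_planck(prob, t_final=t_end, grid_step=0.25,
                                      time_step=5e-7,
                                      snapshot_times=(t_end,))
        D = params.diffusion.D
        s2 = params.diffusion.init_sigma ** 2 + 2 * D * t_end
        g = dfn._Grid(prob, 0.25)
        ref = np.exp(-(g.X ** 2 + g.Y ** 2) / (2 * s2)) / (2 * math.pi * s2)
        got = sol.snapshots[0]
        l2 = np.sqrt(((got - ref) ** 2).sum() / (ref ** 2).sum())
        assert l2 < 0.01


class TestObstacleInterference:
    def test_no_obstacle_means_no_interference(self, default_solution):
        assert default_solution.a_int == {}
        with pytest.raises(KeyError):
            dfn.interference_integral(default_solution, 7)

    def test_forward_obstacle_value_and_access(self, params):
        sol = dfn.solve_splitting(
            dfn.assemble_problem(params, blocked={7: "occupied"}), 0.25)
        a = dfn.interference_integral(sol, 7)
        assert 0.3 < a < 1.0
        # the brief stepping episode contributes far less contact than the
        # ATP-waiting exposure
        assert sol.a_int_episode[7] < 0.1 * a

    def test_blocked_initial_position_is_relocated(self, params):
        sol = dfn.solve_splitting(
            dfn.assemble_problem(params, blocked={7: "occupied"}), 0.25)
        cx, cy = sol.init_center
        assert math.hypot(cx - 8.0, cy) > 5.0   # outside the obstacle
        assert sum(sol.p_b.values()) == pytest.approx(1.0, abs=1e-6)

    def test_waiting_exposure_rear_equals_forward(self, params):
        fwd = dfn.waiting_interference(dfn.assemble_problem(
            params, blocked={7: "occupied"}))
        # footprint of a rear obstacle: occupied site 2, excluded 1 and 3
        rear = dfn.waiting_interference(dfn.assemble_problem(
            params, blocked={2: "occupied", 1: "excluded", 3: "excluded"}))
        assert fwd[7] == pytest.approx(rear[2], rel=1e-6)


class TestBrownianOracle:
    def test_requires_particles(self, params):
        with pytest.raises(ParameterError):
            dfn.brownian_oracle(dfn.assemble_problem(params), n_particles=0)

    def test_deterministic_given_seed(self, params):
        prob = dfn.assemble_problem(params)
        a, _ = dfn.brownian_oracle(prob, n_particles=300, time_step=2e-6,
                                   seed=7, field_step=0.5, max_steps=20000)
        b, _ = dfn.brownian_oracle(prob, n_particles=300, time_step=2e-6,
                                   seed=7, field_step=0.5, max_steps=20000)
        assert a.p_b == b.p_b

    def test_left_right_counts_balance(self, params):
        prob = dfn.assemble_problem(params)
        bp, se = dfn.brownian_oracle(prob, n_particles=4000, time_step=1e-6,
                                     seed=3, field_step=0.25)
        sigma = math.sqrt(se[4] ** 2 + se[5] ** 2)
        assert abs(bp.p_b[4] - bp.p_b[5]) < 3 * max(sigma, 1e-3)
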