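import numpy as np
import pytest

from kinwalk.params import KineticsParams
from kinwalk.lattice import build_lattice
from kinwalk.obstacles import ObstacleSet, UnbindingModel
from kinwalk import stepper as st


class TestStepTable:
    def test_empty_mask_matches_free_solution(self, step_table,
                                              default_solution_coarse):
        e = step_table.ensure({})
        tot = sum(default_solution_coarse.p_b.values())
        for site in range(1, 9):
            assert e.p_b[site] == pytest.approx(
                default_solution_coarse.p_b[site] / tot, rel=1e-9)

    def test_mirror_masks_share_one_solve(self, step_table):
        a = step_table.ensure({6: "occupied", 7: "excluded"})
        b = step_table.ensure({8: "occupied", 7: "excluded"})
        assert a.p_b[8] == pytest.approx(b.p_b[6], rel=1e-12)
        assert a.a_int[6] == pytest.approx(b.a_int[8], rel=1e-12)

    def test_blocked_sites_carry_no_probability(self, step_table):
        e = step_table.ensure({7: "occupied", 6: "excluded", 8: "excluded"})
        assert set(e.p_b) <= {1, 2, 3, 4, 5}
        assert sum(e.p_b.values()) == pytest.approx(1.0, abs=1e-9)

    def test_fallback_renormalises_empty_entry(self, step_table):
        mask = {7: "excluded", 4: "excluded", 5: "excluded", 2: "excluded"}
        e = step_table.lookup(mask)
        assert not e.exact
        assert set(e.p_b) == {1, 3, 6, 8}
        assert sum(e.p_b.values()) == pytest.approx(1.0)

    def test_strict_lookup_raises_on_miss(self, step_table):
        with pytest.raises(KeyError):
            step_table.lookup({1: "excluded", 5: "excluded"}, strict=True)


class TestWalks:
    def test_fixed_seed_reproducible(self, params, kinetics, step_table):
        lat = build_lattice(13, 26.5, 500, True)
        a = st.simulate_walk(lat, None, step_table, kinetics, seed=9)
        b = st.simulate_walk(lat, None, step_table, kinetics, seed=9)
        assert a.sites == b.sites and a.times == b.times

    def test_no_unbinding_runs_to_max_steps(self, params, step_table):
        kin = KineticsParams(p_ub0=0.0, max_steps=50)
        lat = build_lattice(13, 26.5, 5000, True)
        traj = st.simulate_walk(lat, None, step_table, kin, seed=4,
                                start=(5, 2500),
                                unbinding=UnbindingModel(p_ub0=0.0))
        assert traj.termination == "max_steps"
        assert traj.n_steps == 50

    def test_consecutive_sites_are_neighbours(self, params, kinetics,
                                              step_table):
        lat = build_lattice(13, 26.5, 800, True)
        traj = st.simulate_walk(lat, None, step_table, kinetics, seed=21)
        for (p1, a1), (p2, a2) in zip(traj.sites, traj.sites[1:]):
            dpf = (p2 - p1) % 13
            assert abs(a2 - a1) <= 1
            assert dpf in (0, 1, 12)

    def test_no_obstacle_estimators_recover_analytic_values(
            self, params, kinetics, step_table):
        # V = 8 nm (P_fw - P_bw) / dwell ; RL = 8 nm (P_fw - P_bw) / P_ub0
        trajs, _ = st.run_ensemble(params, kinetics, rho=0.0, n_walkers=150,
                                   seed=33, table=step_table)
        es = st.ensemble_statistics(trajs, kinetics)
        e = step_table.ensure({})
        drift = sum(e.p_b[i] for i in (6, 7, 8)) - sum(e.p_b[i] for i in (1, 2, 3))
        v_pred = 8.0 * drift / kinetics.mean_dwell * 1e3
        rl_pred = 8.0 * drift / kinetics.p_ub0
        assert abs(es.mean_velocity - v_pred) < 2 * es.se_velocity + 1.0
        assert abs(es.mean_run_length - rl_pred) < 2 * es.se_run_length + 1.0

    def test_zero_resolution_filters_are_identity(self, params, kinetics,
                                                  step_table):
        lat = build_lattice(13, 26.5, 800, True)
        traj = st.simulate_walk(lat, None, step_table, kinetics, seed=5)
        raw = traj.velocity(0.0, 0.0)
        assert raw == pytest.approx(
            traj.run_length / traj.duration * 1e3, rel=1e-9)

    def test_run_length_ratio_decreases_with_density(self, params, step_table):
        kin = KineticsParams(max_steps=4000)
        means = []
        for rho in (0.0, 0.02, 0.05):
            trajs, _ = st.run_ensemble(params, kin, rho=rho, n_walkers=60,
                                       seed=77, table=step_table, n_axial=1200)
            means.append(np.mean([t.run_length for t in trajs]))
        assert means[0] > means[1] > means[2]

    def test_occupancy_exclusion_never_violated(self, params, kinetics,
                                                step_table):
        from kinwalk.obstacles import deposit_at_density
        lat = build_lattice(13, 26.5, 600, True)
        obs = deposit_at_density(lat, 3, 0.05, seed=3)
        traj = st.simulate_walk(lat, obs, step_table, kinetics, seed=13)
        for pf, ax in traj.sites:
            assert not obs.anchor_grid[pf, ax % 600]
            assert not obs.excluded_grid[pf, ax % 600]


class TestTraffic:
    def test_zero_density_matches_free_walk_scale(self, params, kinetics,
                                                  step_table):
        v, rl, traj = st.simulate_traffic("K+M0", 0.0, params, kinetics,
                                          seed=2, table=step_table)
        assert traj.termination == "unbound"
        assert 500 < v < 1000

    def test_unknown_scenario_rejected(self, params, kinetics, step_table):
        with pytest.raises(Exception):
            st.simulate_traffic("K+X", 0.1, params, kinetics, 0, step_table)

    def test_oversaturated_density_rejected(self, params, kinetics,
                                            step_table):
        with pytest.raises(Exception):
            st.simulate_traffic("K+M0", 0.6, params, kinetics, 0, step_table,
                                n_axial=100)
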