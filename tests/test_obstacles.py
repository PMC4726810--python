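import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinwalk.params import ParameterError
from kinwalk.lattice import build_lattice
from kinwalk import obstacles as ob


@pytest.fixture
def lattice():
    return build_lattice(13, 26.5, 120, True)


class TestFootprints:
    def test_single_site(self, lattice):
        assert ob.footprint_sites((5, 10), 1, lattice) == {(5, 10)}

    def test_lateral_triple(self, lattice):
        got = ob.footprint_sites((5, 10), 3, lattice)
        assert got == {(5, 10), (4, 10), (6, 10)}

    def test_axial_triple_orientation(self, lattice):
        got = ob.footprint_sites((5, 10), 3, lattice, orientation="axial")
        assert got == {(5, 10), (5, 9), (5, 11)}

    def test_nine_site_block(self, lattice):
        got = ob.footprint_sites((5, 10), 9, lattice)
        assert len(got) == 9
        assert {(4, 9), (6, 11), (5, 10)} <= got

    def test_axial_clipping_at_edge(self, lattice):
        got = ob.footprint_sites((5, 0), 3, lattice, orientation="axial")
        assert got == {(5, 0), (5, 1)}

    def test_lateral_wrap_around_cylinder(self, lattice):
        got = ob.footprint_sites((0, 10), 3, lattice)
        assert (12, 10) in got

    def test_invalid_class(self, lattice):
        with pytest.raises(ParameterError):
            ob.footprint_sites((5, 10), 4, lattice)


class TestUnbinding:
    model = ob.UnbindingModel(p_ub0=0.008, alpha_obs=0.044)

    def test_no_interference_is_baseline(self):
        assert ob.unbinding_probability(self.model, 0.0) == 0.008

    def test_linear_in_interference(self):
        assert ob.unbinding_probability(self.model, 0.58) == pytest.approx(
            0.008 + 0.044 * 0.58)

    def test_capped_at_one(self):
        assert ob.unbinding_probability(self.model, 1e6) == 1.0

    def test_negative_interference_rejected(self):
        with pytest.raises(ParameterError):
            ob.unbinding_probability(self.model, -0.1)


class TestDeposition:
    def test_single_site_saturates_fully(self):
        lat = build_lattice(13, 26.5, 40, True)
        _, rho = ob.deposit_to_saturation(lat, 1, seed=0)
        assert rho == pytest.approx(1.0)

    def test_same_seed_same_placements(self, lattice):
        a = ob.deposit_at_density(lattice, 3, 0.03, seed=42)
        b = ob.deposit_at_density(lattice, 3, 0.03, seed=42)
        assert a.anchors == b.anchors

    def test_target_density_hit_exactly(self, lattice):
        obs = ob.deposit_at_density(lattice, 3, 0.0346, seed=1)
        assert len(obs.anchors) == round(0.0346 * lattice.n_sites)

    def test_zero_density_is_empty(self, lattice):
        obs = ob.deposit_at_density(lattice, 3, 0.0, seed=1)
        assert obs.anchors == []

    def test_unreachable_density_raises(self):
        lat = build_lattice(13, 26.5, 30, True)
        with pytest.raises(ParameterError):
            ob.deposit_at_density(lat, 9, 0.5, seed=0)

    def test_saturation_decreases_with_footprint(self):
        rhos = {}
        for m in (3, 5, 9):
            vals = [ob.deposit_to_saturation(
                build_lattice(13, 26.5, 200, True), m, seed=s)[1]
                for s in range(5)]
            rhos[m] = np.mean(vals)
        assert rhos[3] > rhos[5] > rhos[9]

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=10, derandomize=True, deadline=None)
    def test_anchors_never_inside_other_footprints(self, seed):
        lat = build_lattice(13, 26.5, 60, True)
        obs, _ = ob.deposit_to_saturation(lat, 3, seed=seed)
        anchors = set(obs.anchors)
        for a in obs.anchors:
            others = ob.footprint_sites(a, 3, lat) - {a}
            # swept sites may be shared, but never coincide with an anchor
            assert not (others & anchors)


class TestLocalConfig:
    def test_empty_field_all_clear(self, lattice):
        obs = ob.ObstacleSet(lattice=lattice, m_obs=3, r_obs=5.0)
        assert ob.local_obstacle_config(obs, (5, 50)) == {}

    def test_anchor_ahead_blocks_front_row(self, lattice):
        obs = ob.ObstacleSet(lattice=lattice, m_obs=3, r_obs=5.0)
        obs.place((5, 51))
        got = ob.local_obstacle_config(obs, (5, 50))
        assert got == {7: "occupied", 6: "excluded", 8: "excluded"}

    def test_blocked_state_lookup(self, lattice):
        obs = ob.ObstacleSet(lattice=lattice, m_obs=3, r_obs=5.0)
        obs.place((5, 51))
        assert obs.blocked_state(5, 51) == "occupied"
        assert obs.blocked_state(4, 51) == "excluded"
        assert obs.blocked_state(5, 50) is None
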