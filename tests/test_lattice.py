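import json
import math

import numpy as np
import pytest

from kinwalk.params import HeadGeometry, ParameterError
from kinwalk import lattice as lat


@pytest.fixture
def helical():
    return lat.build_lattice(13, 26.5, 100, helical=True)


@pytest.fixture
def square():
    return lat.build_lattice(13, 26.5, 100, helical=False)


def test_lateral_spacing_matches_circumference(helical):
    # 13 protofilaments on a 26.5 nm microtubule give d_side ~ 6.4 nm
    assert helical.lateral_spacing == pytest.approx(6.40, abs=0.005)
    assert helical.lateral_spacing * 13 == pytest.approx(math.pi * 26.5, rel=1e-12)


@pytest.mark.parametrize("diameter,stagger,expected", [
    (26.5, 8.0, 5.49),   # the 13-protofilament mismatch angle
    (26.5, 0.0, 0.0),
    (13.25, 8.0, 10.88),
])
def test_mismatch_angle(diameter, stagger, expected):
    assert lat.lattice_mismatch_angle(diameter, stagger) == pytest.approx(
        expected, abs=0.005)


def test_mismatch_angle_rejects_bad_diameter():
    with pytest.raises(ParameterError):
        lat.lattice_mismatch_angle(-1.0, 8.0)


def test_helical_diagonal_distances(helical):
    nb = lat.neighbor_site_positions(helical, helical.site_id(6, 50))
    far = math.hypot(*nb[6])
    near = math.hypot(*nb[8])
    assert far == pytest.approx(10.73, abs=0.01)
    assert near == pytest.approx(9.77, abs=0.01)
    # the helical distances straddle the square-lattice value
    square_diag = math.hypot(8.0, helical.lateral_spacing)
    assert near < square_diag < far


def test_square_lattice_diagonals_equal_and_mirror(square):
    nb = lat.neighbor_site_positions(square, square.site_id(6, 50))
    d6 = math.hypot(*nb[6])
    d8 = math.hypot(*nb[8])
    assert d6 == pytest.approx(d8, rel=1e-12)
    assert d6 == pytest.approx(10.25, abs=0.01)
    # y -> -y maps (4)<->(5), (6)<->(8), (1)<->(3); (7) and (2) map to themselves
    for a, b in ((4, 5), (6, 8), (1, 3), (7, 7), (2, 2)):
        ax, ay = nb[a]
        bx, by = nb[b]
        assert (ax, ay) == pytest.approx((bx, -by), abs=1e-12)
    # fore-aft symmetry of the square lattice
    assert nb[7][0] == pytest.approx(-nb[2][0], rel=1e-12)


def test_edge_anchor_raises(square):
    with pytest.raises(lat.BoundaryError):
        lat.neighbor_site_positions(square, square.site_id(0, 0))


class TestTiltedBinding:
    geom = HeadGeometry()

    def test_47_degrees_shortens_by_about_15_percent(self):
        _, frac = lat.tilted_binding_offset(self.geom, 47.0, (8.0, -6.4))
        # the printed AA-324 offsets (0.9, 1.8 nm) reproduce the ~14.7%
        # reduction of the head-to-site distance
        assert -100 * frac == pytest.approx(14.7, abs=0.15)

    def test_zero_angle_is_identity(self):
        p, frac = lat.tilted_binding_offset(self.geom, 0.0, (8.0, 6.4))
        assert frac == 0.0

    def test_20_degrees_matches_explicit_rotation(self):
        # brute-force planar geometry for the forward-left diagonal
        s = np.array([8.0, 6.4])
        v0 = np.array([-0.9, 1.8])
        th = math.radians(20.0)
        R = np.array([[math.cos(th), -math.sin(th)],
                      [math.sin(th), math.cos(th)]])
        d0 = np.linalg.norm(s + v0)
        d = np.linalg.norm(s + R @ v0)
        _, frac = lat.tilted_binding_offset(self.geom, 20.0, (8.0, 6.4))
        assert frac == pytest.approx((d - d0) / d0, rel=1e-12)

    def test_monotone_in_angle(self):
        fracs = [lat.tilted_binding_offset(self.geom, th, (8.0, -6.4))[1]
                 for th in np.linspace(0.0, 60.0, 121)]
        assert all(b <= a + 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_rejects_non_diagonal_sites(self):
        with pytest.raises(ParameterError):
            lat.tilted_binding_offset(self.geom, 47.0, (8.0, 0.0))

    def test_mirror_symmetry_of_absorbing_points(self):
        from kinwalk.params import LatticeParams
        pos = lat.absorbing_positions(LatticeParams(), self.geom, tilted=True)
        for a, b in ((6, 8), (1, 3), (4, 5)):
            assert pos[a][0] == pytest.approx(pos[b][0], rel=1e-12)
            assert pos[a][1] == pytest.approx(-pos[b][1], rel=1e-12)
        # tilted diagonals sit closer to the fixed head than the sites
        assert math.hypot(*pos[6]) < math.hypot(8.0, 6.4)


def test_extended_positions_cover_24_sites():
    pos = lat.extended_positions_local()
    assert set(pos) == set(range(1, 25))
    outer = [pos[i] for i in range(9, 25)]
    assert all(max(abs(x) / 8.0, abs(y) / 6.4) == pytest.approx(2.0)
               for x, y in outer)


def test_lattice_json_roundtrip(helical):
    helical.occupancy[3, 10] = 1
    helical.occupancy[3, 11] = 3
    clone = lat.MTLattice.from_json(helical.to_json())
    assert np.array_equal(clone.occupancy, helical.occupancy)
    assert clone.lateral_spacing == helical.lateral_spacing
    table = clone.site_table()
    assert set(table.columns) == {"site_id", "protofilament", "axial_index",
                                  "x_nm", "y_nm", "state"}
    assert len(table) == clone.n_sites
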