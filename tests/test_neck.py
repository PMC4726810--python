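import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinwalk.params import ModelParams, WLCParams, ParameterError
from kinwalk import neck

WLC = WLCParams()


class TestWLCForce:
    def test_zero_extension_is_zero_force(self):
        assert neck.wlc_force(0.0, 5.6, WLC) == 0.0

    def test_half_extension_value(self):
        # (kBT/lp) * [1/4*(1-0.5)^-2 + 0.5 - 1/4] = (4.141/0.6) * 1.25
        f = neck.wlc_force(2.8, 5.6, WLC)
        assert f == pytest.approx(4.141 / 0.6 * 1.25, rel=1e-12)

    def test_divergence_near_contour(self):
        assert neck.wlc_force(5.6 * 0.998, 5.6, WLC) > 1e3

    def test_extension_beyond_contour_rejected(self):
        with pytest.raises(neck.ExtensionError):
            neck.wlc_force(5.6, 5.6, WLC)

    @given(st.floats(min_value=1e-4, max_value=0.995))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_increasing(self, x):
        lc = 5.6
        f1 = neck.wlc_force(x * lc, lc, WLC)
        f2 = neck.wlc_force(min(x + 1e-3, 0.9985) * lc, lc, WLC)
        assert f2 > f1

    def test_convex_beyond_linear_regime(self):
        xs = np.linspace(0.3, 0.99, 1000)
        f = neck.wlc_force(xs * 5.6, 5.6, WLC)
        d2 = np.diff(f, 2)
        assert (d2 > 0).all()


@pytest.mark.parametrize("n0,nuw,n_aa,lc", [
    (14, 0, 14.0, 5.6),
    (4, 0, 4.0, 1.6),
    (14, 2, 21.0, 8.4),
])
def test_contour_length(n0, nuw, n_aa, lc):
    got_naa, got_lc = neck.contour_length(n0, nuw, WLC)
    assert got_naa == pytest.approx(n_aa)
    assert got_lc == pytest.approx(lc)


def test_contour_length_unwinding_limit():
    with pytest.raises(ParameterError):
        neck.contour_length(14, 11, WLC)


class TestNeckEquilibrium:
    params = ModelParams()

    def test_symmetry_axis_zero_axial_force(self):
        # on x = ell_DC the axial force vanishes by symmetry
        st = neck.solve_neck_equilibrium((2.9, 3.0), (0.0, 0.0), self.params)
        assert st.f_head[0] == pytest.approx(0.0, abs=1e-9)
        assert st.residual < 1e-6

    def test_slack_chains_no_unwinding(self):
        st = neck.solve_neck_equilibrium((4.0, 0.5), (0.0, 0.0), self.params)
        assert st.n_uw == 0
        assert st.f_uw < 10.0

    def test_far_diagonal_requires_unwinding(self):
        # the far diagonal absorbing point is out of reach of the fully
        # wound neck: 10 pN is exceeded until turns pop
        st = neck.solve_neck_equilibrium((8.0, 6.4), (0.0, 0.0), self.params)
        assert st.n_uw >= 1
        assert st.f_uw < 10.0

    def test_force_balance_residual(self):
        st = neck.solve_neck_equilibrium((6.0, 2.0), (-3.0, 0.5), self.params)
        total = np.array(st.f_udnl) + np.array(st.f_dcnl) + np.array([-3.0, 0.5])
        assert np.linalg.norm(total) < 1e-6

    def test_unwinding_threshold_crossing(self):
        # bisection on head distance along the axis: n_uw first becomes
        # positive where the wound-neck tension crosses 10 pN
        lo, hi = 3.0, 8.0
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            st = neck.solve_neck_equilibrium((mid, 0.0), (0.0, 0.0), self.params)
            if st.n_uw == 0:
                lo = mid
            else:
                hi = mid
        t, _ = neck._tension_two_chain(
            np.array([lo - 2.9]), 5.6, 1.6, self.params.wlc)
        assert t[0] == pytest.approx(10.0, abs=0.1)

    def test_hysteresis_free_refolding(self):
        # solving far then near returns to the near-position n_uw
        far = neck.solve_neck_equilibrium((8.0, 6.4), (0.0, 0.0), self.params)
        near = neck.solve_neck_equilibrium((4.0, 0.0), (0.0, 0.0), self.params)
        assert near.n_uw <= far.n_uw
        assert near.n_uw == 0

    def test_infeasible_without_unwinding(self):
        p = self.params.with_variants(allow_unwinding=False)
        with pytest.raises(neck.InfeasibleConfigurationError):
            neck.solve_neck_equilibrium((10.0, 6.0), (0.0, 0.0), p)


class TestForceField:
    params = ModelParams()

    def test_zero_load_symmetries(self):
        # grid chosen so x = ell_DC = 2.9 is a node, with symmetric partners
        ff = neck.tabulate_force_field((-12.1, 12.1, -10, 10), 0.5, (0.0, 0.0),
                                       self.params)
        ix = int(np.argmin(np.abs(ff.x - 2.9)))
        assert ff.x[ix] == pytest.approx(2.9)
        for d in (2, 5, 8):
            assert abs(ff.Fx[ix - d, :]).max() == pytest.approx(
                abs(ff.Fx[ix + d, :]).max(), rel=1e-6)
        # Fy antisymmetric in y, Fx symmetric in y
        assert np.allclose(ff.Fy, -ff.Fy[:, ::-1], atol=1e-8)
        assert np.allclose(ff.Fx, ff.Fx[:, ::-1], atol=1e-8)
        # Fy vanishes on the MT axis
        iy = np.argmin(np.abs(ff.y))
        assert abs(ff.Fy[:, iy]).max() < 0.2
        assert np.isfinite(ff.Fx).all() and np.isfinite(ff.Fy).all()

    def test_load_breaks_fore_aft_symmetry(self):
        ff0 = neck.tabulate_force_field((-12, 12, -10, 10), 0.5, (0.0, 0.0),
                                        self.params)
        ff7 = neck.tabulate_force_field((-12, 12, -10, 10), 0.5, (-7.0, 0.0),
                                        self.params)
        iy = np.argmin(np.abs(ff7.y))
        # pointwise comparison is confounded by the shifted unwinding
        # sawtooth, but the potential tilt is unambiguous: the load lowers
        # the rear of the landscape relative to the front
        dx = ff0.x[1] - ff0.x[0]
        tilt0 = -np.sum(ff0.Fx[:, iy]) * dx   # U(front) - U(back)
        tilt7 = -np.sum(ff7.Fx[:, iy]) * dx
        assert tilt7 > tilt0 + 20.0   # pN nm; well beyond discretisation noise
        assert ff7.Fx[:, iy].mean() < ff0.Fx[:, iy].mean() - 0.5

    def test_cache_hit_returns_same_object(self):
        a = neck.tabulate_force_field((-12, 12, -10, 10), 0.5, (0.0, 0.0),
                                      self.params)
        b = neck.tabulate_force_field((-12, 12, -10, 10), 0.5, (0.0, 0.0),
                                      self.params)
        assert a is b

    def test_interpolation_matches_nodes(self):
        ff = neck.tabulate_force_field((-12, 12, -10, 10), 0.5, (0.0, 0.0),
                                       self.params)
        pts = np.array([[ff.x[10], ff.y[7]], [ff.x[3], ff.y[19]]])
        got = ff.interpolate(pts)
        assert got[0] == pytest.approx((ff.Fx[10, 7], ff.Fy[10, 7]), abs=1e-9)
        assert got[1] == pytest.approx((ff.Fx[3, 19], ff.Fy[3, 19]), abs=1e-9)

    def test_radial_and_newton_paths_agree(self):
        # the zero-load fast path must match the generic 2D solver
        pts = np.array([[5.0, 1.0], [0.0, 4.0], [-3.0, -2.0], [8.0, 6.4]])
        fx_r, fy_r, n_r = neck.head_force_field(pts, (0.0, 0.0), self.params)
        fx_n, fy_n, n_n = neck.head_force_field(pts, (1e-13, 0.0), self.params)
        assert np.allclose(fx_r, fx_n, atol=1e-5)
        assert np.allclose(fy_r, fy_n, atol=1e-5)
        assert (n_r == n_n).all()
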