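"""Neck-linker mechanics: WLC forces, coiled-coil unwinding, head force field.

The free head (position h, taken as its AA-324 attachment point) is connected
to the neck by the undocked NL; the docked NL runs from the neck to AA 334 of
the fixed head at (ell_dc, 0).  For a given head position the neck settles
where the vector sum of the two NL tensions and the cargo force vanishes.  The
tension transmitted through the coiled-coil neck, F_UW, unwinds one turn
whenever it reaches the unwinding force (~10 pN), which lengthens both NL
contours by 3.5 amino acids each; the procedure repeats until F_UW drops below
the threshold or the coil is fully unwound.  Refolding follows the same
force-extension relation, so the resulting force field is a single-valued
function of head position (no hysteresis).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .params import ModelParams, WLCParams, ParameterError

_FEAS = 0.999  # fraction of total contour length treated as reachable


class ExtensionError(ValueError):
    """WLC extension at or beyond the contour length."""


class InfeasibleConfigurationError(ValueError):
    """Head position unreachable with the available NL contour."""


def wlc_force(ell_nl, ell_c, params: WLCParams):
    """Worm-like-chain tension (pN) at end-to-end extension ``ell_nl``.

    F = (k_B T / l_p) [ 1/4 (1 - l/l_c)^-2 + l/l_c - 1/4 ].
    Accepts scalars or arrays; strictly increasing, 0 at zero extension,
    diverging as l -> l_c.
    """
    ell_nl = np.asarray(ell_nl, dtype=float)
    ell_c = np.asarray(ell_c, dtype=float)
    if np.any(ell_nl < 0):
        raise ExtensionError("extension must be non-negative")
    if np.any(ell_nl >= ell_c):
        raise ExtensionError("extension must be below the contour length")
    x = ell_nl / ell_c
    f = (params.kBT / params.lp) * (0.25 * (1.0 - x) ** -2 + x - 0.25)
    return float(f) if f.ndim == 0 else f


def contour_length(n_aa_0: float, n_uw: int, params: WLCParams) -> Tuple[float, float]:
    """(N_AA, contour length in nm) after ``n_uw`` unwound turns.

    N_AA = N_AA,0 + 3.5 n_uw; l_c = N_AA · l_a.
    """
    if n_uw < 0:
        raise ParameterError("n_uw must be non-negative")
    if n_uw > params.max_turns:
        raise ParameterError(f"n_uw exceeds the {params.max_turns}-turn coil")
    n_aa = n_aa_0 + params.aa_per_turn * n_uw
    return n_aa, n_aa * params.la


def _wlc_f(x, kbt_lp):
    """Tension as a function of relative extension x = l/l_c (clipped)."""
    x = np.clip(x, 0.0, _FEAS)
    return kbt_lp * (0.25 * (1.0 - x) ** -2 + x - 0.25)


def _tension_two_chain(d, lc1, lc2, params: WLCParams, iters: int = 80):
    """Equal tension of two WLCs in series spanning distance d (vectorized).

    Solves f(l1/lc1) = f((d-l1)/lc2) for l1 by bisection; returns (tension,
    l1).  Valid for d < lc1 + lc2.
    """
    d = np.asarray(d, dtype=float)
    kbt_lp = params.kBT / params.lp
    lo = np.maximum(0.0, d - _FEAS * lc2)
    hi = np.minimum(_FEAS * lc1, d)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        g = _wlc_f(mid / lc1, kbt_lp) - _wlc_f((d - mid) / lc2, kbt_lp)
        take_hi = g < 0.0
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    l1 = 0.5 * (lo + hi)
    return _wlc_f(l1 / lc1, kbt_lp), l1


def radial_tension(r, params: WLCParams, allow_unwinding: bool = True):
    """Zero-load NL tension on the head at distance r from the docked anchor.

    With no cargo force the neck lies on the segment between the head and the
    docked anchor, so the force on the head is radial with this magnitude.
    Returns (tension pN, n_uw, feasible mask).  Infeasible radii (beyond the
    reachable contour) get tension = +inf and feasible = False.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    n_uw = np.zeros(r.shape, dtype=int)
    tension = np.full(r.shape, np.inf)
    feasible = np.zeros(r.shape, dtype=bool)
    max_n = params.max_turns if allow_unwinding else 0
    pending = np.ones(r.shape, dtype=bool)
    while pending.any():
        lc1 = (params.n_aa_undocked + params.aa_per_turn * n_uw) * params.la
        lc2 = (params.n_aa_docked + params.aa_per_turn * n_uw) * params.la
        reach = _FEAS * (lc1 + lc2)
        short = pending & (r >= reach)
        bump = short & (n_uw < max_n)
        n_uw[bump] += 1                     # stay pending, retry next pass
        pending[short & ~bump] = False      # truly unreachable: tension = inf
        solv = pending & ~short
        if solv.any():
            t, _ = _tension_two_chain(r[solv], lc1[solv], lc2[solv], params)
            tension[solv] = t
            feasible[solv] = True
            over = np.zeros(r.shape, dtype=bool)
            over[solv] = t >= params.unwind_force
            over &= n_uw < max_n
            n_uw[over] += 1
            pending[solv] = over[solv]      # re-solve only newly unwound points
    return tension, n_uw, feasible


@dataclass
class NeckState:
    """Converged neck equilibrium for one head position."""

    neck_position: Tuple[float, float]
    n_uw: int
    f_udnl: Tuple[float, float]   # pN, force the undocked NL exerts on the neck
    f_dcnl: Tuple[float, float]   # pN, force the docked NL exerts on the neck
    f_uw: float                   # pN, tension along the coil axis
    f_head: Tuple[float, float]   # pN, force on the free head
    residual: float               # pN, |sum of forces at the neck|
    feasible: bool = True


def _wlc_energy(ell, lc, params: WLCParams):
    """Stretching free energy of one WLC at end-to-end extension ell (pN·nm)."""
    x = np.clip(np.asarray(ell, dtype=float) / lc, 0.0, _FEAS)
    k = params.kBT / params.lp
    return k * lc * (0.25 * (1.0 / (1.0 - x) - 1.0) + 0.5 * x ** 2 - 0.25 * x)


def _equilibrium_2d(h, anchor, cargo, lc1, lc2, tol=1e-9, max_iter=200,
                    polish=True):
    """Vectorized damped-Newton force balance at the neck.

    h: (N,2) head positions; lc1/lc2: (N,) contours; cargo: (2,) force.
    Returns neck positions (N,2), residual norms (N,).
    """
    h = np.asarray(h, dtype=float)
    a = np.asarray(anchor, dtype=float)
    cargo = np.asarray(cargo, dtype=float)
    d = np.linalg.norm(h - a, axis=1)
    dd = np.where(d < 1e-12, 1.0, d)
    _, l1 = _tension_two_chain(d, lc1, lc2, WLC_CACHE[0])
    n = h + (a - h) * (l1 / dd)[:, None]
    cn = np.linalg.norm(cargo)
    if cn > 0:
        # bias the start along the cargo pull; essential when the head sits on
        # top of the docked anchor and the on-segment guess is degenerate
        n = n + 0.25 * min(1.0, cn) * (cargo / cn)[None, :]

    kbt_lp = WLC_CACHE[0].kBT / WLC_CACHE[0].lp

    def residual(n_s, idx):
        v1 = h[idx] - n_s
        v2 = a[None, :] - n_s
        e1 = np.linalg.norm(v1, axis=1)
        e2 = np.linalg.norm(v2, axis=1)
        f1 = _wlc_f(e1 / lc1[idx], kbt_lp)
        f2 = _wlc_f(e2 / lc2[idx], kbt_lp)
        u1 = v1 / np.where(e1 < 1e-12, 1.0, e1)[:, None]
        u2 = v2 / np.where(e2 < 1e-12, 1.0, e2)[:, None]
        R = f1[:, None] * u1 + f2[:, None] * u2 + cargo[None, :]
        return R, e1, e2, u1, u2, f1, f2

    act = np.arange(len(n))
    for _ in range(max_iter):
        R, e1, e2, u1, u2, f1, f2 = residual(n[act], act)
        rn_a = np.linalg.norm(R, axis=1)
        conv = rn_a < tol
        act = act[~conv]
        if act.size == 0:
            break
        R, e1, e2, u1, u2, f1, f2 = (z[~conv] for z in (R, e1, e2, u1, u2, f1, f2))
        # dF/dn for each chain: -(f' u u^T + (f/e)(I - u u^T))
        J = np.zeros((act.size, 2, 2))
        for (e, u, f, lc) in ((e1, u1, f1, lc1[act]), (e2, u2, f2, lc2[act])):
            x = np.clip(e / lc, 1e-12, _FEAS)
            fp = kbt_lp * (0.5 * (1.0 - x) ** -3 + 1.0) / lc
            fr = f / np.where(e < 1e-12, 1.0, e)
            uu = u[:, :, None] * u[:, None, :]
            eye = np.eye(2)[None, :, :]
            J -= fp[:, None, None] * uu + fr[:, None, None] * (eye - uu)
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        det = np.where(np.abs(det) < 1e-30, 1e-30, det)
        dx = (-J[:, 1, 1] * R[:, 0] + J[:, 0, 1] * R[:, 1]) / det
        dy = (J[:, 1, 0] * R[:, 0] - J[:, 0, 0] * R[:, 1]) / det
        step = np.stack([dx, dy], axis=1)
        # damp steps so both extensions stay strictly inside the contour
        alpha = np.ones(act.size)
        for _bt in range(40):
            cand = n[act] + alpha[:, None] * step
            ok = (np.linalg.norm(h[act] - cand, axis=1) < _FEAS * lc1[act]) & \
                 (np.linalg.norm(a[None, :] - cand, axis=1) < _FEAS * lc2[act])
            if ok.all():
                break
            alpha[~ok] *= 0.5
        # and insist the residual does not grow (prevents the oscillation
        # that otherwise sends hard points to the slow fallback)
        for _bt in range(12):
            cand = n[act] + alpha[:, None] * step
            Rc, *_ = residual(cand, act)
            worse = np.linalg.norm(Rc, axis=1) > rn_a[~conv]
            if not worse.any():
                break
            alpha[worse] *= 0.5
        n[act] = n[act] + alpha[:, None] * step
    R, *_ = residual(n, np.arange(len(n)))
    rn = np.linalg.norm(R, axis=1)
    bad = np.nonzero(rn > 1e-6)[0] if polish else np.zeros(0, dtype=int)
    if bad.size:
        # rare degenerate geometries: fall back to direct minimisation of the
        # total elastic + cargo energy, which shares its stationary point with
        # the force balance
        from scipy.optimize import minimize
        par = WLC_CACHE[0]
        for k in bad:
            def energy(nv, k=k):
                e1 = math.hypot(h[k, 0] - nv[0], h[k, 1] - nv[1])
                e2 = math.hypot(a[0] - nv[0], a[1] - nv[1])
                pen = 0.0
                if e1 >= _FEAS * lc1[k]:
                    pen += 1e4 * (e1 - _FEAS * lc1[k] + 1e-3) ** 2
                    e1 = _FEAS * lc1[k]
                if e2 >= _FEAS * lc2[k]:
                    pen += 1e4 * (e2 - _FEAS * lc2[k] + 1e-3) ** 2
                    e2 = _FEAS * lc2[k]
                return (float(_wlc_energy(e1, lc1[k], par))
                        + float(_wlc_energy(e2, lc2[k], par))
                        - cargo[0] * nv[0] - cargo[1] * nv[1] + pen)
            res = minimize(energy, n[k], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 2000})
            n[k] = res.x
        R, *_ = residual(n, np.arange(len(n)))
        rn = np.linalg.norm(R, axis=1)
    return n, rn


# module-level handle so the vectorized solver sees the active WLC parameters
WLC_CACHE = [WLCParams()]


def head_force_field(points: np.ndarray, cargo_force: Tuple[float, float],
                     params: ModelParams) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Force (Fx, Fy) on the free head at each point, plus n_uw per point.

    points: (N, 2) head positions in nm.  Infeasible points (unreachable even
    fully unwound, or with unwinding disabled) get NaN forces; the diffusion
    solver masks them out as excluded volume.
    """
    wlc = params.wlc
    WLC_CACHE[0] = wlc
    pts = np.asarray(points, dtype=float)
    a = np.asarray(wlc.docked_anchor)
    cargo = np.asarray(cargo_force, dtype=float)
    allow_uw = params.diffusion.allow_unwinding
    if np.allclose(cargo, 0.0):
        rel = pts - a[None, :]
        r = np.linalg.norm(rel, axis=1)
        t, n_uw, feas = radial_tension(r, wlc, allow_uw)
        rr = np.where(r < 1e-12, 1.0, r)
        scale = np.where(feas, -t / rr, np.nan)
        scale = np.where(r < 1e-12, 0.0, scale)
        F = scale[:, None] * rel
        return F[:, 0], F[:, 1], n_uw

    n_pts = len(pts)
    n_uw = np.zeros(n_pts, dtype=int)
    Fx = np.full(n_pts, np.nan)
    Fy = np.full(n_pts, np.nan)
    max_n = wlc.max_turns if allow_uw else 0
    d = np.linalg.norm(pts - a[None, :], axis=1)
    active = np.arange(n_pts)
    needs_polish = []
    while active.size:
        lc1 = (wlc.n_aa_undocked + wlc.aa_per_turn * n_uw[active]) * wlc.la
        lc2 = (wlc.n_aa_docked + wlc.aa_per_turn * n_uw[active]) * wlc.la
        reach = _FEAS * (lc1 + lc2)
        short = d[active] >= reach
        bump = short & (n_uw[active] < max_n)
        n_uw[active[bump]] += 1
        dead = short & ~bump
        keep = active[~short]
        redo = active[bump]
        if keep.size:
            lc1k = (wlc.n_aa_undocked + wlc.aa_per_turn * n_uw[keep]) * wlc.la
            lc2k = (wlc.n_aa_docked + wlc.aa_per_turn * n_uw[keep]) * wlc.la
            # rough solves suffice while the coil is still unwinding; points
            # that stay at this level get a polished re-solve below
            neck, res = _equilibrium_2d(pts[keep], a, cargo, lc1k, lc2k,
                                        polish=False)
            v1 = pts[keep] - neck
            e1 = np.linalg.norm(v1, axis=1)
            kbt_lp = wlc.kBT / wlc.lp
            f1 = _wlc_f(e1 / lc1k, kbt_lp)
            u1 = v1 / np.where(e1 < 1e-12, 1.0, e1)[:, None]
            # force on the head pulls it toward the neck
            Fh = -f1[:, None] * u1
            Fx[keep], Fy[keep] = Fh[:, 0], Fh[:, 1]
            # coil tension: the coil is a moment-free member aligned with
            # F1 - F2; with the cargo at its centre the larger of the two end
            # tensions is |F1 - F2|/2 + |Fc·u|/2, and that is what unwinds
            # the first turn
            F1 = f1[:, None] * u1
            v2 = a[None, :] - neck
            e2 = np.linalg.norm(v2, axis=1)
            f2 = _wlc_f(e2 / lc2k, kbt_lp)
            u2 = v2 / np.where(e2 < 1e-12, 1.0, e2)[:, None]
            F2 = f2[:, None] * u2
            dF = F1 - F2
            ndF = np.linalg.norm(dF, axis=1)
            axial_cargo = np.abs(dF @ cargo) / np.where(ndF < 1e-12, 1.0, ndF)
            t_high = 0.5 * ndF + 0.5 * axial_cargo
            t_low = np.maximum(0.5 * ndF - 0.5 * axial_cargo, 0.0)
            # the cargo loads the coil from its centre, so the tension is
            # piecewise constant: the half-coil on the loaded side (about
            # max_turns/2 turns) sees t_high, the other half t_low
            half = max(1, wlc.max_turns // 2)
            drive = np.where(n_uw[keep] < half, t_high, t_low)
            over = (drive >= wlc.unwind_force) & (n_uw[keep] < max_n)
            n_uw[keep[over]] += 1
            redo = np.concatenate([redo, keep[over]])
            fin_bad = keep[~over & (res > 1e-6)]
            if fin_bad.size:
                needs_polish.append(fin_bad)
        active = redo
    if needs_polish:
        idx = np.unique(np.concatenate(needs_polish))
        lc1p = (wlc.n_aa_undocked + wlc.aa_per_turn * n_uw[idx]) * wlc.la
        lc2p = (wlc.n_aa_docked + wlc.aa_per_turn * n_uw[idx]) * wlc.la
        neck, res = _equilibrium_2d(pts[idx], a, cargo, lc1p, lc2p)
        kbt_lp = wlc.kBT / wlc.lp
        v1 = pts[idx] - neck
        e1 = np.linalg.norm(v1, axis=1)
        f1 = _wlc_f(e1 / lc1p, kbt_lp)
        u1 = v1 / np.where(e1 < 1e-12, 1.0, e1)[:, None]
        Fx[idx] = -f1 * u1[:, 0]
        Fy[idx] = -f1 * u1[:, 1]
    return Fx, Fy, n_uw


def solve_neck_equilibrium(free_head_position: Tuple[float, float],
                           cargo_force: Tuple[float, float],
                           params: ModelParams) -> NeckState:
    """Full neck equilibrium (with the unwinding iteration) at one head position."""
    wlc = params.wlc
    WLC_CACHE[0] = wlc
    h = np.asarray([free_head_position], dtype=float)
    a = np.asarray(wlc.docked_anchor)
    cargo = np.asarray(cargo_force, dtype=float)
    max_n = wlc.max_turns if params.diffusion.allow_unwinding else 0
    d = float(np.linalg.norm(h[0] - a))
    n_uw = 0
    for _ in range(max_n + 2):
        _, lc1 = contour_length(wlc.n_aa_undocked, n_uw, wlc)
        _, lc2 = contour_length(wlc.n_aa_docked, n_uw, wlc)
        if d >= _FEAS * (lc1 + lc2):
            if n_uw < max_n:
                n_uw += 1
                continue
            raise InfeasibleConfigurationError(
                f"head at distance {d:.2f} nm unreachable with n_uw={n_uw}")
        neck, res = _equilibrium_2d(h, a, cargo, np.array([lc1]), np.array([lc2]))
        if res[0] > 1e-6:
            raise RuntimeError(
                f"neck equilibrium did not converge (|R| = {res[0]:.2e} pN)")
        kbt_lp = wlc.kBT / wlc.lp
        v1 = h[0] - neck[0]
        v2 = a - neck[0]
        e1, e2 = np.linalg.norm(v1), np.linalg.norm(v2)
        f1 = float(_wlc_f(e1 / lc1, kbt_lp))
        f2 = float(_wlc_f(e2 / lc2, kbt_lp))
        u1 = v1 / (e1 if e1 > 1e-12 else 1.0)
        u2 = v2 / (e2 if e2 > 1e-12 else 1.0)
        F1, F2 = f1 * u1, f2 * u2
        dF = F1 - F2
        ndF = float(np.linalg.norm(dF))
        axial_cargo = abs(float(dF @ cargo)) / ndF if ndF > 1e-12 else 0.0
        t_high = 0.5 * ndF + 0.5 * axial_cargo
        t_low = max(0.5 * ndF - 0.5 * axial_cargo, 0.0)
        half = max(1, wlc.max_turns // 2)
        f_uw = t_high if n_uw < half else t_low
        if f_uw >= wlc.unwind_force and n_uw < max_n:
            n_uw += 1
            continue
        return NeckState(
            neck_position=(float(neck[0, 0]), float(neck[0, 1])),
            n_uw=n_uw,
            f_udnl=(float(F1[0]), float(F1[1])),
            f_dcnl=(float(F2[0]), float(F2[1])),
            f_uw=f_uw,
            f_head=(-float(F1[0]), -float(F1[1])),
            residual=float(res[0]),
        )
    raise RuntimeError("unwinding iteration failed to terminate")


@dataclass
class ForceField:
    """Tabulated force field over a rectangular domain (regular grid)."""

    x: np.ndarray        # (nx,) node coordinates, nm
    y: np.ndarray        # (ny,)
    Fx: np.ndarray       # (nx, ny), pN
    Fy: np.ndarray       # (nx, ny), pN
    n_uw: np.ndarray     # (nx, ny), unwound turns at each node
    cargo_force: Tuple[float, float]

    def interpolate(self, pts: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of (Fx, Fy) at arbitrary points (N,2)."""
        xi = np.clip((pts[:, 0] - self.x[0]) / (self.x[1] - self.x[0]),
                     0, len(self.x) - 1.0001)
        yi = np.clip((pts[:, 1] - self.y[0]) / (self.y[1] - self.y[0]),
                     0, len(self.y) - 1.0001)
        i0 = xi.astype(int)
        j0 = yi.astype(int)
        fx = xi - i0
        fy = yi - j0
        out = np.empty((len(pts), 2))
        for k, F in enumerate((self.Fx, self.Fy)):
            out[:, k] = (F[i0, j0] * (1 - fx) * (1 - fy)
                         + F[i0 + 1, j0] * fx * (1 - fy)
                         + F[i0, j0 + 1] * (1 - fx) * fy
                         + F[i0 + 1, j0 + 1] * fx * fy)
        return out

    def to_dataframe(self):
        import pandas as pd
        X, Y = np.meshgrid(self.x, self.y, indexing="ij")
        return pd.DataFrame({
            "x_nm": X.ravel(), "y_nm": Y.ravel(),
            "Fx_pN": self.Fx.ravel(), "Fy_pN": self.Fy.ravel(),
            "n_uw": self.n_uw.ravel(),
        })


_FIELD_CACHE: dict = {}


def tabulate_force_field(domain: Tuple[float, float, float, float],
                         resolution: float,
                         cargo_force: Tuple[float, float],
                         params: ModelParams) -> ForceField:
    """Evaluate the head force on a regular grid over ``domain``.

    Results are cached on (domain, resolution, cargo force, NL variant).
    NaN values mark unreachable nodes (possible with unwinding disabled).
    """
    if resolution <= 0:
        raise ParameterError("resolution must be positive")
    key = (tuple(np.round(domain, 9)), round(resolution, 9),
           tuple(np.round(cargo_force, 9)), params.wlc, params.diffusion.allow_unwinding)
    if key in _FIELD_CACHE:
        return _FIELD_CACHE[key]
    x0, x1, y0, y1 = domain
    x = np.arange(x0, x1 + resolution / 2, resolution)
    y = np.arange(y0, y1 + resolution / 2, resolution)
    X, Y = np.meshgrid(x, y, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    Fx, Fy, n_uw = head_force_field(pts, cargo_force, params)
    ff = ForceField(x=x, y=y, Fx=Fx.reshape(X.shape), Fy=Fy.reshape(X.shape),
                    n_uw=n_uw.reshape(X.shape), cargo_force=tuple(cargo_force))
    _FIELD_CACHE[key] = ff
    return ff
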