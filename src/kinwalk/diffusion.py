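"""Fokker-Planck solver for the diffusing free head.

The probability density p(x, y, t) of the free-head position obeys

    dp/dt = D (d²p/dx² + d²p/dy²) - d/dx(Fx/γ p) - d/dy(Fy/γ p)

with p = 0 on small circles at the binding sites (absorbing) and zero normal
flux on obstacle circles and the outer walls (reflective).  The probability of
binding to site i is the time integral of the outflow through its boundary.

Discretisation: cell-centred finite volumes on a regular grid with
Scharfetter-Gummel (exponentially fitted) face fluxes, which remain stable and
conservative at the large local Péclet numbers produced by the stretched neck
linkers.  Two solution paths are provided:

* :func:`solve_splitting` solves the stationary problem for the
  time-integrated density u = ∫₀^∞ p dt (L u = -p₀), from which the binding
  probabilities and the obstacle interference integral follow without time
  truncation; this is the production path.
* :func:`solve_fokker_planck` time-steps the same operator (backward Euler)
  and returns density snapshots, per-site flux series and the residual mass,
  used for conservation checks and diagnostics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .params import ModelParams, ParameterError
from . import lattice as lat
from . import neck


class GeometryError(ValueError):
    """Inconsistent diffusion-domain geometry."""


class SolverError(RuntimeError):
    """Conservation or positivity failure in the PDE solve."""


@dataclass(frozen=True)
class DiffusionProblem:
    """Geometry + physics of one free-head diffusion solve."""

    params: ModelParams
    cargo_force: Tuple[float, float] = (0.0, 0.0)
    # site index -> "occupied" (reflective circle, no binding) or "excluded"
    # (no binding, no circle)
    blocked: Tuple[Tuple[int, str], ...] = ()
    extended: bool = False
    init_position: Optional[Tuple[float, float]] = None

    @property
    def domain(self) -> Tuple[float, float, float, float]:
        d = self.params.diffusion
        return d.domain_24 if self.extended else d.domain_8

    def absorbing_points(self) -> Dict[int, Tuple[float, float]]:
        d = self.params.diffusion
        pos = lat.absorbing_positions(
            self.params.lattice, self.params.geom,
            tilted=d.allow_tilted_binding, extended=self.extended)
        blocked = dict(self.blocked)
        pos = {i: p for i, p in pos.items() if i not in blocked}
        if d.allow_tilted_binding:
            # tilting needs clearance: when an obstacle's blocked region
            # leaves no room for the tilt swing, the diagonal binds in the
            # untilted posture instead (the same steric argument that denies
            # tilting at the forward/side/rear sites)
            untilted = lat.absorbing_positions(
                self.params.lattice, self.params.geom, tilted=False,
                extended=self.extended)
            r_b = d.r_absorb
            for site in lat.DIAGONAL_SITES:
                if site not in pos:
                    continue
                px, py = pos[site]
                for _, cx, cy, R in self.reflector_circles():
                    if math.hypot(px - cx, py - cy) < R + r_b + 0.25:
                        pos[site] = untilted[site]
                        break
        return pos

    def reflector_circles(self) -> List[Tuple[int, float, float, float]]:
        """(site, cx, cy, R) for each occupied neighbour site."""
        pos = lat.neighbor_positions_local(
            self.params.lattice.d_side, self.params.lattice.axial_spacing)
        if self.extended:
            pos = lat.extended_positions_local(
                self.params.lattice.d_side, self.params.lattice.axial_spacing)
        out = []
        for site, state in self.blocked:
            if state == "occupied":
                cx, cy = pos[site]
                out.append((site, cx, cy, self.params.obstacle.r_obs))
        return out


def assemble_problem(params: ModelParams,
                     cargo_force: Tuple[float, float] = (0.0, 0.0),
                     blocked: Optional[Dict[int, str]] = None,
                     extended: bool = False,
                     init_position: Optional[Tuple[float, float]] = None
                     ) -> DiffusionProblem:
    """Build a diffusion problem from variant flags and a blocked-site map.

    ``blocked`` maps neighbour indices to "occupied" (an obstacle's bound head
    sits there: binding removed and a reflective circle of radius R_obs added)
    or "excluded" (covered by a diffusing-head footprint: binding removed
    only).
    """
    blocked = blocked or {}
    for site, state in blocked.items():
        if state not in ("occupied", "excluded"):
            raise ParameterError(f"unknown blocked state {state!r}")
        if site not in range(1, 25 if extended else 9):
            raise ParameterError(f"invalid neighbour index {site}")
    return DiffusionProblem(
        params=params, cargo_force=tuple(cargo_force),
        blocked=tuple(sorted(blocked.items())), extended=extended,
        init_position=tuple(init_position) if init_position else None)


# --------------------------------------------------------------------------
# grid machinery

def _bernoulli(w: np.ndarray) -> np.ndarray:
    """B(w) = w / (e^w - 1), the Scharfetter-Gummel weight (stable near 0)."""
    out = np.empty_like(w)
    small = np.abs(w) < 1e-10
    out[small] = 1.0 - 0.5 * w[small]
    ws = np.clip(w[~small], -500, 500)
    out[~small] = ws / np.expm1(ws)
    return out


_FACE_CACHE: dict = {}


class _Grid:
    """Discretised domain: cell classification, operator, flux maps."""

    def __init__(self, problem: DiffusionProblem, grid_step: Optional[float] = None):
        par = problem.params
        h = grid_step or par.diffusion.grid_step
        r_b = par.diffusion.r_absorb
        if h > r_b / 2 + 1e-12:
            raise ParameterError(
                f"grid step {h} too coarse for absorbing radius {r_b}")
        x0, x1, y0, y1 = problem.domain
        nx = int(round((x1 - x0) / h))
        ny = int(round((y1 - y0) / h))
        self.h, self.nx, self.ny = h, nx, ny
        self.xc = x0 + (np.arange(nx) + 0.5) * h
        self.yc = y0 + (np.arange(ny) + 0.5) * h
        X, Y = np.meshgrid(self.xc, self.yc, indexing="ij")
        self.X, self.Y = X, Y
        self.problem = problem

        # blocked cells: obstacle circles + (when unwinding is off) the region
        # the neck linkers cannot reach
        blocked = np.zeros((nx, ny), dtype=bool)
        for _, cx, cy, R in problem.reflector_circles():
            blocked |= (X - cx) ** 2 + (Y - cy) ** 2 <= R ** 2
        wlc = par.wlc
        if not par.diffusion.allow_unwinding:
            lc_sum = (wlc.n_aa_undocked + wlc.n_aa_docked) * wlc.la
            ax, ay = wlc.docked_anchor
            blocked |= (X - ax) ** 2 + (Y - ay) ** 2 >= (0.999 * lc_sum) ** 2

        absorb_site = np.full((nx, ny), -1, dtype=int)
        self.site_points = problem.absorbing_points()
        # mark cells strictly inside the circle (half a cell of clearance);
        # the cut-cell face coefficients place the Dirichlet surface on the
        # analytic circle itself, which keeps the splitting probabilities
        # from rattling with the staircase as the grid is refined
        r_mark = r_b - 0.25 * h
        for site, (cx, cy) in self.site_points.items():
            m = ((X - cx) ** 2 + (Y - cy) ** 2 <= r_mark ** 2) & ~blocked
            absorb_site[m] = site
        # obstacle circles can seal off corner pockets with no absorbing
        # boundary; the head can never occupy them, so mark them blocked
        # (leaving them in would make the stationary operator singular)
        if (absorb_site >= 0).any():
            from scipy.ndimage import label
            lab, ncomp = label(~blocked)
            keep = np.zeros(ncomp + 1, dtype=bool)
            keep[np.unique(lab[absorb_site >= 0])] = True
            keep[0] = False
            blocked |= ~keep[lab]

        self.blocked = blocked
        self.absorb_site = np.where(blocked, -1, absorb_site)
        self.fluid = ~blocked & (self.absorb_site < 0)
        if not self.fluid.any():
            raise GeometryError("no fluid cells in domain")
        self.fluid_index = -np.ones((nx, ny), dtype=int)
        self.fluid_index[self.fluid] = np.arange(self.fluid.sum())
        self.n_fluid = int(self.fluid.sum())
        self._build_operator()

    def _face_velocities(self):
        """Drift velocity F/γ at x-face and y-face midpoints (cached)."""
        par = self.problem.params
        h = self.h
        key = (self.problem.domain, round(h, 9),
               tuple(np.round(self.problem.cargo_force, 9)), par.wlc,
               par.diffusion.allow_unwinding, par.diffusion.gamma)
        hit = _FACE_CACHE.get(key)
        if hit is not None:
            return hit
        fx_pts_x = np.stack([
            np.repeat(self.xc[:-1] + h / 2, self.ny),
            np.tile(self.yc, self.nx - 1)], axis=1)
        fy_pts = np.stack([
            np.repeat(self.xc, self.ny - 1),
            np.tile(self.yc[:-1] + h / 2, self.nx)], axis=1)
        Fx1, _, _ = neck.head_force_field(fx_pts_x, self.problem.cargo_force, par)
        _, Fy2, _ = neck.head_force_field(fy_pts, self.problem.cargo_force, par)
        g = par.diffusion.gamma
        vx = (Fx1 / g).reshape(self.nx - 1, self.ny)
        vy = (Fy2 / g).reshape(self.nx, self.ny - 1)
        out = (np.nan_to_num(vx), np.nan_to_num(vy))
        _FACE_CACHE[key] = out
        return out

    def _build_operator(self):
        D = self.problem.params.diffusion.D
        h = self.h
        vx, vy = self._face_velocities()
        rows, cols, vals = [], [], []
        # flux bookkeeping for absorbing sites: P_b = sum(coef * u[fluid cell])
        site_rows: Dict[int, List[Tuple[int, float]]] = {
            s: [] for s in self.site_points}

        r_b = self.problem.params.diffusion.r_absorb
        site_center = {s: np.array(p) for s, p in self.site_points.items()}

        def absorb_coef(i_f, j_f, sites, base):
            """Cut-cell correction: the Dirichlet surface is the circle, not
            the staircase of covered cells, so the transfer coefficient uses
            the true distance from the fluid centre to the circle."""
            ctr = np.stack([self.xc[i_f], self.yc[j_f]], axis=1)
            tgt = np.stack([site_center[s] for s in sites])
            d = np.linalg.norm(ctr - tgt, axis=1) - r_b
            d = np.clip(d, 0.25 * h, h)
            return base * (h / d)

        def add_faces(iL, jL, iR, jR, w):
            """Faces oriented L->R with SG weight w = v h / D."""
            L_block = self.blocked[iL, jL]
            R_block = self.blocked[iR, jR]
            L_abs = self.absorb_site[iL, jL]
            R_abs = self.absorb_site[iR, jR]
            L_fluid = ~L_block & (L_abs < 0)
            R_fluid = ~R_block & (R_abs < 0)
            BmW = _bernoulli(-w)
            BpW = _bernoulli(w)
            c = D / h ** 2
            ff = L_fluid & R_fluid
            if ff.any():
                l = self.fluid_index[iL[ff], jL[ff]]
                r = self.fluid_index[iR[ff], jR[ff]]
                bm = BmW[ff] * c
                bp = BpW[ff] * c
                rows.extend([l, l, r, r])
                cols.extend([l, r, r, l])
                vals.extend([bm, -bp, bp, -bm])
            fa = L_fluid & (R_abs >= 0)
            if fa.any():
                l = self.fluid_index[iL[fa], jL[fa]]
                bm = absorb_coef(iL[fa], jL[fa], R_abs[fa], BmW[fa] * c)
                rows.append(l)
                cols.append(l)
                vals.append(bm)
                for lidx, site, coef in zip(l, R_abs[fa], bm * h ** 2):
                    site_rows[site].append((lidx, coef))
            af = (L_abs >= 0) & R_fluid
            if af.any():
                r = self.fluid_index[iR[af], jR[af]]
                bp = absorb_coef(iR[af], jR[af], L_abs[af], BpW[af] * c)
                rows.append(r)
                cols.append(r)
                vals.append(bp)
                for ridx, site, coef in zip(r, L_abs[af], bp * h ** 2):
                    site_rows[site].append((ridx, coef))

        iL, jL = np.meshgrid(np.arange(self.nx - 1), np.arange(self.ny),
                             indexing="ij")
        add_faces(iL, jL, iL + 1, jL, vx * h / D)
        iL, jL = np.meshgrid(np.arange(self.nx), np.arange(self.ny - 1),
                             indexing="ij")
        add_faces(iL, jL, iL, jL + 1, vy * h / D)

        rows = np.concatenate([np.atleast_1d(r) for r in rows])
        cols = np.concatenate([np.atleast_1d(c) for c in cols])
        vals = np.concatenate([np.atleast_1d(v) for v in vals])
        n = self.n_fluid
        self.A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        self.site_flux: Dict[int, sp.csr_matrix] = {}
        for site, entries in site_rows.items():
            if entries:
                idx = np.array([e[0] for e in entries])
                cf = np.array([e[1] for e in entries])
            else:
                idx = np.zeros(0, dtype=int)
                cf = np.zeros(0)
            self.site_flux[site] = sp.csr_matrix(
                (cf, (np.zeros(len(idx), dtype=int), idx)), shape=(1, n))

    def initial_density(self) -> Tuple[np.ndarray, Tuple[float, float]]:
        """Gaussian initial condition restricted to fluid cells, mass 1.

        If the nominal centre falls inside a blocked or absorbing region (an
        obstacle at the forward site), the Gaussian is re-centred at the
        nearest fluid cell.
        """
        par = self.problem.params.diffusion
        cx, cy = self.problem.init_position or par.init_position
        sig = par.init_sigma
        # analytic, grid-independent relocation: project the centre out of
        # any covering obstacle circle to one sigma of clearance
        for _ in range(4):
            moved = False
            for _, ox, oy, R in self.problem.reflector_circles():
                d = math.hypot(cx - ox, cy - oy)
                if d < R + sig:
                    if d < 1e-9:
                        cx, cy = ox - (R + sig), oy
                    else:
                        cx = ox + (cx - ox) * (R + sig) / d
                        cy = oy + (cy - oy) * (R + sig) / d
                    moved = True
            if not moved:
                break
        i = int(np.clip((cx - self.xc[0]) / self.h + 0.5, 0, self.nx - 1))
        j = int(np.clip((cy - self.yc[0]) / self.h + 0.5, 0, self.ny - 1))
        if not self.fluid[i, j]:
            fi, fj = np.nonzero(self.fluid)
            d2 = (self.xc[fi] - cx) ** 2 + (self.yc[fj] - cy) ** 2
            k = int(np.argmin(d2))
            cx, cy = float(self.xc[fi[k]]), float(self.yc[fj[k]])
        g = np.exp(-((self.X - cx) ** 2 + (self.Y - cy) ** 2) / (2 * sig ** 2))
        g[~self.fluid] = 0.0
        tot = g.sum() * self.h ** 2
        if tot <= 0:
            raise GeometryError("initial density has no support in the fluid region")
        return (g / tot)[self.fluid], (cx, cy)


@dataclass
class SplittingSolution:
    """Stationary (time-integrated) solution: binding probabilities + A_int.

    ``a_int`` is the obstacle-contact exposure used by the unbinding model:
    the free head spends the ATP-waiting part of each cycle (~the mean dwell)
    tethered to the bound head by both undocked neck linkers, and A_int is
    the equilibrium line density of that tethered head along the obstacle
    boundary times the dwell.  ``a_int_episode`` is the time-and-line
    integral of the post-power-stroke density over the brief stepping episode
    itself (microseconds); it shares the ms/nm units but is orders of
    magnitude smaller.
    """

    problem: DiffusionProblem
    grid_step: float
    p_b: Dict[int, float]
    a_int: Dict[int, float]          # per occupied neighbour site, ms/nm
    a_int_episode: Dict[int, float]
    u_field: np.ndarray = field(repr=False)   # (nx, ny) time-integrated density, ms/nm²
    init_center: Tuple[float, float] = (6.0, 0.0)
    residual_mass: float = 0.0

    @property
    def total_absorbed(self) -> float:
        return float(sum(self.p_b.values()))


def solve_splitting(problem: DiffusionProblem,
                    grid_step: Optional[float] = None) -> SplittingSolution:
    """Binding probabilities P_b,i and interference integrals A_int.

    Solves the stationary equation for the time-integrated density
    u = ∫₀^∞ p dt and integrates the discrete fluxes through each absorbing
    boundary; total absorbed probability equals 1 to solver precision by
    discrete conservation.
    """
    grid = _Grid(problem, grid_step)
    if not grid.site_points:
        # fully caged head: no absorbing boundary remains; binding never
        # happens and only the waiting-state exposure is defined
        return SplittingSolution(
            problem=problem, grid_step=grid.h, p_b={}, a_int=waiting_interference(problem, grid),
            a_int_episode={}, u_field=np.zeros((grid.nx, grid.ny)),
            init_center=problem.init_position or problem.params.diffusion.init_position,
            residual_mass=1.0)
    p0, center = grid.initial_density()
    u = spla.spsolve(grid.A.tocsc(), p0)
    if not np.all(np.isfinite(u)):
        raise SolverError("stationary solve failed (singular operator)")
    if (u < -1e-9 * max(1.0, u.max())).any():
        raise SolverError("negative time-integrated density")
    p_b = {s: float(op.dot(u)[0]) for s, op in grid.site_flux.items()}
    total = sum(p_b.values())
    if abs(total - 1.0) > 1e-4:
        raise SolverError(f"probability not conserved: sum P_b = {total:.6f}")
    a_episode = {}
    for site, cx, cy, R in problem.reflector_circles():
        a_episode[site] = _boundary_line_integral(grid, u, cx, cy, R)
    a_int = waiting_interference(problem, grid)
    U = np.zeros((grid.nx, grid.ny))
    U[grid.fluid] = u
    return SplittingSolution(
        problem=problem, grid_step=grid.h, p_b=p_b, a_int=a_int,
        a_int_episode=a_episode, u_field=U, init_center=center,
        residual_mass=max(0.0, 1.0 - total))


def waiting_interference(problem: DiffusionProblem,
                         grid: Optional[_Grid] = None) -> Dict[int, float]:
    """Obstacle-contact exposure A_int of the ATP-waiting state (ms/nm).

    While the bound head waits for ATP (mean dwell ~10 ms) its partner head
    is tethered by the two undocked neck linkers in series, anchored at the
    bound site.  The head equilibrates in that tether potential on a
    microsecond timescale, so the contact exposure with each obstacle over
    the cycle is the equilibrium line density along the obstacle boundary
    times the mean dwell.  This is the A_int entering the unbinding model
    (kinesin detaches predominantly from this one-head-bound state).
    """
    circles = problem.reflector_circles()
    if not circles:
        return {}
    from dataclasses import replace as _replace
    par = problem.params
    wlc = par.wlc
    tether = _replace(wlc, n_aa_docked=wlc.n_aa_undocked)
    if grid is None:
        grid = _Grid(problem)
    R_all = np.hypot(grid.X, grid.Y)
    rg = np.linspace(0.0, float(R_all.max()) + 0.5, 4000)
    t, _, _ = neck.radial_tension(rg, tether, allow_unwinding=True)
    t = np.minimum(np.nan_to_num(t, posinf=1e3, nan=1e3), 1e3)
    U = np.concatenate([[0.0], np.cumsum(0.5 * (t[1:] + t[:-1]) * np.diff(rg))])
    Ur = np.interp(R_all, rg, U)
    w = np.exp(-np.clip((Ur - Ur.min()) / wlc.kBT, 0.0, 600.0))
    blocked = np.zeros(w.shape, dtype=bool)
    for _, cx, cy, R in circles:
        blocked |= (grid.X - cx) ** 2 + (grid.Y - cy) ** 2 <= R ** 2
    w[blocked] = 0.0
    z = w.sum() * grid.h ** 2
    if z <= 0:
        raise GeometryError("waiting-state tether has no accessible region")
    pi = w / z
    dwell = par.kinetics.mean_dwell
    out = {}
    n_s = 1440
    th = 2 * math.pi * (np.arange(n_s) + 0.5) / n_s
    for site, cx, cy, R in circles:
        r_s = R + 0.75 * grid.h
        px = cx + r_s * np.cos(th)
        py = cy + r_s * np.sin(th)
        i = np.clip(np.round((px - grid.xc[0]) / grid.h).astype(int), 0, grid.nx - 1)
        j = np.clip(np.round((py - grid.yc[0]) / grid.h).astype(int), 0, grid.ny - 1)
        vals = np.where(blocked[i, j], 0.0, pi[i, j])
        out[site] = float(dwell * vals.mean() * 2 * math.pi * R)
    return out


def _boundary_line_integral(grid: _Grid, u: np.ndarray, cx: float, cy: float,
                            R: float, n_samples: int = 720) -> float:
    """∮ u dl along an obstacle circle (sampled just outside the boundary)."""
    U = np.zeros((grid.nx, grid.ny))
    U[grid.fluid] = u
    th = 2 * math.pi * (np.arange(n_samples) + 0.5) / n_samples
    r_s = R + 0.75 * grid.h
    vals = np.zeros(n_samples)
    for k in range(n_samples):
        for grow in range(6):
            px = cx + (r_s + grow * grid.h) * math.cos(th[k])
            py = cy + (r_s + grow * grid.h) * math.sin(th[k])
            i = int((px - grid.xc[0]) / grid.h + 0.5)
            j = int((py - grid.yc[0]) / grid.h + 0.5)
            i = min(max(i, 0), grid.nx - 1)
            j = min(max(j, 0), grid.ny - 1)
            if grid.fluid[i, j]:
                vals[k] = U[i, j]
                break
    return float(vals.mean() * 2 * math.pi * R)


@dataclass
class DiffusionSolution:
    """Transient solution: snapshots, flux series, residual mass."""

    problem: DiffusionProblem
    grid_step: float
    times: np.ndarray                 # ms
    residual_mass: np.ndarray         # mass remaining at each time
    absorbed_flux: Dict[int, np.ndarray]   # per-site outflow rate, 1/ms
    snapshots: List[np.ndarray] = field(default_factory=list)
    snapshot_times: List[float] = field(default_factory=list)
    init_center: Tuple[float, float] = (6.0, 0.0)

    def absorbed_totals(self) -> Dict[int, float]:
        dt = np.diff(self.times, prepend=0.0)
        return {s: float(np.sum(f * dt)) for s, f in self.absorbed_flux.items()}


def solve_fokker_planck(problem: DiffusionProblem, t_final: float = 0.05,
                        grid_step: Optional[float] = None,
                        time_step: float = 2e-5,
                        snapshot_times: Tuple[float, ...] = (),
                        stop_mass: float = 1e-6) -> DiffusionSolution:
    """Backward-Euler time integration of the Fokker-Planck equation.

    Defaults: t_final 0.05 ms (50 μs) with early stop once the remaining
    mass drops below ``stop_mass``.
    """
    grid = _Grid(problem, grid_step)
    p0, center = grid.initial_density()
    n_steps = max(1, int(round(t_final / time_step)))
    M = (sp.identity(grid.n_fluid, format="csr") / time_step + grid.A).tocsc()
    lu = spla.splu(M)
    p = p0.copy()
    times, masses = [], []
    flux = {s: [] for s in grid.site_flux}
    snaps, snap_ts = [], []
    want = sorted(snapshot_times)
    h2 = grid.h ** 2
    t = 0.0
    for _ in range(n_steps):
        p = lu.solve(p / time_step)
        t += time_step
        times.append(t)
        masses.append(float(p.sum() * h2))
        for s, op in grid.site_flux.items():
            flux[s].append(float(op.dot(p)[0]))
        while want and t >= want[0] - 1e-12:
            U = np.zeros((grid.nx, grid.ny))
            U[grid.fluid] = p
            snaps.append(U)
            snap_ts.append(t)
            want.pop(0)
        if masses[-1] < stop_mass:
            break
    times = np.asarray(times)
    masses = np.asarray(masses)
    sol = DiffusionSolution(
        problem=problem, grid_step=grid.h, times=times, residual_mass=masses,
        absorbed_flux={s: np.asarray(f) for s, f in flux.items()},
        snapshots=snaps, snapshot_times=snap_ts, init_center=center)
    # conservation audit: remaining + absorbed must equal 1
    tot = masses[-1] + sum(sol.absorbed_totals().values())
    if abs(tot - 1.0) > 1e-3:
        raise SolverError(f"mass not conserved in transient solve: {tot:.5f}")
    return sol


@dataclass
class BindingProbabilities:
    """Per-site binding probabilities and the direction aggregates."""

    p_b: Dict[int, float]
    residual: float = 0.0

    @property
    def p_fw(self) -> float:
        return sum(self.p_b.get(i, 0.0) for i in lat.FORWARD_SITES)

    @property
    def p_sd(self) -> float:
        return sum(self.p_b.get(i, 0.0) for i in lat.SIDE_SITES)

    @property
    def p_bw(self) -> float:
        return sum(self.p_b.get(i, 0.0) for i in lat.BACKWARD_SITES)

    def tail_sum(self) -> float:
        """Probability of a large step (sites 9-24 of the extended domain)."""
        return sum(v for i, v in self.p_b.items() if i >= 9)

    def normalized(self) -> "BindingProbabilities":
        tot = sum(self.p_b.values())
        if tot <= 0:
            return BindingProbabilities(p_b={}, residual=self.residual)
        return BindingProbabilities(
            p_b={i: v / tot for i, v in self.p_b.items()}, residual=0.0)


def binding_probabilities(solution) -> BindingProbabilities:
    """Extract P_b,i from a stationary or transient solution."""
    if isinstance(solution, SplittingSolution):
        return BindingProbabilities(p_b=dict(solution.p_b),
                                    residual=solution.residual_mass)
    if isinstance(solution, DiffusionSolution):
        tot = solution.absorbed_totals()
        return BindingProbabilities(p_b=tot,
                                    residual=float(solution.residual_mass[-1]))
    raise TypeError(f"unsupported solution type {type(solution)!r}")


def interference_integral(solution: SplittingSolution, obstacle_site: int) -> float:
    """A_int (ms/nm) along the reflective boundary of one obstacle."""
    if obstacle_site not in solution.a_int:
        raise KeyError(f"no obstacle at site {obstacle_site}")
    return solution.a_int[obstacle_site]


def direction_probabilities_vs_load(load_magnitudes, params: ModelParams,
                                    grid_step: Optional[float] = None):
    """P_fw, P_sd, P_bw for a sweep of resisting loads (toward the minus end)."""
    import pandas as pd
    rows = []
    for load in load_magnitudes:
        if load < 0:
            raise ParameterError("loads must be non-negative")
        prob = assemble_problem(params, cargo_force=(-float(load), 0.0))
        bp = binding_probabilities(solve_splitting(prob, grid_step))
        rows.append({"load_pN": float(load), "P_fw": bp.p_fw,
                     "P_sd": bp.p_sd, "P_bw": bp.p_bw})
    return pd.DataFrame(rows)


def large_step_probabilities(params: ModelParams,
                             grid_step: Optional[float] = None) -> BindingProbabilities:
    """Binding probabilities over the extended 24-site domain."""
    prob = assemble_problem(params, extended=True)
    return binding_probabilities(solve_splitting(prob, grid_step))


try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

if _HAVE_NUMBA:
    @_njit(cache=True)
    def _bd_kernel(pos, Fx, Fy, gx0, gy0, inv_h, nx, ny, mu_dt, sig,
                   cxs, cys, crs2, sx, sy, rb2, xlo, xhi, ylo, yhi,
                   max_steps, seed):
        np.random.seed(seed)
        n = pos.shape[0]
        hit = np.full(n, -1, np.int64)
        n_circ = cxs.shape[0]
        n_site = sx.shape[0]
        for k in range(n):
            x = pos[k, 0]
            y = pos[k, 1]
            done = False
            for _ in range(max_steps):
                fx = (x - gx0) * inv_h
                fy = (y - gy0) * inv_h
                i0 = int(fx)
                j0 = int(fy)
                if i0 < 0:
                    i0 = 0
                if j0 < 0:
                    j0 = 0
                if i0 > nx - 2:
                    i0 = nx - 2
                if j0 > ny - 2:
                    j0 = ny - 2
                ax = fx - i0
                ay = fy - j0
                if ax < 0.0:
                    ax = 0.0
                if ay < 0.0:
                    ay = 0.0
                if ax > 1.0:
                    ax = 1.0
                if ay > 1.0:
                    ay = 1.0
                Fxi = (Fx[i0, j0] * (1 - ax) * (1 - ay)
                       + Fx[i0 + 1, j0] * ax * (1 - ay)
                       + Fx[i0, j0 + 1] * (1 - ax) * ay
                       + Fx[i0 + 1, j0 + 1] * ax * ay)
                Fyi = (Fy[i0, j0] * (1 - ax) * (1 - ay)
                       + Fy[i0 + 1, j0] * ax * (1 - ay)
                       + Fy[i0, j0 + 1] * (1 - ax) * ay
                       + Fy[i0 + 1, j0 + 1] * ax * ay)
                xn = x + Fxi * mu_dt + sig * np.random.normal()
                yn = y + Fyi * mu_dt + sig * np.random.normal()
                # specular reflection at the outer walls
                if xn < xlo:
                    xn = 2 * xlo - xn
                elif xn > xhi:
                    xn = 2 * xhi - xn
                if yn < ylo:
                    yn = 2 * ylo - yn
                elif yn > yhi:
                    yn = 2 * yhi - yn
                # radial reflection off the obstacle circles
                for c in range(n_circ):
                    dxc = xn - cxs[c]
                    dyc = yn - cys[c]
                    r2 = dxc * dxc + dyc * dyc
                    if r2 <= crs2[c]:
                        r = math.sqrt(r2)
                        R = math.sqrt(crs2[c])
                        if r < 1e-9:
                            break
                        rr = (2.0 * R - r) / r
                        xn = cxs[c] + dxc * rr
                        yn = cys[c] + dyc * rr
                        break
                ok = xlo < xn < xhi and ylo < yn < yhi
                if ok:
                    for c in range(n_circ):
                        dxc = xn - cxs[c]
                        dyc = yn - cys[c]
                        if dxc * dxc + dyc * dyc <= crs2[c]:
                            ok = False
                            break
                if ok:
                    x = xn
                    y = yn
                for s in range(n_site):
                    dxs = x - sx[s]
                    dys = y - sy[s]
                    if dxs * dxs + dys * dys <= rb2:
                        hit[k] = s
                        done = True
                        break
                if done:
                    break
        return hit


def brownian_oracle(problem: DiffusionProblem, n_particles: int = 20000,
                    time_step: float = 5e-7, seed: int = 0,
                    field_step: float = 0.125,
                    max_steps: int = 400000) -> Tuple[BindingProbabilities, Dict[int, float]]:
    """Overdamped Langevin particle simulation with the same boundaries.

    Independent check of the PDE solver: particles drift with F/γ, diffuse
    with D, reflect off obstacle circles and walls (rejected moves) and are
    absorbed at the binding circles.  Returns empirical splitting
    probabilities and their binomial standard errors.
    """
    if n_particles < 1:
        raise ParameterError("need at least one particle")
    par = problem.params
    rng = np.random.default_rng(seed)
    ff = neck.tabulate_force_field(problem.domain, field_step,
                                   problem.cargo_force, par)
    D = par.diffusion.D
    gamma = par.diffusion.gamma
    r_b = par.diffusion.r_absorb
    x0, x1, y0, y1 = problem.domain
    sites = problem.absorbing_points()
    site_ids = list(sites)
    centers = np.array([sites[s] for s in site_ids])
    circles = [(cx, cy, R) for _, cx, cy, R in problem.reflector_circles()]

    grid = _Grid(problem,
                 grid_step=min(field_step, par.diffusion.r_absorb / 2))
    _, (cx0, cy0) = grid.initial_density()
    pos = rng.normal([cx0, cy0], par.diffusion.init_sigma, size=(n_particles, 2))
    for cx, cy, R in circles:   # push any unlucky initial draws outside
        d = np.linalg.norm(pos - [cx, cy], axis=1)
        inside = d < R + 1e-9
        if inside.any():
            pos[inside] = [cx, cy] + (pos[inside] - [cx, cy]) * \
                ((R + 1e-6) / d[inside])[:, None]
    alive = np.ones(n_particles, dtype=bool)
    hit = np.full(n_particles, -1, dtype=int)
    sig = math.sqrt(2 * D * time_step)
    if _HAVE_NUMBA:
        cxs = np.array([c[0] for c in circles], dtype=float)
        cys = np.array([c[1] for c in circles], dtype=float)
        crs2 = np.array([c[2] ** 2 for c in circles], dtype=float)
        hit = np.asarray(_bd_kernel(
            pos, ff.Fx, ff.Fy, float(ff.x[0]), float(ff.y[0]),
            1.0 / (ff.x[1] - ff.x[0]), len(ff.x), len(ff.y),
            time_step / gamma, sig, cxs, cys, crs2,
            np.ascontiguousarray(centers[:, 0]),
            np.ascontiguousarray(centers[:, 1]), r_b ** 2,
            x0, x1, y0, y1, max_steps, int(seed) & 0x7FFFFFFF))
        alive = hit < 0
        p_b, se = {}, {}
        for k, s in enumerate(site_ids):
            q = float((hit == k).mean())
            p_b[s] = q
            se[s] = math.sqrt(max(q * (1 - q), 1.0 / n_particles) / n_particles)
        return BindingProbabilities(p_b=p_b, residual=float(alive.mean())), se
    for _ in range(max_steps):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        p = pos[idx]
        F = ff.interpolate(p)
        newp = p + (F / gamma) * time_step + rng.normal(0.0, sig, p.shape)
        ok = (newp[:, 0] > x0) & (newp[:, 0] < x1) & \
             (newp[:, 1] > y0) & (newp[:, 1] < y1)
        for cx, cy, R in circles:
            ok &= (newp[:, 0] - cx) ** 2 + (newp[:, 1] - cy) ** 2 > R ** 2
        p = np.where(ok[:, None], newp, p)
        d2 = ((p[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        closest = np.argmin(d2, axis=1)
        absorbed = d2[np.arange(len(p)), closest] <= r_b ** 2
        hit[idx[absorbed]] = closest[absorbed]
        alive[idx[absorbed]] = False
        pos[idx] = p
    p_b, se = {}, {}
    for k, s in enumerate(site_ids):
        n_k = int((hit == k).sum())
        q = n_k / n_particles
        p_b[s] = q
        se[s] = math.sqrt(max(q * (1 - q), 1.0 / n_particles) / n_particles)
    return BindingProbabilities(p_b=p_b, residual=float(alive.mean())), se
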