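"""Stochastic kinesin walks on lattices with obstacles or other motors.

Each mechanochemical cycle draws an exponential dwell, an unbinding event
(P_ub = P_ub0 + α_obs Σ A_int over the obstacle circles in the current
neighbourhood), and a destination among the accessible neighbour sites with
the splitting probabilities of the Fokker-Planck solve for the local
blocked-site configuration.  Splitting probabilities are precomputed per
blocked-neighbour mask (a StepTable); masks never solved exactly are
approximated by zeroing the blocked destinations of the closest precomputed
entry and renormalising, with per-obstacle interference summed from the
single-obstacle entries.
"""
from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .params import ModelParams, ParameterError
from .lattice import MTLattice, NEIGHBOR_STEPS, build_lattice
from . import diffusion as dfn
from .obstacles import ObstacleSet, UnbindingModel, local_obstacle_config

MaskKey = Tuple[Tuple[int, str], ...]

# mirror map under y -> -y (left/right protofilament swap)
_MIRROR_Y = {1: 3, 2: 2, 3: 1, 4: 5, 5: 4, 6: 8, 7: 7, 8: 6}
# mirror map under x -> -x (plus/minus end swap), for minus-end walkers
_MIRROR_X = {1: 6, 2: 7, 3: 8, 4: 4, 5: 5, 6: 1, 7: 2, 8: 3}


def canonical_mask(mask: Dict[int, str]) -> MaskKey:
    return tuple(sorted(mask.items()))


def _map_mask(mask: Dict[int, str], mapping: Dict[int, int]) -> Dict[int, str]:
    return {mapping[i]: s for i, s in mask.items()}


@dataclass
class StepEntry:
    """Splitting probabilities + interference for one blocked-neighbour mask."""

    p_b: Dict[int, float]
    a_int: Dict[int, float]
    exact: bool = True

    @property
    def total_a_int(self) -> float:
        return sum(self.a_int.values())


@dataclass
class StepTable:
    """Mask -> StepEntry cache backed by the Fokker-Planck solver."""

    params: ModelParams
    load: float = 0.0
    grid_step: Optional[float] = None
    entries: Dict[MaskKey, StepEntry] = field(default_factory=dict)

    def _solve(self, mask: Dict[int, str]) -> StepEntry:
        prob = dfn.assemble_problem(
            self.params, cargo_force=(-self.load, 0.0), blocked=mask)
        sol = dfn.solve_splitting(prob, self.grid_step)
        bp = dfn.binding_probabilities(sol).normalized()
        return StepEntry(p_b=dict(bp.p_b), a_int=dict(sol.a_int), exact=True)

    def ensure(self, mask: Dict[int, str], solve: bool = True) -> StepEntry:
        """Entry for ``mask``; solved exactly (and mirror-cached) on demand."""
        key = canonical_mask(mask)
        if key in self.entries:
            return self.entries[key]
        mirr = _map_mask(mask, _MIRROR_Y)
        mkey = canonical_mask(mirr)
        if mkey in self.entries:
            e = self.entries[mkey]
            ent = StepEntry(
                p_b={_MIRROR_Y[i]: v for i, v in e.p_b.items()},
                a_int={_MIRROR_Y[i]: v for i, v in e.a_int.items()},
                exact=e.exact)
            self.entries[key] = ent
            return ent
        if not solve:
            raise KeyError(f"mask {key} not in step table")
        ent = self._solve(mask)
        self.entries[key] = ent
        return ent

    def lookup(self, mask: Dict[int, str], strict: bool = False) -> StepEntry:
        """Entry for ``mask``; falls back to renormalisation when absent.

        The fallback zeroes the blocked destinations of the empty-mask entry,
        renormalises over the remaining sites, and sums A_int over the
        occupied neighbours from their single-obstacle entries.
        """
        key = canonical_mask(mask)
        if key in self.entries:
            return self.entries[key]
        try:
            return self.ensure(mask, solve=False)
        except KeyError:
            if strict:
                raise
        base = self.entries.get(())
        if base is None:
            raise KeyError("step table has no empty-mask entry to renormalise from")
        p = {i: v for i, v in base.p_b.items() if i not in mask}
        tot = sum(p.values())
        if tot <= 0:
            p = {}
        else:
            p = {i: v / tot for i, v in p.items()}
        a_int: Dict[int, float] = {}
        for site, state in mask.items():
            if state != "occupied":
                continue
            single = self.ensure(_single_obstacle_mask(site), solve=False) \
                if canonical_mask(_single_obstacle_mask(site)) in self.entries \
                else None
            if single is None:
                try:
                    single = self.ensure({site: "occupied"}, solve=False)
                except KeyError:
                    single = None
            a_int[site] = single.a_int.get(site, 0.0) if single else 0.0
        ent = StepEntry(p_b=p, a_int=a_int, exact=False)
        self.entries[key] = ent
        return ent


def _single_obstacle_mask(site: int, orientation: str = "lateral",
                          m_obs: int = 3) -> Dict[int, str]:
    """Blocked-neighbour mask of one m_obs-footprint obstacle anchored at ``site``."""
    dax0, dpf0 = NEIGHBOR_STEPS[site]
    from .obstacles import footprint_offsets
    rev = {v: k for k, v in NEIGHBOR_STEPS.items()}
    mask = {site: "occupied"}
    for dax, dpf in footprint_offsets(m_obs, orientation):
        if (dax, dpf) == (0, 0):
            continue
        tgt = (dax0 + dax, dpf0 + dpf)
        if tgt in rev:
            mask[rev[tgt]] = "excluded"
    return mask


def masks_in_field(obstacles: ObstacleSet) -> List[Dict[int, str]]:
    """Distinct blocked-neighbour masks over all legal standing sites."""
    lat = obstacles.lattice
    state = obstacles.anchor_grid.astype(np.int8) * 2 \
        + obstacles.excluded_grid.astype(np.int8)
    legal = state[:, 1:-1] == 0
    code = np.zeros(legal.shape, dtype=np.int64)
    order = sorted(NEIGHBOR_STEPS)
    for k, idx in enumerate(order):
        dax, dpf = NEIGHBOR_STEPS[idx]
        shifted = np.roll(state, -dpf, axis=0)[:, 1 + dax:state.shape[1] - 1 + dax]
        code += shifted.astype(np.int64) * 3 ** k
    out = []
    for c in np.unique(code[legal]):
        if c == 0:
            out.append({})
            continue
        mask = {}
        cc = int(c)
        for k, idx in enumerate(order):
            s = (cc // 3 ** k) % 3
            if s == 1:
                mask[idx] = "excluded"
            elif s == 2:
                mask[idx] = "occupied"
        out.append(mask)
    return out


def precompute_step_tables(mask_set, params: ModelParams, load: float = 0.0,
                           grid_step: Optional[float] = None,
                           max_exact_blocked: int = 3) -> StepTable:
    """Solve the diffusion problem for every mask (empty mask always included).

    Masks with more than ``max_exact_blocked`` blocked neighbours are left to
    the renormalisation fallback; mirror-symmetric masks share one solve.
    """
    table = StepTable(params=params, load=load, grid_step=grid_step)
    table.ensure({})
    for mask in mask_set:
        if len(mask) <= max_exact_blocked:
            table.ensure(mask)
    return table


@dataclass
class WalkTrajectory:
    """One kinesin walk: step sequence, dwell times, termination cause."""

    sites: List[Tuple[int, int]]       # (protofilament, axial) per step
    times: List[float]                 # ms, cumulative at each arrival
    termination: str                   # unbound | max_steps | lattice_end
    axial_spacing: float = 8.0
    seed: Optional[int] = None

    @property
    def n_steps(self) -> int:
        return len(self.sites) - 1

    @property
    def run_length(self) -> float:
        """Net axial displacement (nm) at termination."""
        return (self.sites[-1][1] - self.sites[0][1]) * self.axial_spacing

    @property
    def duration(self) -> float:
        return self.times[-1] - self.times[0]

    def positions_nm(self) -> np.ndarray:
        return np.array([(s[1] - self.sites[0][1]) * self.axial_spacing
                         for s in self.sites])

    def velocity(self, spatial_resolution: float = 0.0,
                 temporal_resolution: float = 0.0) -> float:
        """Mean velocity (nm/s) from the resolution-filtered position trace."""
        if self.duration <= 0:
            return 0.0
        x = self.positions_nm()
        t = np.asarray(self.times)
        if temporal_resolution > 0:
            tg = np.arange(t[0], t[-1], temporal_resolution)
            if len(tg) < 2:
                tg = np.array([t[0], t[-1]])
            idx = np.searchsorted(t, tg, side="right") - 1
            x = x[np.clip(idx, 0, len(x) - 1)]
            t = tg
        if spatial_resolution > 0:
            x = np.round(x / spatial_resolution) * spatial_resolution
        return (x[-1] - x[0]) / (t[-1] - t[0]) * 1e3


def simulate_walk(lattice: MTLattice, obstacles: Optional[ObstacleSet],
                  table: StepTable, kinetics, seed: int,
                  start: Optional[Tuple[int, int]] = None,
                  unbinding: Optional[UnbindingModel] = None) -> WalkTrajectory:
    """Simulate one kinesin walk until unbinding, max_steps, or the lattice end."""
    rng = np.random.default_rng(seed)
    ub = unbinding or UnbindingModel(p_ub0=kinetics.p_ub0,
                                     alpha_obs=table.params.obstacle.alpha_obs)
    if start is None:
        start = _find_start(lattice, obstacles, rng)
    pf, ax = start
    sites = [(pf, ax)]
    times = [0.0]
    t = 0.0
    termination = "max_steps"
    for _ in range(kinetics.max_steps):
        mask = local_obstacle_config(obstacles, (pf, ax)) if obstacles else {}
        entry = table.lookup(mask)
        t += rng.exponential(kinetics.mean_dwell)
        p_ub = min(1.0, ub.p_ub0 + ub.alpha_obs * entry.total_a_int)
        if rng.random() < p_ub:
            termination = "unbound"
            times.append(t)
            sites.append((pf, ax))
            break
        dest = _draw_destination(entry, rng)
        if dest is None:          # fully caged: wait out the cycle
            times.append(t)
            sites.append((pf, ax))
            continue
        dax, dpf = NEIGHBOR_STEPS[dest]
        pf = (pf + dpf) % lattice.n_protofilaments
        ax = ax + dax
        times.append(t)
        sites.append((pf, ax))
        if ax <= 0 or ax >= lattice.n_axial_sites - 1:
            termination = "lattice_end"
            break
    return WalkTrajectory(sites=sites, times=times, termination=termination,
                          axial_spacing=lattice.axial_spacing, seed=seed)


def _draw_destination(entry: StepEntry, rng) -> Optional[int]:
    items = list(entry.p_b.items())
    tot = sum(v for _, v in items)
    if tot <= 0:
        return None
    r = rng.random() * tot
    acc = 0.0
    for site, v in items:
        acc += v
        if r < acc:
            return site
    return items[-1][0]


def _find_start(lattice: MTLattice, obstacles: Optional[ObstacleSet], rng,
                ax0: int = 2) -> Tuple[int, int]:
    for _ in range(1000):
        pf = int(rng.integers(lattice.n_protofilaments))
        ax = ax0 + int(rng.integers(3))
        if obstacles is None or (not obstacles.anchor_grid[pf, ax]
                                 and not obstacles.excluded_grid[pf, ax]):
            return (pf, ax)
    raise ParameterError("could not place the walker on the lattice")


@dataclass
class EnsembleStats:
    mean_velocity: float       # nm/s
    mean_run_length: float     # nm
    se_velocity: float
    se_run_length: float
    n: int


def ensemble_statistics(trajectories: List[WalkTrajectory], kinetics,
                        bootstrap: int = 200, seed: int = 0) -> EnsembleStats:
    """Experiment-like velocity and run-length estimates with bootstrap SEs.

    Velocities use position traces quantised to the spatial resolution and
    sampled at the temporal resolution; run lengths are net displacements at
    termination.
    """
    if len(trajectories) == 0:
        raise ParameterError("empty ensemble")
    v = np.array([tr.velocity(kinetics.spatial_resolution,
                              kinetics.temporal_resolution)
                  for tr in trajectories])
    rl = np.array([tr.run_length for tr in trajectories])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(v), size=(bootstrap, len(v)))
    bv = v[idx].mean(axis=1)
    brl = rl[idx].mean(axis=1)
    return EnsembleStats(mean_velocity=float(v.mean()),
                         mean_run_length=float(rl.mean()),
                         se_velocity=float(bv.std(ddof=1)),
                         se_run_length=float(brl.std(ddof=1)),
                         n=len(v))


def run_ensemble(params: ModelParams, kinetics, rho: float, n_walkers: int,
                 seed: int, table: Optional[StepTable] = None,
                 n_axial: int = 2000, precompute: bool = True
                 ) -> Tuple[List[WalkTrajectory], StepTable]:
    """Deposit obstacles at ``rho`` and run ``n_walkers`` independent walks.

    Each walker gets a freshly deposited obstacle field (seeded) and an
    independent RNG stream derived from the root seed.
    """
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=2 * n_walkers)
    if table is None:
        table = StepTable(params=params, load=0.0)
        table.ensure({})
    trajs = []
    for w in range(n_walkers):
        lattice = build_lattice(13, 26.5, n_axial, True)
        obstacles = None
        if rho > 0:
            from .obstacles import deposit_at_density
            obstacles = deposit_at_density(
                lattice, params.obstacle.m_obs, rho, int(child_seeds[2 * w]),
                r_obs=params.obstacle.r_obs,
                orientation=params.obstacle.footprint)
            if precompute:
                for mask in masks_in_field(obstacles):
                    if len(mask) <= 3:
                        table.ensure(mask)
        trajs.append(simulate_walk(lattice, obstacles, table, kinetics,
                                   int(child_seeds[2 * w + 1])))
    return trajs, table


# --------------------------------------------------------------------------
# traffic: many motors on one microtubule

@dataclass
class _Motor:
    pf: int
    ax: int
    kind: str          # "tagged" | "immobile" | "plus" | "minus"
    unwrapped: float = 0.0


class _TrafficField:
    """Shared occupancy grids with counted exclusions (footprints may overlap)."""

    def __init__(self, lattice: MTLattice, orientation: str = "lateral"):
        self.lat = lattice
        shape = (lattice.n_protofilaments, lattice.n_axial_sites)
        self.anchor = np.zeros(shape, dtype=np.int16)
        self.excl = np.zeros(shape, dtype=np.int16)
        from .obstacles import footprint_offsets
        self.offsets = footprint_offsets(3, orientation)

    def _cells(self, pf0, ax0):
        npf, nax = self.anchor.shape
        for dax, dpf in self.offsets:
            yield (pf0 + dpf) % npf, (ax0 + dax) % nax, (dax, dpf) == (0, 0)

    def add(self, m: _Motor):
        for pf, ax, is_anchor in self._cells(m.pf, m.ax):
            (self.anchor if is_anchor else self.excl)[pf, ax] += 1

    def remove(self, m: _Motor):
        for pf, ax, is_anchor in self._cells(m.pf, m.ax):
            (self.anchor if is_anchor else self.excl)[pf, ax] -= 1

    def state(self, pf, ax) -> Optional[str]:
        pf %= self.anchor.shape[0]
        ax %= self.anchor.shape[1]
        if self.anchor[pf, ax] > 0:
            return "occupied"
        if self.excl[pf, ax] > 0:
            return "excluded"
        return None

    def mask_around(self, pf0, ax0) -> Dict[int, str]:
        out = {}
        for idx, (dax, dpf) in NEIGHBOR_STEPS.items():
            s = self.state(pf0 + dpf, ax0 + dax)
            if s is not None:
                out[idx] = s
        return out


def simulate_traffic(scenario: str, rho: float, params: ModelParams, kinetics,
                     seed: int, table: Optional[StepTable] = None,
                     n_axial: int = 600, t_max: float = 20000.0
                     ) -> Tuple[float, float, WalkTrajectory]:
    """A tagged kinesin among other motors at molar ratio ``rho``.

    Scenarios: "K+M0" (immobile kinesins), "K+M+" (co-directional walkers),
    "K+M-" (minus-end-directed motors).  All motors carry the 3-site walking
    footprint and exclude each other's binding per the sharing rule; events
    are scheduled on a continuous-time queue with exponential dwells.
    Returns (velocity nm/s, run length nm, tagged trajectory).
    """
    kinds = {"K+M0": "immobile", "K+MPhi": "immobile",
             "K+M+": "plus", "K+M-": "minus"}
    if scenario not in kinds:
        raise ParameterError(f"unknown scenario {scenario!r}")
    other = kinds[scenario]
    rng = np.random.default_rng(seed)
    lattice = build_lattice(13, 26.5, n_axial, True)
    fieldgrid = _TrafficField(lattice, params.obstacle.footprint)
    if table is None:
        table = StepTable(params=params, load=0.0)
        table.ensure({})
    ub = UnbindingModel(p_ub0=kinetics.p_ub0,
                        alpha_obs=params.obstacle.alpha_obs)

    motors: List[_Motor] = []
    n_target = int(round(rho * lattice.n_sites))
    tries = 0
    while len(motors) < n_target and tries < 50 * lattice.n_sites:
        tries += 1
        pf = int(rng.integers(lattice.n_protofilaments))
        ax = int(rng.integers(lattice.n_axial_sites))
        if fieldgrid.state(pf, ax) is None:
            m = _Motor(pf=pf, ax=ax, kind=other)
            fieldgrid.add(m)
            motors.append(m)
    if len(motors) < n_target:
        raise ParameterError(f"cannot place motors at rho={rho} (near saturation)")

    tagged = None
    for _ in range(1000):
        pf = int(rng.integers(lattice.n_protofilaments))
        ax = int(rng.integers(lattice.n_axial_sites))
        if fieldgrid.state(pf, ax) is None:
            tagged = _Motor(pf=pf, ax=ax, kind="tagged")
            fieldgrid.add(tagged)
            break
    if tagged is None:
        raise ParameterError("cannot place the tagged walker")

    active = [tagged] + ([] if other == "immobile" else motors)
    heap = []
    for i, m in enumerate(active):
        heapq.heappush(heap, (rng.exponential(kinetics.mean_dwell), i))
    sites = [(tagged.pf, tagged.ax)]
    times = [0.0]
    termination = "max_steps"
    nax = lattice.n_axial_sites
    while heap:
        t, i = heapq.heappop(heap)
        if t > t_max:
            break
        m = active[i]
        fieldgrid.remove(m)
        mask = fieldgrid.mask_around(m.pf, m.ax)
        if m.kind == "minus":
            mask = _map_mask(mask, _MIRROR_X)
        entry = table.lookup(mask)
        if m.kind == "tagged":
            p_ub = min(1.0, ub.p_ub0 + ub.alpha_obs * entry.total_a_int)
            if rng.random() < p_ub:
                times.append(t)
                sites.append((m.pf, m.ax))
                termination = "unbound"
                fieldgrid.add(m)
                break
        dest = _draw_destination(entry, rng)
        if dest is not None:
            if m.kind == "minus":
                dest = _MIRROR_X[dest]
            dax, dpf = NEIGHBOR_STEPS[dest]
            m.pf = (m.pf + dpf) % lattice.n_protofilaments
            m.ax = (m.ax + dax) % nax
            m.unwrapped += dax * lattice.axial_spacing
            if m.kind == "tagged":
                times.append(t)
                sites.append((m.pf, m.ax))
        fieldgrid.add(m)
        heapq.heappush(heap, (t + rng.exponential(kinetics.mean_dwell), i))

    # rebuild an unwrapped trajectory for the tagged walker
    unwrapped_sites = [sites[0]]
    for k in range(1, len(sites)):
        prev = unwrapped_sites[-1]
        dax = sites[k][1] - sites[k - 1][1]
        if dax > 1:
            dax -= nax
        elif dax < -1:
            dax += nax
        unwrapped_sites.append((sites[k][0], prev[1] + dax))
    traj = WalkTrajectory(sites=unwrapped_sites, times=times,
                          termination=termination,
                          axial_spacing=lattice.axial_spacing, seed=seed)
    v = traj.velocity(kinetics.spatial_resolution, kinetics.temporal_resolution)
    return v, traj.run_length, traj
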