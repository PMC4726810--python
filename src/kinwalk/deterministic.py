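"""Closed-form velocity and run-length predictors.

The deterministic model expresses the obstacle-density dependence as

    V(ρ)  = V0 / (1 + Σ_k a_k ρ^k)
    RL(ρ) = RL0 · [1 / (1 + Σ_k b_k ρ^k)] · V(ρ)/V0

with coefficients fitted to the stochastic model's output (the analytic
mapping from the single-obstacle first-passage analysis to a_k, b_k is not
re-derived here; n_step is exposed so such a mapping can be plugged in).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .params import ModelParams, ParameterError
from .lattice import NEIGHBOR_STEPS
from .obstacles import footprint_offsets
from .stepper import StepTable, canonical_mask


class FittingError(ValueError):
    """Rank-deficient or inconsistent coefficient fit."""


@dataclass
class DeterministicModel:
    """Polynomial obstacle-response model for velocity and run length."""

    v0: float                   # nm/s
    rl0: float                  # nm
    a_k: Sequence[float] = ()   # velocity coefficients, k = 1..k_max
    b_k: Sequence[float] = ()   # run-length coefficients
    residual_v: float = 0.0
    residual_rl: float = 0.0

    def to_dict(self) -> dict:
        return {"V0_nm_s": self.v0, "RL0_nm": self.rl0,
                "a_k": list(self.a_k), "b_k": list(self.b_k)}


def velocity_vs_density(model: DeterministicModel, rho: float) -> float:
    """V(ρ) = V0 / (1 + Σ a_k ρ^k)."""
    if rho < 0:
        raise ParameterError("rho must be non-negative")
    denom = 1.0 + sum(a * rho ** (k + 1) for k, a in enumerate(model.a_k))
    return model.v0 / denom


def runlength_vs_density(model: DeterministicModel, rho: float) -> float:
    """RL(ρ) = RL0 · [1/(1 + Σ b_k ρ^k)] · V(ρ)/V0."""
    if rho < 0:
        raise ParameterError("rho must be non-negative")
    denom = 1.0 + sum(b * rho ** (k + 1) for k, b in enumerate(model.b_k))
    return model.rl0 / denom * (velocity_vs_density(model, rho) / model.v0)


def fit_coefficients(samples_v: Sequence[Tuple[float, float]],
                     samples_rl: Optional[Sequence[Tuple[float, float]]] = None,
                     k_max: int = 2, v0: Optional[float] = None,
                     rl0: Optional[float] = None) -> DeterministicModel:
    """Least-squares fit of the a_k (and optionally b_k) coefficients.

    ``samples_v``: (rho, V) pairs including rho = 0 unless ``v0`` is given.
    The fit is linear in the coefficients: V0/V - 1 = Σ a_k ρ^k.
    """
    if k_max < 1:
        raise FittingError("k_max must be at least 1 (no density dependence otherwise)")
    rho_v = np.array([r for r, _ in samples_v], dtype=float)
    v = np.array([val for _, val in samples_v], dtype=float)
    if v0 is None:
        at0 = rho_v == 0
        if not at0.any():
            raise FittingError("need a rho=0 sample or an explicit V0")
        v0 = float(v[at0].mean())
    sel = rho_v > 0
    if np.unique(rho_v[sel]).size < k_max:
        raise FittingError("need at least k_max distinct non-zero densities")

    def poly_fit(rho, y):
        X = np.stack([rho ** (k + 1) for k in range(k_max)], axis=1)
        if np.linalg.matrix_rank(X) < k_max:
            raise FittingError("rank-deficient design matrix")
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ coef
        return coef, float(np.sqrt(np.mean((pred - y) ** 2)))

    a_k, res_v = poly_fit(rho_v[sel], v0 / v[sel] - 1.0)
    model = DeterministicModel(v0=v0, rl0=rl0 if rl0 is not None else 0.0,
                               a_k=tuple(a_k), residual_v=res_v)
    if samples_rl is not None:
        rho_r = np.array([r for r, _ in samples_rl], dtype=float)
        rl = np.array([val for _, val in samples_rl], dtype=float)
        if rl0 is None:
            at0 = rho_r == 0
            if not at0.any():
                raise FittingError("need a rho=0 sample or an explicit RL0")
            rl0 = float(rl[at0].mean())
        selr = rho_r > 0
        vr = np.array([velocity_vs_density(model, r) for r in rho_r[selr]])
        y = rl0 * (vr / v0) / rl[selr] - 1.0
        b_k, res_rl = poly_fit(rho_r[selr], y)
        model = DeterministicModel(v0=v0, rl0=rl0, a_k=tuple(a_k),
                                   b_k=tuple(b_k), residual_v=res_v,
                                   residual_rl=res_rl)
    return model


# --------------------------------------------------------------------------
# first-passage analysis: mean steps to advance past an obstacle

class DivergenceError(RuntimeError):
    """The walker cannot reach the target row (trapped)."""


def mean_steps_to_advance(table: StepTable,
                          obstacle: Optional[Tuple[int, str]] = None,
                          n_rows: int = 1,
                          start: Tuple[int, int] = (0, 0),
                          window: Tuple[int, int, int] = (-12, 8, 8)) -> float:
    """Expected number of steps for a net axial advance of ``n_rows`` sites.

    First-passage analysis on the lattice Markov chain induced by the step
    table.  ``obstacle`` = (m_obs, orientation) places a single obstacle with
    its anchor one row ahead of the origin on the walker's protofilament;
    sites inside its footprint cannot be visited.  The walk starts at
    ``start`` (relative (axial, protofilament)) and is absorbed at axial row
    ``start[0] + n_rows``.  Beyond ``window`` the obstacle is out of range and
    the empty-mask entry applies; walkers leaving the lateral or rear window
    edge are re-entered at the edge (the forward bias makes this correction
    negligible).
    """
    ax_lo, ax_hi_pf, pf_w = window
    target = start[0] + n_rows
    foot = set()
    if obstacle is not None:
        m_obs, orientation = obstacle
        for dax, dpf in footprint_offsets(m_obs, orientation):
            foot.add((1 + dax, dpf))

    # the walker is already bound at its start site when the obstacle is
    # characterised, so the start is a state even when the footprint covers
    # it; the footprint still forbids rebinding there after leaving
    states = [(ax, pf) for ax in range(ax_lo, target)
              for pf in range(-pf_w, pf_w + 1) if (ax, pf) not in foot]
    if tuple(start) in foot:
        states.append(tuple(start))
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    A = np.eye(n)
    rhs = np.ones(n)

    for (ax, pf), i in index.items():
        mask = {}
        for idx, (dax, dpf) in NEIGHBOR_STEPS.items():
            if (ax + dax, pf + dpf) in foot:
                # anchor is the only occupied member of the footprint
                mask[idx] = "occupied" if (ax + dax, pf + dpf) == (1, 0) \
                    else "excluded"
        try:
            entry = table.ensure(mask)
        except Exception:
            entry = table.lookup(mask)
        tot = sum(entry.p_b.values())
        if tot <= 0:
            raise DivergenceError(f"walker trapped at {(ax, pf)}")
        for idx, p in entry.p_b.items():
            if p <= 0:
                continue
            dax, dpf = NEIGHBOR_STEPS[idx]
            nxt = (ax + dax, pf + dpf)
            if nxt[0] >= target:
                continue   # absorbed
            # clamp at the window edges
            nxt = (max(nxt[0], ax_lo),
                   min(max(nxt[1], -pf_w), pf_w))
            if nxt in foot:
                nxt = (ax, pf)
            A[i, index[nxt]] -= p / tot
    try:
        T = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise DivergenceError("first-passage system singular") from exc
    if not np.isfinite(T[index[tuple(start)]]) or T[index[tuple(start)]] < 0:
        raise DivergenceError("no forward-reachable path")
    return float(T[index[tuple(start)]])


def n_step_vs_mobs(table: StepTable, m_values: Sequence[int] = (1, 3, 5, 9),
                   orientation: str = "lateral") -> Dict[int, float]:
    """Mean steps to clear a single obstacle ahead, per footprint class.

    The walker approaches along the obstacle's protofilament from the nearest
    site its bound head may legally occupy (larger footprints push it further
    back) and must reach the first row fully past the footprint.  Larger
    obstacles both lengthen the required advance and block more of the
    detour, so n_step grows steeply with m_obs.
    """
    out = {}
    for m in m_values:
        foot = {(1 + dax, dpf) for dax, dpf in footprint_offsets(m, orientation)}
        s = 0
        while (s, 0) in foot:
            s -= 1
        target_row = max(ax for ax, _ in foot) + 1
        out[m] = mean_steps_to_advance(table, obstacle=(m, orientation),
                                       n_rows=target_row - s, start=(s, 0))
    return out
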