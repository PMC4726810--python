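"""Microtubule binding-site lattice and local neighbour geometry.

Coordinate convention: x = MT axis toward the plus end, y = tangential
direction, origin at the fixed head's bound site; all positions in nm.  Only
β-tubulin sites are represented (the kinesin head binds β-tubulin only).

Neighbour numbering around a bound head follows the step diagram used
throughout the model: (1)(2)(3) the rear row (left, centre, right), (4)(5)
the side sites, (6)(7)(8) the front row, where "left" is +y.  The extended
24-site problem adds indices (9)-(24) on the outer ring of the 5×5 block of
sites, row-major from the rear-left corner.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .params import HeadGeometry, LatticeParams, ParameterError


class BoundaryError(ValueError):
    """Anchor too close to the lattice edge."""


# neighbour index -> (axial step, protofilament step); pf +1 is the left (+y) side
NEIGHBOR_STEPS: Dict[int, Tuple[int, int]] = {
    1: (-1, +1), 2: (-1, 0), 3: (-1, -1),
    4: (0, +1), 5: (0, -1),
    6: (+1, +1), 7: (+1, 0), 8: (+1, -1),
}
FORWARD_SITES = (6, 7, 8)
SIDE_SITES = (4, 5)
BACKWARD_SITES = (1, 2, 3)
DIAGONAL_SITES = (1, 3, 6, 8)


@dataclass
class MTLattice:
    """2D array of β-tubulin binding sites with helical mismatch.

    ``occupancy`` codes: 0 free, 1 obstacle anchor, 2 motor-bound,
    3 excluded (covered by a diffusing head's footprint, not bindable).
    """

    n_protofilaments: int
    diameter: float
    axial_spacing: float
    lateral_spacing: float
    stagger: float
    n_axial_sites: int
    helical: bool
    right_diagonal_near: bool = True
    occupancy: np.ndarray = field(default=None, repr=False)  # (n_pf, n_axial) uint8

    def __post_init__(self) -> None:
        if self.occupancy is None:
            self.occupancy = np.zeros(
                (self.n_protofilaments, self.n_axial_sites), dtype=np.uint8)

    @property
    def n_sites(self) -> int:
        return self.n_protofilaments * self.n_axial_sites

    @property
    def pf_shift(self) -> float:
        """Axial shift per protofilament (stagger/n_pf), signed by handedness."""
        if not self.helical:
            return 0.0
        s = self.stagger / self.n_protofilaments
        # right_diagonal_near: the right (-y) protofilament sits further back,
        # so its forward diagonal is nearer; equivalently +y protofilaments
        # are shifted forward.
        return s if self.right_diagonal_near else -s

    def site_position(self, pf: int, axial: int) -> Tuple[float, float]:
        """Position of site (protofilament, axial index) in the lattice frame."""
        x = axial * self.axial_spacing + pf * self.pf_shift
        y = pf * self.lateral_spacing
        return (x, y)

    def site_id(self, pf: int, axial: int) -> int:
        return pf * self.n_axial_sites + axial

    def site_from_id(self, sid: int) -> Tuple[int, int]:
        return divmod(sid, self.n_axial_sites)[0], sid % self.n_axial_sites

    def to_json(self) -> str:
        occ = self.occupancy.ravel()
        # run-length encode occupancy
        changes = np.flatnonzero(np.diff(occ)) + 1
        starts = np.concatenate(([0], changes))
        lengths = np.diff(np.concatenate((starts, [occ.size])))
        rle = [[int(occ[s]), int(n)] for s, n in zip(starts, lengths)]
        return json.dumps({
            "n_protofilaments": self.n_protofilaments,
            "diameter_nm": self.diameter,
            "axial_spacing_nm": self.axial_spacing,
            "lateral_spacing_nm": self.lateral_spacing,
            "stagger_nm": self.stagger,
            "n_axial_sites": self.n_axial_sites,
            "helical": self.helical,
            "right_diagonal_near": self.right_diagonal_near,
            "occupancy_rle": rle,
        })

    @classmethod
    def from_json(cls, text: str) -> "MTLattice":
        d = json.loads(text)
        occ = np.concatenate([
            np.full(n, v, dtype=np.uint8) for v, n in d["occupancy_rle"]
        ]) if d["occupancy_rle"] else np.zeros(0, dtype=np.uint8)
        lat = cls(
            n_protofilaments=d["n_protofilaments"], diameter=d["diameter_nm"],
            axial_spacing=d["axial_spacing_nm"],
            lateral_spacing=d["lateral_spacing_nm"], stagger=d["stagger_nm"],
            n_axial_sites=d["n_axial_sites"], helical=d["helical"],
            right_diagonal_near=d["right_diagonal_near"],
        )
        lat.occupancy = occ.reshape(lat.n_protofilaments, lat.n_axial_sites)
        return lat

    def site_table(self) -> pd.DataFrame:
        """All sites as a DataFrame (site_id, protofilament, axial_index, x_nm, y_nm, state)."""
        pf, ax = np.meshgrid(np.arange(self.n_protofilaments),
                             np.arange(self.n_axial_sites), indexing="ij")
        x = ax * self.axial_spacing + pf * self.pf_shift
        y = pf * self.lateral_spacing
        return pd.DataFrame({
            "site_id": pf.ravel() * self.n_axial_sites + ax.ravel(),
            "protofilament": pf.ravel(), "axial_index": ax.ravel(),
            "x_nm": x.ravel(), "y_nm": y.ravel(),
            "state": self.occupancy.ravel(),
        })


def build_lattice(n_protofilaments: int = 13, diameter: float = 26.5,
                  n_axial_sites: int = 100, helical: bool = True,
                  axial_spacing: float = 8.0, stagger: float = 8.0,
                  right_diagonal_near: bool = True) -> MTLattice:
    """Build the β-tubulin binding-site lattice.

    The lateral spacing is derived from the circumference,
    d_side = π·diameter/n_protofilaments (6.4 nm for 13 protofilaments on a
    26.5 nm microtubule).  ``helical=True`` applies the per-protofilament
    axial shift stagger/n_protofilaments; ``helical=False`` gives the square
    lattice without mismatch.
    """
    if n_protofilaments < 3 or n_axial_sites < 3:
        raise ParameterError("need at least 3 protofilaments and 3 axial sites")
    if diameter <= 0 or axial_spacing <= 0:
        raise ParameterError("dimensions must be positive")
    lateral = math.pi * diameter / n_protofilaments
    return MTLattice(
        n_protofilaments=n_protofilaments, diameter=diameter,
        axial_spacing=axial_spacing, lateral_spacing=lateral, stagger=stagger,
        n_axial_sites=n_axial_sites, helical=helical,
        right_diagonal_near=right_diagonal_near,
    )


def lattice_mismatch_angle(diameter: float, stagger: float) -> float:
    """Helical mismatch angle in degrees: atan(stagger / (π·diameter)).

    (26.5 nm, 8 nm) gives the 13-protofilament value of 5.49°.
    """
    if diameter <= 0:
        raise ParameterError("diameter must be positive")
    return math.degrees(math.atan2(stagger, math.pi * diameter))


def neighbor_site_positions(lattice: MTLattice, anchor: int) -> Dict[int, Tuple[float, float]]:
    """Positions of the 8 neighbouring sites relative to the anchor site.

    Returned in the fixed-head frame (anchor at the origin).  Raises
    BoundaryError if the anchor is not interior.
    """
    pf, ax = lattice.site_from_id(anchor)
    missing = []
    for idx, (dax, dpf) in NEIGHBOR_STEPS.items():
        if not (0 <= ax + dax < lattice.n_axial_sites):
            missing.append(idx)
        # protofilaments wrap around the cylinder, so no lateral edge
    if missing:
        raise BoundaryError(f"anchor has no neighbours {missing}")
    x0, y0 = lattice.site_position(pf, ax)
    out = {}
    for idx, (dax, dpf) in NEIGHBOR_STEPS.items():
        x = (ax + dax) * lattice.axial_spacing + (pf + dpf) * lattice.pf_shift
        y = (pf + dpf) * lattice.lateral_spacing
        out[idx] = (x - x0, y - y0)
    return out


def neighbor_positions_local(d_side: float = 6.4, axial_spacing: float = 8.0,
                             helical: bool = False, pf_shift: float = 8.0 / 13.0,
                             right_diagonal_near: bool = True) -> Dict[int, Tuple[float, float]]:
    """Local 8-neighbour geometry used by the diffusion domain.

    The default diffusion problem uses the square (non-helical) geometry, which
    keeps the left/right mirror symmetry observed experimentally; set
    ``helical=True`` to include the lattice-mismatch shift.
    """
    shift = 0.0 if not helical else (pf_shift if right_diagonal_near else -pf_shift)
    out = {}
    for idx, (dax, dpf) in NEIGHBOR_STEPS.items():
        out[idx] = (dax * axial_spacing + dpf * shift, dpf * d_side)
    return out


def extended_positions_local(d_side: float = 6.4, axial_spacing: float = 8.0
                             ) -> Dict[int, Tuple[float, float]]:
    """24-neighbour geometry: the 8 inner sites plus the outer ring (9)-(24).

    Outer-ring indices run row-major over the boundary of the 5×5 site block
    centred on the fixed head, starting at the rear-left corner.
    """
    out = neighbor_positions_local(d_side, axial_spacing, helical=False)
    idx = 9
    for dax in (-2, -1, 0, 1, 2):
        for dpf in (2, 1, 0, -1, -2):
            if max(abs(dax), abs(dpf)) < 2:
                continue
            out[idx] = (dax * axial_spacing, dpf * d_side)
            idx += 1
    return out


def _rotate(v: Tuple[float, float], deg: float) -> Tuple[float, float]:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return (v[0] * c - v[1] * s, v[0] * s + v[1] * c)


def tilted_binding_offset(geom: HeadGeometry, theta_d: float,
                          diagonal_position: Tuple[float, float]
                          ) -> Tuple[Tuple[float, float], float]:
    """Absorbing position for a diagonal site under tilted-posture binding.

    The geometric centre of the binding amino acids is placed at the diagonal
    site; the head is rotated about that centre by ``theta_d`` so that AA 324
    swings toward the fixed head.  Returns the resulting AA-324 position (the
    absorbing point, in the fixed-head frame) and the fractional change of its
    distance from the fixed head's bound site relative to theta_d = 0
    (negative = closer; -0.147 at the default 47°).

    Tilting applies only to the four diagonal sites: near the forward, side
    and backward sites the fixed head leaves no room for the free head to
    tilt.
    """
    if not (0.0 <= theta_d < 90.0):
        raise ParameterError("theta_d must lie in [0, 90) degrees")
    sx, sy = diagonal_position
    if abs(sx) < 1e-9 or abs(sy) < 1e-9:
        raise ParameterError(
            "tilted binding applies only to diagonal sites; got a site on an axis")
    ox, oy = geom.aa324_offset
    sgx, sgy = math.copysign(1.0, sx), math.copysign(1.0, sy)
    v0 = (-ox * sgx, oy * sgy)  # AA-324 offset for the untilted bound posture
    p0 = (sx + v0[0], sy + v0[1])
    # rotation sense: AA 324 moves toward the fixed head (mirror per quadrant)
    vr = _rotate(v0, sgx * sgy * theta_d)
    p = (sx + vr[0], sy + vr[1])
    d0 = math.hypot(*p0)
    d = math.hypot(*p)
    return p, (d - d0) / d0


def absorbing_positions(params: LatticeParams, geom: HeadGeometry,
                        tilted: bool = True, theta_d: float | None = None,
                        extended: bool = False,
                        helical: bool = False) -> Dict[int, Tuple[float, float]]:
    """Absorbing-point map for the diffusion problem.

    When ``tilted``, each diagonal site (1, 3, 6, 8) absorbs at a point pulled
    toward the fixed head along the head-to-site direction by the fractional
    distance reduction of the tilted binding posture (14.7% at the default
    47°, from :func:`tilted_binding_offset`); all other sites absorb at their
    geometric positions.
    """
    theta = geom.theta_d if theta_d is None else theta_d
    if extended:
        pos = extended_positions_local(params.d_side, params.axial_spacing)
    else:
        pos = neighbor_positions_local(
            params.d_side, params.axial_spacing, helical=helical,
            pf_shift=params.stagger / params.n_protofilaments,
            right_diagonal_near=params.right_diagonal_near)
    if tilted:
        for idx in DIAGONAL_SITES:
            _, frac = tilted_binding_offset(geom, theta, pos[idx])
            sx, sy = pos[idx]
            pos[idx] = (sx * (1.0 + frac), sy * (1.0 + frac))
    return pos
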