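"""Model parameters and physical constants.

Internal unit system: nm, ms, pN (so energies are pN·nm and k_B T = 4.141 pN·nm
at 300 K, diffusivities are nm²/ms).  Conversions happen only at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Tuple

KB = 1.380649e-2  # pN·nm/K  (Boltzmann constant in internal units)


class ParameterError(ValueError):
    """Invalid physical or geometric parameter."""


@dataclass(frozen=True)
class WLCParams:
    """Worm-like-chain neck linkers and the coiled-coil neck.

    The two neck linkers (NLs) of kinesin-1 are modelled as worm-like chains
    with persistence length ``lp`` and per-amino-acid contour ``la``.  The
    undocked NL has ``n_aa_undocked`` free amino acids, the docked one
    ``n_aa_docked`` (AA 334 is bound to the fixed head).  Each unwound turn of
    the coiled-coil neck releases ``aa_per_turn`` amino acids into *each* NL;
    a turn unwinds when the coil tension reaches ``unwind_force``.
    """

    kBT: float = 4.141          # pN·nm at 300 K
    temperature: float = 300.0  # K
    lp: float = 0.6             # nm, persistence length
    la: float = 0.4             # nm, contour length per amino acid
    n_aa_undocked: int = 14     # AA 325-338 (kinesin-1); 17 for kinesin-2
    n_aa_docked: int = 4        # AA 335-338
    aa_per_turn: float = 3.5    # amino acids released per NL per unwound turn
    unwind_force: float = 10.0  # pN per turn
    max_turns: int = 10         # the neck is coiled for about 10 turns
    ell_dc: float = 2.9         # nm, AA324-AA334 distance of the docked NL

    def __post_init__(self) -> None:
        if self.lp <= 0 or self.la <= 0:
            raise ParameterError("persistence and contour lengths must be positive")
        if self.max_turns < 0 or self.unwind_force <= 0:
            raise ParameterError("invalid coiled-coil parameters")

    @property
    def docked_anchor(self) -> Tuple[float, float]:
        """Anchor point of the docked NL: AA 334 of the fixed head, (ell_dc, 0)."""
        return (self.ell_dc, 0.0)


@dataclass(frozen=True)
class HeadGeometry:
    """Rigid-body geometry of a kinesin head near a binding site.

    ``aa324_offset`` is the position of AA 324 (the NL attachment) relative to
    the geometric centre of the MT-binding amino acids, in the head's own
    frame: 0.9 nm axial, 1.8 nm tangential.
    """

    head_length: float = 7.0    # nm
    head_diameter: float = 4.5  # nm
    aa324_offset: Tuple[float, float] = (0.9, 1.8)  # nm (axial, tangential)
    theta_d: float = 47.0       # deg, allowable tilt when binding diagonally
    ell_dc: float = 2.9         # nm

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_d < 90.0):
            raise ParameterError("theta_d must lie in [0, 90) degrees")


@dataclass(frozen=True)
class LatticeParams:
    """Microtubule binding-site lattice geometry (β-tubulin sites only)."""

    n_protofilaments: int = 13
    diameter: float = 26.5      # nm
    axial_spacing: float = 8.0  # nm, tubulin-dimer repeat
    d_side: float = 6.4         # nm, tangential spacing used in the diffusion domain
    stagger: float = 8.0        # nm, total axial offset per full helical turn
    helical: bool = True
    right_diagonal_near: bool = True  # which diagonal is the 9.77 nm one


@dataclass(frozen=True)
class DiffusionParams:
    """Free-head diffusion and solver settings."""

    D: float = 73600.0            # nm²/ms (= 73.6 μm²/s)
    gamma: float = 5.625e-5       # pN·ms/nm (= 5.625e-8 g/s)
    r_absorb: float = 0.5         # nm, radius of each absorbing binding boundary
    grid_step: float = 0.125      # nm
    domain_8: Tuple[float, float, float, float] = (-12.0, 12.0, -10.0, 10.0)
    domain_24: Tuple[float, float, float, float] = (-20.0, 20.0, -16.0, 16.0)
    init_position: Tuple[float, float] = (6.0, 0.0)  # nm, post-power-stroke
    init_sigma: float = 0.5       # nm, width of the initial Gaussian
    allow_unwinding: bool = True  # U_on / U_off
    allow_tilted_binding: bool = True  # T_on / T_off


@dataclass(frozen=True)
class ObstacleParams:
    """Obstacle footprint, blocked region and unbinding coupling."""

    m_obs: int = 3             # sites per obstacle footprint (1|3|5|9)
    r_obs: float = 5.0         # nm, radius of the reflective blocked region
    alpha_obs: float = 0.044   # nm/ms, unbinding per unit interference integral
    footprint: str = "lateral"  # orientation of the 3-site footprint


@dataclass(frozen=True)
class KineticsParams:
    """Stepping kinetics and experiment-like estimator resolutions."""

    mean_dwell: float = 10.0       # ms per mechanochemical cycle at high [ATP]
    p_ub0: float = 0.008           # unbinding probability per step, no obstacles
    max_steps: int = 100000
    spatial_resolution: float = 8.0   # nm
    temporal_resolution: float = 33.0  # ms

    def __post_init__(self) -> None:
        if self.mean_dwell <= 0:
            raise ParameterError("mean_dwell must be positive")
        if not 0.0 <= self.p_ub0 <= 1.0:
            raise ParameterError("p_ub0 must be a probability")


@dataclass(frozen=True)
class ModelParams:
    """Aggregate parameter set for the full model."""

    wlc: WLCParams = field(default_factory=WLCParams)
    geom: HeadGeometry = field(default_factory=HeadGeometry)
    lattice: LatticeParams = field(default_factory=LatticeParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    obstacle: ObstacleParams = field(default_factory=ObstacleParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)

    def __post_init__(self) -> None:
        # Einstein relation must hold to 0.5%
        if abs(self.diffusion.D * self.diffusion.gamma / self.wlc.kBT - 1.0) > 5e-3:
            raise ParameterError("D·gamma must equal k_B·T within 0.5%")

    def with_naa(self, n_aa_undocked: int) -> "ModelParams":
        """Variant with a different undocked-NL length (17 for kinesin-2)."""
        return replace(self, wlc=replace(self.wlc, n_aa_undocked=n_aa_undocked))

    def with_variants(self, allow_unwinding: bool | None = None,
                      allow_tilted_binding: bool | None = None) -> "ModelParams":
        d = self.diffusion
        if allow_unwinding is not None:
            d = replace(d, allow_unwinding=allow_unwinding)
        if allow_tilted_binding is not None:
            d = replace(d, allow_tilted_binding=allow_tilted_binding)
        return replace(self, diffusion=d)

    def to_dict(self) -> dict:
        return asdict(self)


def einstein_diffusivity(gamma: float, temperature: float = 300.0) -> float:
    """Diffusion coefficient D = k_B T / γ in nm²/ms.

    With the printed drag coefficient γ = 5.625e-5 pN·ms/nm (5.625e-8 g/s)
    at 300 K this evaluates to 73.6 μm²/s.
    """
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    return KB * temperature / gamma


DEFAULT_PARAMS = ModelParams()
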