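# Model and methods

`kinwalk` models the two-dimensional stepping of kinesin-1 on the outer
surface of a microtubule (MT). One head is bound ("fixed"); the other
("free") diffuses under the elastic forces of the two neck linkers (NLs)
until it is absorbed at one of the neighbouring β-tubulin binding sites. The
direction statistics of that diffusion, combined with a per-cycle unbinding
probability, generate full walks whose velocity and run length respond to
obstacles on the lattice.

All internal units are nm, ms, pN; k_B T = 4.141 pN·nm at 300 K.

## Geometry

The MT surface is unrolled into a plane: x along the axis toward the plus
end, y tangential, origin at the fixed head's bound site. β-tubulin sites
form a lattice with 8 nm axial repeat and d_side = π·26.5/13 ≈ 6.4 nm
lateral spacing; the helical mismatch (8 nm of stagger per turn, i.e.
8/13 nm per protofilament, mismatch angle atan(8/26.5π) ≈ 5.49°) makes the
two forward diagonal neighbours 10.73 and 9.77 nm away instead of 10.25 nm.
Because this ~5% asymmetry is within the experimental symmetry of left/right
stepping, the diffusion domain uses the symmetric (square) neighbour
geometry by default; the helical positions are available via a flag.

The eight neighbours are numbered (1)(2)(3) rear row, (4)(5) sides,
(6)(7)(8) front row, "left" being +y. The extended 24-site problem adds the
outer ring of the 5×5 site block.

**Tilted binding.** AA 324 (the NL attachment) sits (0.9, 1.8) nm from the
geometric centre of a head's MT-binding residues. When the free head binds a
diagonal site it can tilt by up to θ_d = 47° about that centre, which
shortens the head-to-site distance by 14.7%; rotating the printed offsets
reproduces this number (the code computes 14.79%, the difference being the
rounding of the printed offsets). The diagonal absorbing points are placed
along the fixed-head-to-site ray at that reduced distance. This ray-scaled
construction — rather than the raw rotated AA-324 position — is what
reproduces the published binding-probability table; both constructions are
implemented (`tilted_binding_offset` exposes the rotation geometry).
Tilting applies only to the four diagonal sites; at the forward, side and
rear sites the fixed head leaves no room to tilt.

## Neck-linker mechanics

Each NL is a worm-like chain, F = (k_B T/ℓ_p)[¼(1−ℓ/ℓ_c)⁻² + ℓ/ℓ_c − ¼],
with ℓ_p = 0.6 nm and ℓ_c = N_AA·0.4 nm. The undocked NL (14 AA for
kinesin-1, 17 for kinesin-2) runs from the free head's AA 324 to the neck;
the docked NL (4 free AA) runs from the neck to AA 334 of the fixed head at
(ℓ_DC, 0) = (2.9, 0). For a given head position the neck settles where the
two NL tensions and the cargo force sum to zero (damped Newton on the 2×2
force balance, residual < 1e−6 pN, with an energy-minimisation fallback for
degenerate geometries). The force on the head is the undocked-NL tension;
with no cargo force it is radial about (ℓ_DC, 0), which the implementation
exploits with a fast 1D tension table.

**Coiled-coil unwinding.** The neck coil (~10 turns) unwinds a turn whenever
the coil tension reaches 10 pN, adding 3.5 AA to each NL's contour; the
force-extension relation is identical on release, so the field is
single-valued in head position. The coil is treated as a moment-free member
whose axis aligns with F_UDNL − F_DCNL; with the cargo force applied at its
centre the tension is piecewise constant along the coil, the loaded half
seeing ½|F₁−F₂| + ½|F_c·û| and the other half ½|F₁−F₂| − ½|F_c·û|. The
first ~max_turns/2 turns therefore unwind at the larger end tension, the
rest at the smaller. This choice matters only under load: it sets the stall
behaviour (forward/backward parity near 7 pN). The coil anchor geometry is
not fully specified by the source material; this two-end-tension reading is
the package's own mechanical closure, and it produces a forward/backward
ratio of ≈1.1 at 7 pN on the finest grid used (published calibration: ≈1.3).

## Head diffusion

The free-head density obeys the Fokker-Planck equation with D = 73,600
nm²/ms (73.6 μm²/s, equal to k_B T/γ for the printed drag γ = 5.625e−8 g/s)
and drift F/γ. Binding sites are absorbing circles of radius r_b = 0.5 nm
(the source gives no boundary size; sensitivity is part of the convergence
study below), obstacles are reflective circles of radius R_obs, and the
outer walls of the domain (x ∈ [−12, 12], y ∈ [−10, 10] nm for the 8-site
problem; [−20, 20]×[−16, 16] for 24 sites) are reflective. The initial
condition is an isotropic Gaussian (σ = 0.5 nm) at the post-power-stroke
position (6, 0) nm; if an obstacle covers it, the centre is projected out of
the blocked circle to one σ of clearance along the line to the nominal
centre (an analytic, grid-independent rule).

When an obstacle stands at the forward site, the tilted absorbing point of
the adjacent diagonals would sit only 0.08 nm from its blocked region — the
tilt swing has no room, by the same steric argument that denies tilting at
the non-diagonal sites. Diagonals therefore fall back to their untilted
absorbing position whenever the tilted point has less than r_b + 0.25 nm of
clearance from an occupied circle; without this rule the splitting
probabilities of the obstructed problem depend on an unresolvable
near-tangency and the PDE and particle solvers converge to different
answers.

**Discretisation.** Cell-centred finite volumes with Scharfetter-Gummel
(exponentially fitted) face fluxes, which stay stable and strictly
conservative at the local Péclet numbers produced by stretched NLs. Binding
probabilities are read from the time-integrated density u = ∫₀^∞ p dt, which
satisfies the stationary system L u = −p₀; total absorbed probability then
equals 1 to solver precision with no time-truncation error. A backward-Euler
transient solver provides density snapshots, per-site flux series and the
residual-mass audit (|1 − mass − absorbed| < 1e−4 enforced).

Absorbing circles are imposed by marking cells inside r_b − h/4 and scaling
each absorbing-face coefficient by h/d, d being the true distance from the
fluid cell centre to the circle; this cut-cell correction pins the Dirichlet
surface to the analytic circle and removes the staircase rattle that
otherwise makes the small splitting probabilities oscillate under grid
refinement. With it, halving the production grid step (0.125 nm → 0.0625 nm)
changes each main P_b by < 2% (0.16% forward, ~1.2% diagonal, ~0.9% side).
An overdamped Langevin simulation with the same boundaries
(`brownian_oracle`, a compiled per-particle kernel with specular wall
reflection) provides an independent Monte-Carlo check. Its Euler-Maruyama
boundary-layer bias shrinks linearly with the time step (verified by
dt-halving); at the time steps used, the PDE and particle estimates agree
within 3 binomial standard errors plus that first-order bias allowance on
the unobstructed, obstructed and 7 pN-loaded problems.

The grid steps used by the shipped runs: 0.125 nm for all zero-load solves
(31k cells), 1/12 nm for the 7 pN load solve (where the forward/backward
ratio is still converging upward: 0.92 at h = 0.25, 1.07 at 0.125, 1.10 at
1/12), 0.125 nm on the extended domain (123k cells).

## Obstacles and interference

An obstacle (an immobile kinesin or a comparable MT-associated protein)
anchors one bound head at a site and makes a footprint of m_obs sites
unbindable: the anchor plus the sites swept by its own tethered head.
Defaults: m_obs = 3 as the lateral triple (anchor ± one protofilament),
m = 5 the plus shape, m = 9 the 3×3 block. The lateral default follows the
tether geometry (the swept head easily reaches the 6.4 nm lateral
neighbours, while the 8 nm axial neighbours lie uphill in the tether
potential); an axial triple is available via `footprint="axial"`. Swept
("excluded") sites may be shared between obstacles, but no head may bind a
site inside another's footprint. Random sequential deposition under this
rule jams at anchor/site ratios 0.432 (m=3), 0.364 (m=5), 0.187 (m=9) on a
13×500 cylindrical lattice, matching the published saturation ratios to
within 2%.

Only the anchor carries the reflective R_obs circle in the diffusion
problem; excluded sites merely lose their absorbing boundary.

**Interference and unbinding.** Kinesin detaches predominantly while one
head is diffusing, i.e. during the ~10 ms ATP wait when the partner head is
tethered to the bound head by both (undocked) NLs. The interference measure
A_int of an obstacle is therefore computed as the equilibrium line density
of that tethered head along the obstacle's circle, times the mean dwell:

    A_int = mean_dwell × ∮ π_tether dℓ      (ms/nm)

with π_tether the Boltzmann density of the two-NL series tether (unwinding
included) anchored at the bound site. With no fitted constants this yields
0.56 ms/nm for a 5 nm obstacle at the forward site (published value 0.58).
The per-step unbinding probability is P_ub = P_ub0 + α_obs Σ A_int with
α_obs = 0.044 nm/ms and P_ub0 = 0.008 (set so the unobstructed run length is
~1 μm at 8 nm per step). Two known departures of this reading, both carried
openly: the kinesin-2 tether (17 AA) contacts the forward obstacle *more*
(0.64 ms/nm), not less (published: 0.46), and side-placed obstacles — whose
circles cut deep into the tether pocket but which a walking kinesin can
never stand next to under the sharing rule — exceed the forward value, so
strict maximality at the forward site holds only over walk-reachable
placements. The time-and-line integral of the stepping episode itself
(`a_int_episode`, the direct reading of the interference definition over the
splitting solve) is also computed; it is ~25× smaller because absorption
takes only tens of microseconds, and it does show forward-maximal ordering.

## Stochastic walks and traffic

Each cycle: exponential dwell (mean 10 ms), unbinding draw, then a
destination drawn from the splitting probabilities of the local
blocked-neighbour configuration, renormalised over accessible sites. Exact
Fokker-Planck solves back every mask seen in a deposited field with up to
three blocked neighbours (mirror-symmetric masks share one solve); rarer
masks fall back to zeroing blocked destinations of the empty-mask entry and
renormalising, with A_int taken from the single-obstacle entries. Ensembles
use a 13×2000-site lattice; estimator filters mimic experiments (positions
quantised to 8 nm, sampled at 33 ms — the sources give no values; both are
configurable). With no obstacles the estimators recover the analytic values
V₀ = 8·(P_fw−P_bw)/dwell ≈ 765 nm/s and RL₀ = 8·(P_fw−P_bw)/P_ub0 ≈ 0.96 μm
(sideways steps advance 0 nm, hence the small offset from 8 nm/dwell).

At the calibration density ρ = 0.0346 (8% of the m=3 saturation) the model
gives V/V₀ ≈ 0.87 and RL/RL₀ ≈ 0.69 versus the published 0.82 and 0.57.
The shortfall traces to the interference ledger above: reproducing the
published run-length drop would need roughly twice the accumulated
obstacle-contact exposure per run, and the published per-obstacle A_int
values for non-forward placements (shown only graphically in the source)
are evidently larger than this package's waiting-state values.

Traffic scenarios place many motors (immobile, co-directional, or
minus-end-directed with mirrored step tables) on an axially periodic
lattice, advance them on a continuous-time event queue with footprint
exclusion, and track one tagged walker. Co-directional crowds slow the
tagged motor least and immobile crowds most, reproducing the qualitative
ordering.

**n_step.** The expected number of steps to clear a single obstacle is
computed by first-passage analysis on the lattice Markov chain induced by
the step table: the walker starts at the nearest legally occupiable on-axis
site behind the obstacle and must reach the first row past the footprint.
n_step grows strictly with m_obs (≈2.6, 4.1, 4.8, 6.1 for m = 1, 3, 5, 9).

## Deterministic models

V(ρ) = V₀/(1+Σa_k ρ^k) and RL(ρ) = RL₀·[1/(1+Σb_k ρ^k)]·V(ρ)/V₀ are fitted
(linear least squares, k_max = 2 by default) to stochastic-ensemble samples;
the analytic mapping from n_step to the coefficients is not re-derived.
Exact coefficient recovery on self-generated data is verified to 1e−6.

## Synthetic data and scope

All inputs are generated: lattices, obstacle fields (seeded RSA), force
fields and walk ensembles. The generator mimics a clean single-motor assay:
fixed dwell statistics (no ATP dependence), permanent obstacles, no
rebinding after detachment, no cargo-mediated coupling between motors, and
a flat 2D lattice (no MT curvature or radial motion). Passing tests
therefore validate the model's internal consistency and its reproduction of
published summary numbers, not the full variability of real motility data.

## Known limitations

- The loaded force field depends on the coil-anchor closure; the
  forward/backward parity load is ~6-7 pN here versus ~7-8 pN implied by the
  published calibration, and the 7 pN ratio converges from below toward the
  published 1.3.
- The large-step tail probability (distant-site binding) converges to
  ~1.5e−7, an order of magnitude above the published 1.3e−8; the quantity is
  exponentially sensitive to the far-field NL tension, where a ~1 pN
  difference accounts for the gap.
- The obstacle-density response underestimates the run-length reduction
  (see interference ledger above).
- Unbinding exposure ignores load (walks are simulated at zero cargo
  force).
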