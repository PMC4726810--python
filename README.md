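# kinwalk

A two-dimensional model of kinesin-1 stepping on microtubules, for
biophysicists studying how obstacles — immobile motors, MT-associated
proteins such as tau — degrade motor transport.

Kinesin walks by throwing its free head ~6 nm forward (the power stroke) and
letting it diffuse, tethered by the two neck linkers (NLs), until it binds
one of the eight neighbouring β-tubulin sites. `kinwalk` implements that
picture end to end:

* **Neck mechanics** — each NL is a worm-like chain,
  `F = (k_B T/ℓ_p)[¼(1−ℓ/ℓ_c)⁻² + ℓ/ℓ_c − ¼]`, with coiled-coil neck turns
  unwinding at ~10 pN and adding 3.5 amino acids of contour per NL per turn.
  The resulting force field F(x, y) on the free head is tabulated over the
  diffusion domain.
* **Head diffusion** — the Fokker-Planck equation
  `∂p/∂t = D∇²p − ∇·(F p/γ)` (D = 73.6 μm²/s) is solved with absorbing
  circles at the binding sites and reflective obstacles/walls, by a
  conservative finite-volume scheme with Scharfetter-Gummel fluxes. The
  splitting probabilities P_b,i of binding each site come from one
  stationary solve of the time-integrated density; an overdamped Langevin
  particle simulation cross-checks them.
* **Obstacles** — footprints of 1/3/5/9 sites deposited by random sequential
  adsorption, a per-obstacle interference measure A_int (equilibrium contact
  of the ATP-waiting tethered head with the obstacle boundary × dwell), and
  the unbinding law `P_ub = P_ub0 + α_obs Σ A_int`.
* **Walks and traffic** — stochastic stepping with exact per-configuration
  step tables, run-length/velocity estimators with experiment-like
  resolution filters, and multi-motor traffic scenarios (immobile,
  co-directional, minus-end-directed crowds).
* **Deterministic response** — `V(ρ) = V₀/(1+Σa_k ρ^k)` and
  `RL(ρ) = RL₀·[1/(1+Σb_k ρ^k)]·V(ρ)/V₀` fitted to ensemble output, plus the
  first-passage statistic n_step (steps to clear an obstacle).

See `docs/methods.md` for the model assumptions, numerical choices and known
limitations.

## Worked example

```python
from kinwalk import ModelParams, assemble_problem, solve_splitting, \
    binding_probabilities

params = ModelParams()                     # published parameter set
sol = solve_splitting(assemble_problem(params))
bp = binding_probabilities(sol)
print(f"P(forward)  = {bp.p_b[7]:.3f}")
print(f"P(diagonal) = {bp.p_b[6]:.4f} each")
print(f"P(side)     = {bp.p_b[4]:.4f} each")
```

prints

```
P(forward)  = 0.874
P(diagonal) = 0.0404 each
P(side)     = 0.0225 each
```

— the free head steps straight forward ~87% of the time, to a forward
diagonal ~4% per side (possible only thanks to neck unwinding and the tilted
binding posture), and sideways ~2% per side, in line with the published
zero-load table (0.871 / 0.0452 / 0.0193). Obstacles change both the step
statistics and the unbinding:

```python
sol7 = solve_splitting(assemble_problem(params, blocked={7: "occupied"}))
print(f"A_int = {sol7.a_int[7]:.2f} ms/nm")   # -> A_int = 0.56 ms/nm
```

The command line mirrors the library:

```sh
kinwalk diffuse --load-pn 7 --out results/      # loaded splitting solve
kinwalk deposit --rho 0.0346 --seed 1           # obstacle field
kinwalk walk --rho 0.0346 --n-walkers 200       # V and RL vs obstacle density
kinwalk traffic --scenario K+M+ --rho 0.1       # motor crowds
```

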