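# Methods

## The two representations

**Individual-based model.** Cells are discrete agents on a regular lattice
`x_i = x_min + iΔx` (`i = 0..n_x`), `y_j = y_min + jΔy` (`j = 0..n_y`),
with integer occupancies `n[i, j]` and per-site environment counts `e[i]`.
In one step of length `Δt`, each cell does at most one of: move left/right
(probabilities `β∓` evaluated at the **target** site's total cell and
environment counts — this is what produces the asymmetric `−n ∂x Dᵐ`
transport in the limit), switch phenotype down/up (`μ∓`, evaluated at the
**current** site — producing the Fokker–Planck form `∂yy(Dᵖ n)`), divide in
place, die, or nothing. A single uniform draw per cell partitions `[0, 1]`
into these events, enforcing mutual exclusivity; the engine validates
`Σ(event probabilities) ≤ 1` at every occupied lattice cell and raises an
actionable error (naming the cell and the offending sum) when the step
sizes violate it. All probabilities are evaluated on the start-of-step
state and applied simultaneously (synchronous update), which avoids the
order dependence of sequential sweeps; transient overshoot of the site
capacity by a cell is tolerated because the volume-filling rules vanish at
capacity. Each environment element at site `i` is independently removed
with probability `min(1, Σ_j λ(j, n[i, j]))`. Moves out of the lattice and
switches past the phenotype bounds are forced to probability zero by the
engine regardless of the rule bodies.

**Continuum model.** The mean-field limit (`Δx, Δy, Δt → 0` with
`Δx²/Δt`, `Δy²/Δt` finite) gives the PDE quoted in the README. The package
treats the six coefficient functions `vᵐ, Dᵐ, vᵖ, Dᵖ, r, ν` as the primary
objects; `ibm.rules_from_coefficients` inverts the limit definitions at
finite steps,

    β∓ = (Δt/Δx²) Dᵐ ± (Δt/2Δx) vᵐ,
    μ∓ = (Δt/Δy²) Dᵖ ± (Δt/2Δy) vᵖ,
    γ = Δt·max(r, 0),   death = Δt·max(−r, 0),   λ = Δt·Δy·ν,

so drift, diffusion and net growth match the continuum coefficients
exactly at the configured resolution. Two deliberate departures from a
naive transcription:

* **Signed growth.** The lattice rule γ is a pure birth probability, but
  the T-cell preset has net `r < 0` for exhausted cells; `r` is therefore
  split into a birth and a death probability so each remains a true
  probability.
* **Degradation weight.** The environment equation's loss term is the
  *integral* `∫ν dy`, while the lattice accumulates a *sum* over phenotype
  states; the extra `Δy` in `λ` makes the expected per-element removal
  rate the midpoint quadrature of that integral. Without it the lattice
  environment would decay `1/Δy` times too fast. (Relatedly, the printed
  lattice rule for degradation nominally increments the environment count;
  it is implemented as a decrement, consistently with the continuum decay
  law and with "degradation".)

**Count ↔ density mapping.** The correspondence is set by a site capacity
`K` (default 100): `ρ = κN/K`, `e_density = κe/K`, and for the structured
density `n(x, y) = κ n_ij/(K Δy)`. `K` controls demographic noise
(fluctuations shrink like `1/√K`) and is exposed on `LatticeConfig`.
Ensembles are seeded through a single `SeedSequence(seed)` whose spawned
children drive independent replicate generators, so results are exactly
reproducible and replicates independent.

## Discretisation of the PDE

* **x-axis** — node-centred flux form. The flux
  `G = vᵐn + Dᵐ∂x n − n ∂x Dᵐ` is built at cell interfaces (coefficients
  by arithmetic mean, gradients by central difference); the boundary
  interface fluxes are set to exactly zero, which is the ghost-point
  construction in which the *flux*, not each term separately, vanishes —
  the only reading well-posed for every coefficient choice. The scheme is
  conservative by telescoping and second-order accurate (verified against
  the heat kernel on three grid levels; observed order ≈ 2.01).
* **y-axis** — finite volumes with a genuine cell-centred convention:
  `n_y + 1` cells of width `Δy = (y_max − y_min)/(n_y + 1)`, centres at
  `y_min + (j + ½)Δy`. The midpoint quadrature `ρ = Δy Σ_j n_j` is exact
  for linear integrands and is precisely the quantity the fluxes conserve.
  Advection uses the Koren κ = 1/3 MUSCL limiter
  `φ(θ) = max(0, min(2θ, (1+2θ)/3, 2))`, upwinded on the sign of the
  interface velocity (`u = −vᵖ`; positive `vᵖ` transports mass toward
  smaller `y`); diffusion is the second difference of the product
  `w = Dᵖn`, since the equation is posed in Fokker–Planck form. Boundary
  interface fluxes are exactly zero. When a preset has no phenotype
  transport the operator short-circuits to zero rather than running the
  limiter on zero velocities.
* **time** — `scipy.integrate.solve_ivp` with the adaptive explicit
  Runge–Kutta 5(4) pair, `max_step = 0.1` and save cadence 0.1 by default;
  the integrator substeps below this as stability requires. Because the
  semi-discrete mass is an exactly conserved linear functional of the
  state, conservation holds to rounding (measured relative drift ~4e-16
  over `t ∈ [0, 10]`), independent of tolerances. `solve` aborts with
  diagnostics on integrator failure or on densities exceeding `10κ/Δy`.

### IBM↔PDE comparison

`diagnostics.matched_lattice` places lattice phenotype states on the PDE's
y-cell centres so counts map onto densities without interpolation.
`compare_ibm_pde` reports per-save-time L2/L∞ norms and the fraction of
lattice points where the ensemble mean departs from the PDE by more than
4 standard errors. On the unbiased-walk + logistic benchmark
(50 × 10 lattice, `Δx = 0.5`, `Δt = 0.025`, `K = 100`, 500 replicates,
horizon `t = 2`) the total-density profiles agree to ≈ 2% of the peak; the
residual is the `O(Δt)` one-event-per-step bias plus the `O(1/K)`
correlation correction the mean-field closure discards, both of which
shrink under refinement.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| `kappa` | carrying capacity (cells + environment) | 1 | density |
| `p_star` | Allee threshold | 0.25 | — (must lie in (0, ½)) |
| `gamma0`, `gamma1` | T-cell death / maximal growth rate | 1, 10 | 1/time |
| `k1`, `k2` | exhaustion from activity / from tumour contact | 0.5, 0.5 | 1/time, 1/(time·density) |
| `epsilon` | phenotypic diffusivity of T cells | 0.01 | phenotype²/time |
| `r_C` | tumour growth rate | 0.1 | 1/time |
| `lambda_bar` | T-cell toxicity on the tumour | 10 | 1/(time·density) |
| `site_capacity` (`K`) | counts per full lattice site | 100 | cells |

A single "exhaustion rate" knob in the T-cell scenario is read as
`k1 = k2` (both describe exhaustion; they are exposed independently for
users who want to separate activity-driven from contact-driven
exhaustion).

## Initial conditions

* *Range expansion*: the lineage-labelling line `x = 5y` cannot live on a
  measure-zero set of a grid; each phenotype cell deposits density `1/Δy`
  in the x-node nearest `5y_j`, so the occupied diagonal has `ρ = O(1)`
  and the initial mass is independent of `Δy`.
* *Go-or-grow / T-cell*: a Gaussian bump `exp(−100(x² + (y−y₀)²))`
  (`y₀ = 0` motile, `y₀ = 1` naive) normalised by the analytic
  `max_y ∫ exp(...) dx` over the actual domain — the bump (width ≈ 0.07)
  is too narrow for discrete quadrature at practical `Δx` — so the initial
  total density peaks exactly at `κ`; a final rescale guards the
  volume-filling coefficients against quadrature overshoot of `κ`. The
  environment starts cleared (0) wherever the bump exceeds 0.001 (the
  condition is evaluated as a max over `y`, giving a clean cleared region)
  and at `κ/2` elsewhere.

## Benchmark configurations

Chosen so that fronts stay well inside the domain at the final plotted
time and the full validation suite runs in minutes on one core:

* Fisher / Allee speeds: `x ∈ [0, 100]`, `Δx = 0.1`, 20 phenotype cells,
  `t ∈ [0, 40]` in the test suite (`x ∈ [0, 60]` / `[0, 40]` with
  `t ∈ [0, 30]` / `[0, 40]` in the acceptance script); speeds are the mean
  of successive front-position difference quotients over the trailing 50%
  of save times (`ρ = 0.1` level set, rightmost downward crossing, linear
  interpolation — the rightmost rule disambiguates non-monotone
  profiles), discarding the transient.
* Go-or-grow contrast: `x ∈ [0, 30]`, `Δx = 0.2`, 20 phenotype cells,
  `t = 30`. With the trait diffusivity `Dᵖ = 1`, phenotype diffusion sets
  the explicit stability limit `Δt ≲ Δy²/2`, which makes the cost scale
  like `Δy⁻²`; 20 cells resolve the bulk/front structure contrast while
  keeping each variant under a minute. "Bulk" is `3 < x < x* − 5`.
* T-cell regimes: `x ∈ [0, 25]`, `Δx = 0.2`, 25 phenotype cells,
  `t ∈ [0, 50]`, exhaustion rates 0.1 and 1.0.
* Mean-field benchmark: as above (50 × 10 lattice, 500 replicates).

## What the synthetic scenarios do and do not show

The presets emulate the canonical regimes of structured invasion — lineage
surfing in pulled vs pushed waves, the migration–proliferation dichotomy,
and immune exhaustion — under idealised conditions: one spatial dimension,
deterministic initial data, no measurement noise, linear trade-offs, and
coefficients exactly shared between scales. Passing tests therefore
demonstrate internal consistency (IBM ↔ PDE ↔ analytic oracles), not
fidelity to any particular experimental system; fitting to data,
chemotaxis/haptotaxis, off-lattice motion and higher-dimensional domains
are out of scope.

## Numerical choices and degenerate inputs

* Limiter ratios are computed with a sign-preserving denominator floor
  (1e-100), so flat regions fall back gracefully to first order without
  overflow; ghost cells replicate edge values, which the zero boundary
  flux makes immaterial.
* `front_position` returns NaN (not an error) when no downward crossing
  exists; `wave_speed` requires ≥ 3 defined positions and otherwise
  advises a longer run.
* `mean_phenotype` masks positions with `ρ` below a density floor
  (default 1e-6·κ) where the moment ratio is noise.
* Negative-undershoot tolerance for the limited advection is 1e-8 in the
  validation suite; measured undershoot is at rounding level.
* The `ensemble` standard errors use the unbiased variance; a standard
  error floor of one cell per `K·n_reps` regularises the 4-SE comparison
  where sampled variance is zero.

## Known limitations

* The one-draw-per-cell step makes the IBM `O(Δt)` accurate in
  distribution; halving `Δt` halves the mean-field bias but doubles cost.
* The explicit integrator makes stiff phenotype diffusion (`Dᵖ ~ 1` at
  fine `Δy`) expensive; an IMEX scheme is a deliberate non-goal.
* `Dᵖ = 1` with finite-step inversion can demand very small `Δt` for the
  lattice model (`μ` scales like `Δt/Δy²`); the validator reports the
  offending probability and the step sizes that caused it.
* Pulled-front speeds converge from below like `O(1/t)` (with an
  additional `O(Δx²)` discrete correction), so finite-horizon estimates
  sit a few percent under `2√(rD)`; pushed fronts converge exponentially
  fast and land within fractions of a percent of the exact bistable
  speed.
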