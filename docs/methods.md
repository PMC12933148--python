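# Methods

## Model overview

`oceancp` solves the steady state of a linear ocean biogeochemical
model and partitions its organic-matter production by the *interior
residence time* of the regenerated inorganic products — the time
between remineralization at depth and the first return to the euphotic
zone. The residence-time-partitioned sequestration flux
Φ<sub>τ≥t</sub> answers the question marine-carbon-management cares
about: how much of today's organic production is still sequestered
`t` years from now?

The model is built from four layers:

1. **Transport.** A sparse operator `A` (s⁻¹) with the convention
   `dc/dt = A c + sources`, satisfying `A·1 = 0` (a constant field is
   unmoved) and `vᵀA = 0` (volume-weighted mass conservation) exactly.
   At desk scale `A` comes from a synthetic single-basin overturning
   streamfunction (upwind advection) plus horizontal/vertical diffusion
   (central, symmetric exchange), which guarantees both invariants and
   non-negative off-diagonals by construction. Full-scale applications
   load an externally estimated transport matrix through
   `read_transport_archive` (NetCDF or HDF5 triplet archives; y⁻¹
   operators are converted to s⁻¹ on load).

2. **Phosphorus cycle** (DIP, POP, semilabile DOP, labile DOP).
   Biological uptake is `γ·[DIP]` in the euphotic zone, with
   `γ = NPP / (r_C:P(DIP_obs)·DIP_obs)` diagnosed from the prescribed
   NPP field and the observed surface phosphate climatology. Uptake is
   split by fixed fractions between POP (residual), semilabile DOP
   (`sigma_dop`) and labile DOP (`sigma_dopl`). POP remineralizes
   instantaneously along a Martin power-law profile
   `f(z) = f(z₀)(z/z₀)^(−b)` below the euphotic base z₀, with
   `b = b0 + bθ·θ̄` and `θ̄` the normalized temperature averaged over
   the top three model layers. Dissolved pools decay back to DIP with
   `k = kd·Q10^((T−T₀)/10)`, `T₀ = 30 °C`; the labile pool has a fixed
   12 h lifetime. The coupled system conserves total phosphorus, so it
   is singular; the balance equation of the largest box is replaced by
   the constraint that the global volume-weighted mean DIP equal a
   prescribed inventory (that equation is implied by conservation, so
   the solution satisfies all the original balances — a unit test
   checks this).

3. **Carbon cycle** (DIC, ALK, PIC, POC, three DOC pools, O₂), slaved
   to the phosphorus solution. Organic carbon production is organic
   phosphorus production times the variable uptake stoichiometry
   `r_C:P = 1/(cc·[DIP] + dd)`, split between POC, semilabile DOC and
   refractory DOC; labile DOC production is the non-negative residual
   `max(0, NPP − r_C:P·γ·DIP)` that tops total production up to the
   prescribed satellite NPP field. Carbon remineralization mirrors the
   phosphorus formulation with its own `b`, `kd`, `Q10`. PIC is
   produced at a rain ratio times POC production and redissolves along
   an exponential depth profile.

4. **Residence-time partitioning.** Each organic pool's steady-state
   remineralization field is released as a pulse of regenerated tracer
   and propagated by `dR/dt = (A − Λ)R`, where Λ is a fast restoring
   sink (default 500 y⁻¹) confined to the euphotic zone that
   approximates an absorbing surface. The surviving global inventory
   `M(t) = vᵀ exp(t(A−Λ)) r₀` *is* the sequestration flux
   Φ<sub>τ≥t</sub> of that pool: M(0) equals the pool's production and
   the fraction surviving to `t` is the production whose regenerated
   product stays interior at least `t`. The residence clock starts at
   remineralization, deliberately excluding the sinking interval; that
   interval is short compared to interior residence for all pools
   except refractory DOC, which carries negligible flux.

## Closures that do not affect the sequestration accounting

- **DIC/ALK.** Full carbonate-system gas exchange is replaced by fast
  (≈1 month) surface restoring toward reference surface values. The
  regenerated-tracer analysis never touches DIC/ALK themselves, only
  the remineralization rate fields, so this closure has no effect on
  the curves; it exists so the inversion's DIC/ALK
  misfit terms are exercisable.
- **O₂.** Linear stoichiometric coupling (150 mol O₂ : mol P) with
  surface restoring to a linearized saturation `0.35 − 0.0053·T`
  mol m⁻³. Without a respiration cutoff the linear model can drive O₂
  negative in poorly ventilated boxes; such values are reported as an
  oxygen debt (the usual convention for linear O₂ closures) rather
  than raised as errors.

## Parameters

| name | meaning | units | default | notes |
|---|---|---|---|---|
| `bC0`, `bCtheta` | carbon Martin exponent, `b = b0 + bθ·θ̄` | – | 1.0, 0.6 | warm water → shallower POC remin |
| `bP0`, `bPtheta` | phosphorus Martin exponent | – | 0.8, 0.4 | P remineralizes deeper than C |
| `kdC`, `kdP` | reference DOM decay at 30 °C | s⁻¹ | 0.5 y⁻¹, 0.05 y⁻¹ | semilabile DOC ~decades, DOP ~centuries in cold water |
| `Q10C`, `Q10P` | temperature sensitivity | – | 2.2, 2.0 | ≥ 1 |
| `cc`, `dd` | `r_C:P = 1/(cc·DIP + dd)` | m³ mol⁻¹, – | 2.0, 7.33e-3 | ≈120:1 at the mean surface DIP |
| `sigma_dop`, `sigma_dopl` | P production to semilabile / labile DOP | – | 0.30, 0.0 | base model has no labile DOP |
| `sigma_docs`, `sigma_docr` | non-labile C production to semilabile / refractory DOC | – | 0.30, 0.002 | refractory share sized to a realistic deep DOC inventory |
| `kappa_l` | labile-pool decay | s⁻¹ | 1/12 h | fixed |
| `kappa_r` | refractory DOC decay | s⁻¹ | 1/16,000 y | fixed, not optimized |
| `pic_rain_ratio`, `pic_dissolution_scale` | PIC production / dissolution | –, m | 0.07, 3000 | |
| `o2_to_p` | O₂:P stoichiometry | mol/mol | 150 | fixed |
| `dip_inventory` | global mean DIP constraint | mol m⁻³ | 2.17e-3 | |

The optimizable subset and its bounds live in a data-driven registry
(`CycleParameters.bounds`, 16 entries) and can be edited without code
changes. θ̄ normalization is min–max over columns to [0,1] by default
(`theta_normalization="zscore"` switches to standardization). The
euphotic zone is the top 2 model layers by default, configurable.

## Synthetic ocean

The desk-scale generator emulates a global-scale single basin
(80°S–80°N, full zonal extent, ~3.5 km deep, default 8×4×8 = 256
boxes): a 30 Sv single-cell overturning, horizontal diffusivity
10³ m² s⁻¹ and vertical diffusivity 2×10⁻⁴ m² s⁻¹ (an effective value
that also stands in for unresolved upwelling at 8 layers), a
thermocline temperature profile, a surface phosphate climatology
enriched toward high latitudes, and a prescribed global NPP of
55 Pg C y⁻¹ distributed by surface DIP times a light envelope with a
seeded log-normal perturbation. Observations are the model's own
equilibrium fields with mean-preserving multiplicative log-normal
noise and optional missingness.

Under these conditions the equilibrium lands in the regime the
full-scale literature reports: labile DOC carries roughly half of
total organic carbon production, production C:P is far above Redfield
(~220:1) and falls toward ~Redfield at century horizons, and
phosphorus outlives carbon in the interior.

What the generator does **not** emulate: real geography and
bathymetry, seasonality, observational error covariances, water-mass
structure, and genuinely data-constrained circulation. Passing tests
therefore demonstrate the correctness and internal consistency of the
machinery (conservation, first-passage accounting, recoverability of
parameters), not agreement with the real ocean.

## Numerics

- Steady states: sparse LU (`splu`) on the assembled systems; the
  phosphorus block system is 3n×3n, every carbon tracer is a separate
  n×n solve. Pools with identically zero production are set to exact
  zeros rather than solver dust.
- Survival integration: Crank–Nicolson (trapezoid) steps on a
  geometric schedule (dt from 10⁻³ y growing ×1.2 to a 10 y cap),
  with output times as step endpoints so no interpolation error
  enters. The schedule is refined — dt0, the cap, *and* the growth
  increment halved — until two successive sweeps agree within the
  requested `rtol` (1e-5 for production curves, tighter in
  oracle-comparison tests); during the ramp dt scales like
  (growth−1)·t, which is why the growth factor must tighten too. The
  global inventory is checked to be non-increasing up to a round-off
  floor of 10⁻¹³ of the initial inventory.
- The dense matrix-exponential oracle (`firstpassage_oracle`) is
  capped at 500 boxes and is used only as an independent cross-check.
- Optimization: L-BFGS-B with finite differences in log-parameter
  space, bound-constrained, with a hard evaluation budget and a 10¹²
  penalty for failed forward solves.
- Tie-breaks / degenerate inputs: a spatially constant temperature
  yields θ̄ ≡ 0 (degenerate min–max range); columns no deeper than the
  euphotic zone recycle their export into the deepest euphotic box;
  particle flux reaching the seafloor remineralizes in the bottom wet
  box (no burial).

## Problem sizes

Unit and acceptance tests run on 90-box (5×3×6) and 196-box (7×4×7)
oceans; the acceptance script uses the 256-box default. Curve
tolerances are 10⁻⁴–10⁻⁵ relative for reported numbers and 3×10⁻⁷ in
the integrator-vs-oracle comparison. These sizes were chosen so the
whole analysis chain — including two sensitivity experiments and a
four-parameter inversion — completes in minutes on one core.

## Known limitations

- The sequestration flux is a global scalar per horizon; no
  per-location residence-time maps or adjoint densities.
- POP/POC/PIC "concentrations" are diagnostics (flux divided by a
  nominal 100 m d⁻¹ sinking speed); particles are not transported
  tracers.
- No nitrogen or iron cycles, no seasonal circulation, no sediment
  burial, no full carbonate chemistry, and point estimation only (no
  posterior uncertainty).
- Desk-scale results are illustrative of mechanisms; quantitative
  full-scale numbers require an externally estimated transport matrix
  and gridded climatologies via the archive readers.
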