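# Methods

## Models

Cell density `rho(x, t)` (cells mm⁻²) in an expanding epithelial monolayer
obeys a conservation law with logistic growth,

    d_t rho + div(j) = r rho (1 - rho / K).

Two constitutive choices for the flux are implemented:

* **Fisher-KPP** (`family="linear"`): Fickian flux `j = -D grad(rho)` —
  cells move randomly. Supports pulled travelling waves of speed
  `c = 2 sqrt(D r)` and exponentially decaying leading edges.
* **Porous-Fisher** (`family="porous"`): Darcy flux `j = rho v`,
  `v = -grad(P)` with power-law population pressure
  `P(rho) = D rho^(m-1)` (default `m = 2`) — cells move down pressure
  gradients. The diffusivity `D(rho) = D rho^(m-1)` degenerates at vacuum,
  producing compactly supported profiles with sharp fronts; for `m = 2`
  the travelling-wave speed is `c = sqrt(D K r / 2)`. `m -> 1` recovers
  the linear model.

For `n` tissues seeded at disjoint locations, each species `rho_i` is
advected by the gradient of the **total** pressure
`P = D (sum_j rho_j)^(m-1)` (porous) or diffuses independently (linear);
proliferation is limited by the total density through
`r rho_i (1 - sum_j rho_j / K)`. Adding the porous equations recovers the
single-species equation for the total density, and initially segregated
species remain separated by a sharp interface.

Internal units are mm, hours, cells mm⁻². User-facing diffusion constants
are μm² h⁻¹ (linear) and μm² h⁻¹ per (cells mm⁻²)^(m−1) (porous; for
m = 2 this is μm² (cells h)⁻¹) and are converted on input, which keeps
solver arithmetic in one unit system.

## Finite-volume solver

Explicit, conservative, positivity-preserving, on uniform cell-centred
grids: `cartesian2d` for collisions (a `ny = 1` grid degenerates to 1D)
and `radial1d` for circular expansions (first centre at `h/2`, fluxes
weighted by face radius so polar mass is conserved exactly).

The face flux is `F = -M (P_R - P_L)/h` with the mobility `M` taken from
the upwind cell (by the sign of the face velocity) for the porous family,
and the plain Fickian difference for the linear family. Mobility is
exactly zero in vacuum — no regularization — which preserves compact
supports and sharp fronts. Reaction uses explicit Euler in the same step.

Time-step control: `dt <= CFL h² / (2 g D_eff)` with `CFL = 0.4`,
`g` = number of active dimensions (2 for radial geometry: the innermost
annulus has twice the Cartesian face-to-volume ratio) and
`D_eff = (m-1) D rho_max^(m-1)` (porous, with `rho_max` floored at `K`
when growth is active) or `D` (linear); additionally `dt <= 0.1 / r`.
Under this bound the upwind update is positivity-preserving. Each output
interval is subdivided evenly so requested times are hit exactly and runs
are deterministic.

Validation (all in the test suite and `scripts/acceptance.py`): exact mass
conservation without growth; L¹ convergence to the heat kernel (linear)
and to the Barenblatt source solution of `d_t u = (D/2) Lap(u²)`,
`u = s^(-1/3)(C - x²/(12 s^(2/3)))_+` with `s = D t / 2`; front speeds
within 5% of the two closed forms above; discrete sum-consistency of the
two-species porous system with the single-species solve (machine
precision, because per-species upwind mobilities sum to the total's);
agreement of radial and 2D solves of the same circular expansion.

Default resolutions: h = 25 μm (2D collisions; 50 μm in the demonstration
suites), h = 10 μm radial (production) with 15–20 μm used by the test and
acceptance runs — these resolve the 115 μm observation voxel and the
front width while keeping the demonstration runs inside desk-scale
runtimes.

## Synthetic observation protocol

The generator emulates the published experimental protocol for circular
expansions: a 3.4 mm-diameter tissue seeded at 2600 cells mm⁻² (the
seeding density of the collision experiments; the expansion seeding
density is not reported, so this is an explicit assumption), a 6 h
burn-in standing in for the post-stencil-removal transient that the
calibration discards, then voxel observations at t = 16, 26, 36, 46 h on
a 115 μm lattice anchored at the domain corner. Voxel values are **area
averages** of the model field (densities quantified by nucleus counting
are an area measure), computed by 4×4 subsampled interpolation — mass is
conserved to well under 0.5%. Additive i.i.d. Gaussian noise `N(0, σ²)`
per voxel and time; negative values are retained, matching the Gaussian
likelihood exactly. Noise is seeded per (time, voxel-lattice-index), so
subsets of voxels are reproducible independently of iteration order.
Optional 11-replicate averaging reduces residual noise by `sqrt(11)`.

What the generator does **not** emulate: image formation, nucleus-centroid
detection, spatially or temporally correlated errors, the non-monotonic
intermediate-time density profiles reported experimentally, and densities
exceeding the carrying capacity at late times. Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
assumed error model, not robustness to misspecification.

## Inference

`theta = (D, r, K, sigma)` with log₁₀-uniform box priors. Published
bounds are adopted; two are corrected because they exclude the published
estimates: the K box becomes [10³, 10⁴] cells mm⁻² (printed upper bound
10³·⁵ < both fitted K) and the porous D box becomes [10⁻²·⁵, 10¹·⁵]
μm² (cells h)⁻¹ (printed bounds are reversed). Circular-expansion
likelihoods run the radial solver — identical physics at a fraction of
the cost — and voxel-average the solution with exactly the generator's
quadrature, so the fitted model is well specified on synthetic data. The
calibration initial condition is the known burn-in (6 h) profile, not a
function of theta, mirroring the use of the measured early-time profile.

* **Maximum likelihood**: bound-constrained L-BFGS-B on log₁₀ parameters
  from multistart points sampled uniformly in the box. `sigma` is profiled
  analytically (`sigma² = mean squared residual`, clipped to the box),
  which halves the search dimension without changing the argmax.
* **MCMC**: Metropolis-Hastings on log₁₀ parameters, Gaussian proposals,
  covariance adapted every 50 iterations after iteration 500 to the
  running sample covariance scaled by `2.38²/d` plus a 10⁻¹⁰ diagonal
  jitter. The initial proposal step (0.005 log₁₀ units) is chosen near
  the posterior scale of the expansion problem so the pre-adaptation
  phase already mixes; the full-length convention is 12 000 iterations ×
  3 chains with the last 5000 retained per chain, and the demonstration
  runs use 3000 × 3 with the last 1500 retained.
* **Diagnostics**: split Gelman-Rubin R̂ per parameter (cross-checked
  against `arviz`); univariate KDE modes (Gaussian kernel, Silverman
  bandwidth); central 95% credible intervals; plot-matrix histograms.

On synthetic data at the published porous posterior modes the pipeline
reproduces the published behaviour: unimodal, narrow marginals
(sd/mode ≈ 0.2–1%), posterior modes within one posterior s.d. of the ML
estimates, the generating parameters inside all 95% intervals, and a
negative D–r posterior correlation reflecting the front-speed trade-off.

## Collision analysis

The tissue–tissue interface is the sign change of `rho_1 - rho_2` between
the two supports, located per grid line parallel to the collision axis by
linear interpolation and averaged over lines — exact for segregated
porous solutions, and a graceful fallback for the mixed linear solutions.
A line counts as collided only when no below-threshold (default
10 cells mm⁻²) stretch separates the supports; collision detection is on
output times only (cadence ≤ a few hours, finer than any claim made).
The mixing diagnostic `overlap_index` is `∫rho₁rho₂ / (∫rho₁ ∫rho₂ / A)`:
0 for disjoint supports, 1 for identical uniform fields.

Rectangle-pair defaults (1.0 × 2.0 mm rectangles, 0.5 mm gap,
2600 cells mm⁻², with 1800 cells mm⁻² and 500 μm variants for the
density- and width-mismatch cases) follow the published mismatch values
where printed and are labelled assumptions otherwise.

**Displacement scaling law.** For two touching 1D tissues with a mass
mismatch and no proliferation, the total density converges to the
Barenblatt source solution of the porous-medium equation, and the species
interface is the material point carrying the fixed mass split — the
corresponding quantile of the self-similar profile. Its offset from the
centroid therefore grows like the Barenblatt width, `t^(1/(m+1))`: faster
boundary motion for smaller pressure exponents, frozen boundaries as
`m -> infinity`, and instantaneous mixing in the linear limit. The
package fits the late-time (last decade of the horizon) log-log slope of
the simulated displacement and compares it with `1/(m+1)`; measured
exponents are ≈ 0.34 (m = 2) and ≈ 0.26 (m = 3). An alternative exponent
`1/(m-1)` sometimes quoted for this law is inconsistent with both this
derivation and the simulations, and would predict slower (indeed
negative-exponent) motion for m < 1 rather than faster.

## Design choices and limitations

* The cited finite-volume scheme is not specified in full in the source;
  the upwind-mobility discretization here is a standard member of that
  family and is validated through the convergence and invariant suites
  rather than by line-by-line equivalence.
* Explicit time stepping only; stiff regimes (very large D or m) pay the
  parabolic dt penalty. No implicit integrators, unstructured meshes, 3D,
  adhesion, viscoelasticity, cell-cycle or cell-size structure.
* `division_time` is reported both exactly (`1/effective rate`) and in
  the headline convention (rate rounded to one significant figure first),
  since the published 10 h / 11 h figures follow the latter.
* The three-species tessellation demo and the hexagonal eight-circle
  array use the two-colour alternating labelling of the experimental
  layouts; exact artwork geometries are out of scope.
* Real experimental datasets are external and are not fitted here; all
  quantitative checks run on the synthetic protocol.
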