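# tissuefit

Continuum modelling and Bayesian calibration of epithelial tissue
expansion and collision.

Expanding epithelial monolayers (e.g. MDCK cell sheets) are well
described at the tissue scale by reaction–diffusion equations for the
cell density ρ(**x**, t) (cells mm⁻²). `tissuefit` implements the two
canonical models side by side, for single tissues and for colliding
multi-tissue systems, together with the statistical machinery needed to
calibrate them against voxelized density measurements and to ask whether
their parameters are *practically identifiable* from realistic data.

* **Fisher-KPP** (random cell motion):
  ∂ₜρ = D Δρ + r ρ (1 − ρ/K)
* **Porous-Fisher** (motion down population-pressure gradients,
  P(ρ) = D ρ^{m−1}, default m = 2):
  ∂ₜρ = D ∇·(ρ ∇ρ) + r ρ (1 − ρ/K)

and their n-species cross-diffusion extensions, where every tissue feels
the gradient of the **total** pressure — the mechanism that produces the
sharp, slowly-moving boundaries observed when real tissues collide.

The package provides, as library modules behind a statsmodels-style
`ExpansionModel` / Results interface:

* a conservative, positivity-preserving finite-volume solver (explicit,
  upwind mobilities, no-flux boundaries; 2D Cartesian and 1D radial);
* geometry builders for the experiment families: circles, rectangle
  pairs (control / density mismatch / width mismatch), unequal circles,
  hexagonal eight-circle arrays, multi-species tessellations;
* a synthetic observation generator emulating the experimental protocol
  (115 μm voxels, observation times 16–46 h, additive Gaussian noise,
  optional replicate averaging);
* maximum-likelihood (multistart, bound-constrained, log-scale) and
  adaptive Metropolis–Hastings MCMC calibration with log-uniform priors,
  split Gelman–Rubin diagnostics and posterior summaries;
* collision analysis: interface tracking, collision times, boundary
  displacement, segregation/mixing indices, and the late-time
  displacement scaling law ~ t^{1/(m+1)};
* a `tissuefit` CLI (`simulate`, `collide`, `synth`, `infer`,
  `summarize`) driven by YAML run configurations.

See `docs/methods.md` for the numerical scheme, the observation model,
and the reasoning behind every default.

## Worked example

Derived biology from the Porous-Fisher posterior modes
(D = 1.18 μm² (cells h)⁻¹, r = 0.214 h⁻¹, K = 5319 cells mm⁻²):

```python
from tissuefit import ModelParams, growth_summary

porous = ModelParams("porous", D=1.18, r=0.214, K=5319.0)
d = growth_summary(porous, rho_bar=3000.0)
print(f"cell radius        : {d.cell_radius_um:.2f} um")
print(f"effective rate     : {d.effective_rate:.4f} 1/h")
print(f"division time      : {d.division_time:.1f} h  (headline: {d.division_time_printed:.0f} h)")
print(f"avg diffusivity    : {d.average_diffusivity:.0f} um^2/h")
```

```
cell radius        : 7.37 um
effective rate     : 0.0933 1/h
division time      : 10.7 h  (headline: 11 h)
avg diffusivity    : 3540 um^2/h
```

The cell radius follows from hexagonal close packing at the carrying
capacity, K = 1/(2√3 a²); the effective rate is the logistic rate at a
typical bulk density of 3000 cells mm⁻², and its reciprocal is the
implied division time. The average diffusivity D·ρ̄ = 3540 μm² h⁻¹ is
about three times the Fisher-KPP estimate (1073 μm² h⁻¹).

Full calibration loop on synthetic data generated at those same
parameters (σ = 427 cells mm⁻², observation times 16–46 h):

```python
from tissuefit import ExpansionModel

truth = ModelParams("porous", D=1.18, r=0.214, K=5319.0)
model = ExpansionModel.from_synthetic(truth, sigma=427.0, seed=1,
                                      domain_radius_mm=3.4, solver_h_mm=0.02)
ml = model.fit(n_starts=5, seed=1)
post = model.fit_mcmc(n_iter=3000, n_chains=3, seed=1, start=ml.params, retain=1500)
print(post.summary())
```

```
Adaptive MCMC: 3 chains x 3000 iterations (last 1500 retained per chain)
acceptance rates: [0.408, 0.366, 0.294]

                  mode         mean        sd      ci_2.5%     ci_97.5%      rhat
parameter
D             1.167153     1.171301  0.012070     1.145892     1.195652  1.006899
r             0.216171     0.216039  0.001883     0.212271     0.219870  1.005192
K          5312.155472  5313.784377  9.048791  5296.796649  5331.842834  0.999830
sigma       430.160969   430.951218  2.527133   426.071024   435.832176  1.013469
```

All four marginals are unimodal and narrow (sd/mode ≈ 0.2–1%), the
generating parameters sit inside every 95% credible interval, and the
posterior modes agree with the maximum-likelihood estimates — the
practical-identifiability signature this pipeline is built to assess.

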