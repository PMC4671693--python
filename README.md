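# colonyabc

Likelihood-free (ABC) inference of the parameters that drive an expanding
cell colony — cell diffusivity *D*, cell-to-cell adhesion strength *q* and
proliferation rate *λ* — from barrier-assay style image summaries, for
quantitative cell biologists and biostatisticians working with
individual-based models whose likelihoods are intractable.

## What it does

The package couples three pieces:

1. **A lattice exclusion-process simulator.** Agents on a square lattice
   (spacing Δ = 18 µm, one site per cell) move to von Neumann neighbours
   with probability `P_m (1 − q)^n` (n = occupied neighbours) and deposit
   daughters with probability `P_p`, under random sequential updates of
   step τ = 0.04 h; events onto occupied sites abort. Per-step
   probabilities convert to rates via `D = P_m Δ²/(4τ)` and `λ = P_p/τ`.
2. **Summary statistics.** A condition with three replicates becomes the
   15-vector `L = (R(1), R(2), R(3), c1..c6, p1..p6)` — ordered equivalent
   circular colony radii plus cell counts and isolated-cell fractions in
   six transect sub-regions — and is then projected to one regression-based
   statistic per parameter (stepwise BIC selection over `(L, L²)`),
   compared through a squared Mahalanobis discrepancy with a
   simulation-estimated covariance.
3. **Adaptive SMC-ABC samplers.** The main sampler (ASMC) adapts its
   tolerance schedule by dropping the worst-discrepancy half of the
   particle system and replenishes with importance re-weighted
   resample-perturb-simulate proposals; MCMC-replenishment (RSMC),
   population Monte Carlo (APMC) and plain rejection baselines are
   included, along with weighted posterior summaries (means, 90% credible
   intervals, CV, Kish-ESS-based MCSE, generalized variance) and
   sequential Bayesian learning across time periods and experimental
   scenarios.

See `docs/methods.md` for the model, algorithms and design choices.

## Worked example

Simulate a quarter-scale validation dataset at known parameters, then
recover them:

```python
import numpy as np
from colonyabc import (
    UniformBoxPrior, asmc, posterior_summary,
    make_validation_dataset, ColonyPilotSimulator,
    pilot_abc, build_training_set, fit_projection,
    estimate_W, calibrate_eps_final,
)

# three replicate colonies at (Pm, q, Pp) = (0.1, 0.2, 0.0012),
# i.e. D = 202.5 µm²/h, q = 0.2, λ = 0.03 /h
_, L_obs, scen = make_validation_dataset(seed=5, scale=0.25)

sim = ColonyPilotSimulator(scen.cfg, scen.layout, scen.n_replicates)
prior = UniformBoxPrior((0, 0, 0), (1, 1, 1), ("Pm", "q", "Pp"))

# iterated pilot: pins down the proliferation axis; motility and adhesion
# keep their uninformative priors (the D-q ridge must not be truncated)
region = pilot_abc(L_obs.as_vector(), prior, sim, budget=330,
                   keep_fraction=0.08, inflate=0.2, rounds=3, seed=2)
box = UniformBoxPrior((0, 0, 0), (1, 1, float(region.highs[2])),
                      ("Pm", "q", "Pp"))

train = build_training_set(box, sim, M=500, seed=3,
                           param_names=("Pm", "q", "Pp"))
model = fit_projection(train)
W = estimate_W(model, L_obs.as_vector(), sim, box.bounds, n_cal=32, seed=4)
S_obs = model.project(L_obs.as_vector())
eps = calibrate_eps_final(S_obs, W, quantile=0.6)

system = asmc(S_obs, box,
              lambda th, s: model.project(sim.pilot_vector(th, s)),
              W.W, n_particles=80, eps_final=eps, seed=100)
print(posterior_summary(system, scen.cfg).to_frame().round(4))
```

Output (deterministic for these seeds):

```
  parameter      mean      ci5      ci95        sd  cv_percent     mcse
0         D  267.5146  21.5711  594.1879  194.0180     72.5261  30.9325
1         q    0.2717   0.0169    0.5470    0.1521     55.9745   0.0242
2    lambda    0.0297   0.0196    0.0363    0.0056     18.7192   0.0009
```

The generating values (202.5 µm² h⁻¹, 0.2, 0.03 h⁻¹) fall inside all
three 90% credible intervals, with posterior means of 267.5, 0.27 and
0.0297. At this reduced lattice size the data constrain the proliferation
rate tightly (CV ≈ 19%), adhesion moderately and diffusivity only loosely
(the well-known D–q ridge); full-scale summaries sharpen all three.

A `colonyabc` command-line interface wraps the same pipeline
(`simulate`, `summarize`, `pilot`, `train-summaries`, `infer`,
`sequential`, `compare`).

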