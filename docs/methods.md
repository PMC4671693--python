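# Methods

## The model

`colonyabc` simulates and fits a discrete, lattice-based exclusion-process
model of an expanding cell colony in a barrier assay. Agents occupy sites of
a square lattice with spacing Δ (default 18 µm, one nucleus diameter); each
site holds at most one agent. Time advances in steps of τ (default 0.04 h)
under an approximate random sequential update (RSU): per step, C(t) motility
candidates are drawn with replacement from the agents present at the step
start and processed one at a time, then C(t) proliferation candidates
likewise. A motility candidate moves to a uniformly chosen von Neumann
neighbour with probability P_m (1−q)^n, where n ∈ {0..4} is its occupied
nearest-neighbour count *at decision time* and q ∈ [0,1] is the
cell-to-cell adhesion strength; a proliferation candidate deposits a
daughter on a uniformly chosen neighbour with probability P_p. Events that
target an occupied site or fall off the lattice abort; daughters only enter
the sampling pool at the next step; there is no death. The per-step
probabilities map onto biological rates through

    D = P_m Δ² / (4τ)   [µm² h⁻¹]      λ = P_p / τ   [h⁻¹]

so with the default constants, P_m, P_p ∈ [0,1] induce D ∈ [0, 2025] µm² h⁻¹
and λ ∈ [0, 25] h⁻¹. The default geometry is a 867-site-wide lattice (a
15.6 mm well), with 20,000 cells seeded uniformly at random inside a disc of
radius 177 sites.

Implementation notes:

* The two sweeps are resolved motility-first, then proliferation — one
  consistent reading of the sequential-update scheme; the alternative
  (interleaved sweeps) differs only at O(P_m P_p) per step and is
  indistinguishable at the parameter magnitudes of interest.
* The constant-probability gate of each sweep is drawn as one binomial count
  followed by that many uniform agent picks. This is an exact
  reformulation of per-draw Bernoulli thinning, not an approximation.
* Candidates whose four neighbouring targets are all blocked are skipped
  without spending random draws — such events can only abort.
* A fully saturated lattice is absorbing (every event aborts), so the
  kernel stops exactly when C(t) equals the site count.
* Per-event randomness comes from an xorshift64* stream re-seeded each time
  step from a `SeedSequence`-derived per-step seed; binomial counts use the
  numpy stream seeded the same way. Together with an agent buffer carried
  across schedule segments, this makes a run a pure function of its seed,
  identical however the schedule is sliced — so a two-stage schedule with
  equal parameters reproduces the one-stage run bit for bit.

## Summary statistics

One condition (default three replicates) is summarised by the 15-vector
L = (R(1), R(2), R(3), c₁..c₆, p₁..p₆): ordered equivalent circular radii of
the replicates, and per-sub-region cell counts and isolated-cell fractions
averaged over replicates. The leading edge is detected on the occupancy
grid the way image segmentation treats a micrograph: morphological closing
with a disc structuring element (radius 3 sites, configurable), hole
filling, largest connected component; the enclosed area A gives
R = √(A/π). The six sub-regions are contiguous windows (39 × 28 sites at
full scale, i.e. 700 × 500 µm) along the horizontal transect, starting at
the lattice centre column and extending outward; their exact placement is a
convention, exposed in the layout config. An agent is isolated when its
four nearest neighbours — looked up on the full lattice, including
neighbours outside the window — are all empty. An empty window reports an
isolated fraction of 0 so that L stays finite for extreme parameter draws.

## Semi-automatic summaries and discrepancy

ABC matching on the raw 15-dimensional L is inefficient, so the package
projects it to one derived statistic per free parameter:

1. **Pilot run.** Rejection ABC with a component-standardised Euclidean
   distance on L locates the region of non-negligible posterior density;
   the axis-aligned bounding box of the accepted draws (inflated by a
   configurable margin, clipped to the prior) becomes the training region.
   The pilot can be iterated (`rounds > 1`), splitting the same simulation
   budget across rounds that redraw inside the previous box. This matters
   in practice: under a uniform prior most proliferation draws saturate the
   lattice and produce a degenerate summary plateau with no gradient, and
   a single coarse round cannot shrink the proliferation axis enough for
   the regression step to see signal.
2. **Training.** M parameter vectors are drawn uniformly on the region,
   each with a simulated L_i (M = 5,000 at full scale; smaller at desk
   scale, see below).
3. **Projection.** For each parameter j, a linear model
   θ_j = α_j + β_jᵀ g(L) + ξ with g(L) = (L, L²) (30 candidate terms) is
   selected by bidirectional stepwise search under BIC, starting from the
   intercept-only model, adding or dropping the single best term per step.
   BIC is computed from the residual sum of squares with the residual
   variance floored at 10⁻¹² · var(θ_j), so an (exactly) interpolating fit
   terminates instead of churning on rounding noise. The derived summary is
   S_j(y) = β̂_jᵀ g(L) — without the intercept, which cancels in the
   difference S_obs − S_sim.
4. **Covariance.** W is the sample covariance of the derived summaries of
   n_cal (default 100) simulations at the regression-predicted posterior
   mean θ̂ = α̂ + β̂ᵀ g(L_obs), clipped into the prior support. If the
   smallest eigenvalue falls below ε = 10⁻⁸ tr(W)/J, εI is added.
5. **Discrepancy.** ρ(y_obs, y_sim) = (S_obs − S_sim)ᵀ W⁻¹ (S_obs − S_sim).

The calibration simulations are retained: a quantile of
ρ(S_obs, S_cal,i) over them (`calibrate_eps_final`) provides a target
tolerance that is attainable by construction and tracks both the scale of
W and any bias in θ̂. This is how desk-scale runs choose ε_final (the 0.6
quantile, trading a slightly broader posterior for far fewer model
simulations per run); a fixed ε_final can always be passed instead.

## Samplers

All samplers target π(θ | ρ ≤ ε) for particle systems of size N
(default 1,000):

* **rejection** — prior draws, keep the smallest-ρ fraction.
* **ASMC** (the package's main sampler) — adaptive tolerances with
  importance re-weighting. Each iteration drops the fraction α (default
  0.5) of particles with the largest ρ, sets ε_k to the largest surviving
  ρ (clamped to ε_final on the last round), and replenishes by
  resample-from-weights → Gaussian perturbation (covariance twice the
  weighted survivor covariance) → simulate → accept if ρ ≤ ε_k. A new
  particle's weight is π(θ) / Σ_j W_j K_k(θ | θ_j) — the weighted
  kernel-mixture importance ratio. Particles carry these raw ratios
  (prior draws carry 1) and weights are normalised on use; for cross-
  generation comparability, prior densities are properly normalised
  (the uniform box returns 1/volume; the truncated bivariate-normal prior
  estimates its truncation mass by a cached fixed-seed Monte Carlo).
  Proposals outside the prior support are rejected before any simulation
  is spent. The run stops at ε_final or when the replenishment acceptance
  rate falls below 1% over a 1,000-attempt window (returned flagged
  incomplete).
* **RSMC** — the MCMC-kernel replenishment baseline: same adaptive
  tolerances; dropped particles are resampled uniformly from survivors and
  moved through R_t MCMC-ABC steps, with R_t = ⌈log 0.01 / log(1−p̂)⌉
  tuned from the first pass's acceptance rate; equal weights throughout.
  Duplicated particles (its documented drawback) reappear when the repeat
  count is forced to zero.
* **APMC** — the population Monte Carlo baseline: one
  resample-perturb-simulate pass per iteration (no acceptance test),
  merged with the population keeping the best N by ρ, newcomers weighted
  by the same mixture ratio; its implied tolerance may fluctuate.

Posterior summaries are weighted: mean, 90% credible interval as 5th/95th
weighted percentiles (left-continuous inverse CDF), CV = sd/|mean|,
MCSE = sd/√ESS with Kish's ESS = 1/Σw², pairwise correlations, and the
generalized variance (determinant of the weighted covariance). When a
lattice config is supplied, P_m and P_p coordinates are first rescaled to D
and λ.

## Sequential learning

Two-period inference draws stage-1 (D, q) afresh per simulation from a
bivariate normal fitted (weighted) to the first-period posterior — thereby
marginalising first-period uncertainty — runs the colony to the period
boundary, switches to the stage-2 parameters under inference, and matches
on the terminal summaries. Cross-scenario learning converts the
(D, q)-scale bivariate normal to the (P_m, q) probability scale (an exact
linear map), multiplies by a uniform prior on P_p, truncates to the
admissible box, and runs plain ASMC under that prior; with a flat prior
this reduces exactly to the uninformative analysis. Bivariate normality is
diagnosed by a Q-Q plot of χ²(2) quantiles against ordered squared
Mahalanobis distances at weighted plotting positions.

## Synthetic data and problem sizes

The validation configuration generates three replicate colonies at
(P_m, q, P_p) = (0.1, 0.2, 0.0012) — that is (D, q, λ) =
(202.5 µm² h⁻¹, 0.2, 0.03 h⁻¹) — with C(0) = 20,000 for T = 24 h at full
scale. Scaled variants shrink width and seeding radius linearly and C(0)
quadratically, preserving the initial density; sub-region windows scale
linearly (10 × 7 sites at the default desk scale 0.25: width 217,
radius 44, C(0) = 1,250).

The package's own desk-scale study sizes, used by the test suite:

* pilot: 330 simulations over 3 rounds, keep fraction 0.08, inflation 0.2;
* training: M = 500; calibration: n_cal = 32; ε_final = the 0.6 quantile of
  the calibrated reference discrepancies;
* ASMC: N = 80 particles; recovery assessed over 10 regenerated datasets,
  with W and ε_final recalibrated per dataset.
* The training region and ASMC prior keep the pilot's bound only on the
  proliferation axis, which the pilot identifies decisively; motility and
  adhesion retain their uninformative U(0,1) priors. Iterating the pilot
  box on all axes narrows *along* the weakly identified D–q ridge and can
  truncate its ends, which destroys interval coverage for ridge-end
  parameter values — constraining only the decisively identified axis
  avoids that failure mode while keeping simulations affordable.

What desk scale does *not* show: quarter-scale windows hold ~15× fewer
agents than the experimental 39 × 28-site windows, so the adhesion
parameter q is only weakly identified and its posterior stays broad;
full-scale magnitudes (e.g. total simulation counts of the samplers on the
colony problem) require the 867² lattice and cluster-sized budgets. Desk
scale asserts orderings and coverage, not magnitudes.

The conjugate toy problem (uniform prior on a normal mean, summary =
sample mean, known noise) provides an analytic ABC-posterior oracle by
quadrature for any tolerance; all four samplers are required to agree with
it within Monte Carlo error.

## Numerical choices and limitations

* Weighted quantiles use the left-continuous inverse CDF: deterministic
  and order-independent.
* The perturbation covariance is floored at 10⁻¹² tr/J to stay Cholesky-
  decomposable when survivors nearly coincide.
* Empty-window isolated fractions are defined as 0; degenerate pilot
  summary components (zero spread) are dropped from the pilot distance
  with a warning.
* The regression-predicted θ̂ may fall outside [0,1]; it is clipped (with a
  warning) before calibration — θ̂ is only a calibration point.
* The simulator is approximate RSU, not exact continuous-time dynamics;
  τ = 0.04 h is adopted as the operating step throughout.
* Real-image segmentation is out of scope: the package consumes occupancy
  grids or already-tabulated summary CSVs, not micrographs.
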