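"""Synthetic datasets for validating the inference pipeline.

The full-scale validation configuration mirrors the barrier assay: an
867-site lattice (15.6 mm well at 18 µm spacing), 20,000 cells seeded in a
disc of radius 177 sites, generating parameters (P_m, q, P_p) =
(0.1, 0.2, 0.0012) — i.e. D = 202.5 µm² h⁻¹, q = 0.2, lambda = 0.03 h⁻¹ —
observed at T = 24 h with three replicates.

Scaled-down variants shrink the lattice width, seeding radius and initial
cell count together so that the initial density C(0) / (disc area) is
preserved; summary behaviour then transfers qualitatively while a full ABC
run stays cheap.  The default desk scale is 0.25: width 217, radius 44,
C(0) = 1,250, sub-region windows 10 x 7 sites.

A conjugate Gaussian toy problem (uniform prior on a normal mean, summary =
sample mean) provides an analytic ABC-posterior oracle for checking the
samplers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .colony_model import (
    ColonyState,
    LatticeConfig,
    ModelParams,
    disc_site_coordinates,
    simulate,
)
from .summaries import PilotSummary, SubRegionLayout, default_layout, pilot_summary

__all__ = [
    "ScaledScenario",
    "scaled_scenario",
    "ColonyPilotSimulator",
    "make_validation_dataset",
    "make_scenario_pair",
    "ToyProblem",
    "make_toy_problem",
]

#: generating parameters of the validation study
VALIDATION_PARAMS = ModelParams(motility_prob=0.1, adhesion=0.2, proliferation_prob=0.0012)

_FULL_WIDTH = 867
_FULL_RADIUS = 177
_FULL_COUNT = 20_000
_FULL_WINDOW = (39, 28)  # (width, height) in sites


@dataclass(frozen=True)
class ScaledScenario:
    """A validation configuration shrunk by a linear factor ``scale``.

    The lattice width and seeding radius scale linearly and the initial
    count quadratically, preserving the seeding density; sub-region windows
    scale linearly in both directions.
    """

    scale: float
    cfg: LatticeConfig
    layout: SubRegionLayout
    params: ModelParams
    n_replicates: int = 3

    @property
    def initial_density(self) -> float:
        return self.cfg.initial_count / len(disc_site_coordinates(self.cfg))


def scaled_scenario(
    scale: float = 1.0,
    params: ModelParams = VALIDATION_PARAMS,
    observation_times_h: tuple[float, ...] = (24.0,),
    n_replicates: int = 3,
) -> ScaledScenario:
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    width = int(round(_FULL_WIDTH * scale))
    radius = int(round(_FULL_RADIUS * scale))
    count = int(round(_FULL_COUNT * scale**2))
    cfg = LatticeConfig(
        width_sites=width,
        initial_count=count,
        initial_radius_sites=radius,
        observation_times_h=observation_times_h,
    )
    win_w = max(2, int(round(_FULL_WINDOW[0] * scale)))
    win_h = max(2, int(round(_FULL_WINDOW[1] * scale)))
    layout = default_layout(cfg, window_width=win_w, window_height=win_h)
    return ScaledScenario(scale=scale, cfg=cfg, layout=layout, params=params, n_replicates=n_replicates)


@dataclass
class ColonyPilotSimulator:
    """Maps a parameter vector to the 15-dimensional pilot summary L by
    simulating the replicate colonies.

    ``param_names`` selects which of (Pm, q, Pp) are free (in that order);
    the rest are pinned at ``fixed``.  ``schedule_times`` gives the stage
    end times; all stages share the free parameters unless a
    ``stage_params_fn`` hook supplies per-stage parameters (used for
    two-stage sequential designs).
    """

    cfg: LatticeConfig
    layout: SubRegionLayout
    n_replicates: int = 3
    param_names: tuple[str, ...] = ("Pm", "q", "Pp")
    fixed: dict = field(default_factory=dict)
    closing_radius: int = 3

    def params_from_vector(self, theta: np.ndarray) -> ModelParams:
        vals = dict(self.fixed)
        for name, v in zip(self.param_names, np.asarray(theta, dtype=float)):
            vals[name] = float(min(1.0, max(0.0, v)))
        return ModelParams(
            motility_prob=vals.get("Pm", 0.0),
            adhesion=vals.get("q", 0.0),
            proliferation_prob=vals.get("Pp", 0.0),
        )

    def simulate_states(self, theta: np.ndarray, seed: int) -> list[ColonyState]:
        params = self.params_from_vector(theta)
        end = max(self.cfg.observation_times_h)
        rep_seeds = np.random.SeedSequence(seed).generate_state(self.n_replicates)
        return [
            simulate([(end, params)], self.cfg, int(s) % 2**31)[-1] for s in rep_seeds
        ]

    def pilot_vector(self, theta: np.ndarray, seed: int) -> np.ndarray:
        states = self.simulate_states(theta, seed)
        return pilot_summary(
            states, self.layout, self.cfg, closing_radius=self.closing_radius
        ).as_vector()

    def __call__(self, theta: np.ndarray, seed: int) -> np.ndarray:
        return self.pilot_vector(theta, seed)


def make_validation_dataset(
    seed: int, scale: float = 1.0, params: ModelParams = VALIDATION_PARAMS
) -> tuple[list[ColonyState], PilotSummary, ScaledScenario]:
    """Generate the validation dataset: three replicate colonies at the
    given parameters, observed at 24 h, plus their pilot summary."""
    scen = scaled_scenario(scale=scale, params=params)
    end = max(scen.cfg.observation_times_h)
    rep_seeds = np.random.SeedSequence(seed).generate_state(scen.n_replicates)
    states = [
        simulate([(end, params)], scen.cfg, int(s) % 2**31)[-1] for s in rep_seeds
    ]
    summary = pilot_summary(states, scen.layout, scen.cfg)
    return states, summary, scen


def make_scenario_pair(
    seed: int,
    scale: float,
    diffusivity: float,
    adhesion: float,
    proliferation_rate: float,
    observation_times_h: tuple[float, ...] = (24.0,),
):
    """Two datasets sharing (D, q): proliferation suppressed (scenario 1,
    lambda = 0) and proliferating (scenario 2, the given lambda).  Returns
    ((states1, summary1), (states2, summary2), (scen1, scen2))."""
    from .colony_model import RateParams, params_from_rates

    base_cfg = scaled_scenario(scale=scale, observation_times_h=observation_times_h).cfg
    p1 = params_from_rates(
        RateParams(diffusivity=diffusivity, proliferation_rate=0.0, adhesion=adhesion),
        base_cfg,
    )
    p2 = params_from_rates(
        RateParams(
            diffusivity=diffusivity,
            proliferation_rate=proliferation_rate,
            adhesion=adhesion,
        ),
        base_cfg,
    )
    scen1 = scaled_scenario(scale=scale, params=p1, observation_times_h=observation_times_h)
    scen2 = scaled_scenario(scale=scale, params=p2, observation_times_h=observation_times_h)
    ss = np.random.SeedSequence(seed)
    out = []
    for scen, child in zip((scen1, scen2), ss.spawn(2)):
        end = max(scen.cfg.observation_times_h)
        rep_seeds = child.generate_state(scen.n_replicates)
        states = [
            simulate([(end, scen.params)], scen.cfg, int(s) % 2**31)[-1]
            for s in rep_seeds
        ]
        out.append((states, pilot_summary(states, scen.layout, scen.cfg)))
    return out[0], out[1], (scen1, scen2)


@dataclass
class ToyProblem:
    """Conjugate Gaussian test-bed for the ABC samplers.

    The simulator draws ``n_obs`` values from N(mu, noise_sd²) and returns
    their mean.  With a uniform prior on mu and acceptance rule
    ``(s - s_obs)² / w <= eps`` the ABC posterior density is available in
    closed form up to normalisation:

        pi_eps(mu) ∝ Phi((s_obs + h - mu)/se) - Phi((s_obs - h - mu)/se)

    with ``h = sqrt(eps * w)`` and ``se = noise_sd / sqrt(n_obs)``, which
    the oracle integrates numerically.
    """

    n_obs: int
    true_mean: float
    noise_sd: float
    s_obs: float
    prior_low: float
    prior_high: float
    summary_variance: float  # w used in the scalar Mahalanobis distance

    @property
    def se(self) -> float:
        return self.noise_sd / np.sqrt(self.n_obs)

    def simulate_summary(self, theta: np.ndarray, seed: int) -> np.ndarray:
        mu = float(np.atleast_1d(theta)[0])
        rng = np.random.default_rng(seed)
        return np.array([rng.normal(mu, self.noise_sd, self.n_obs).mean()])

    def __call__(self, theta: np.ndarray, seed: int) -> np.ndarray:
        return self.simulate_summary(theta, seed)

    def posterior_moments(self, eps: float, n_grid: int = 20_001) -> tuple[float, float]:
        """Exact mean and variance of the ABC posterior at tolerance
        ``eps`` (squared-distance scale), by quadrature on a fine grid."""
        mu = np.linspace(self.prior_low, self.prior_high, n_grid)
        if np.isinf(eps):
            dens = np.ones_like(mu)
        else:
            h = np.sqrt(eps * self.summary_variance)
            dens = stats.norm.cdf((self.s_obs + h - mu) / self.se) - stats.norm.cdf(
                (self.s_obs - h - mu) / self.se
            )
        z = np.trapezoid(dens, mu)
        mean = np.trapezoid(mu * dens, mu) / z
        var = np.trapezoid((mu - mean) ** 2 * dens, mu) / z
        return float(mean), float(var)

    def exact_posterior_moments(self) -> tuple[float, float]:
        """Limit eps -> 0: the conjugate posterior restricted to the prior."""
        mu = np.linspace(self.prior_low, self.prior_high, 20_001)
        dens = stats.norm.pdf(self.s_obs, loc=mu, scale=self.se)
        z = np.trapezoid(dens, mu)
        mean = np.trapezoid(mu * dens, mu) / z
        var = np.trapezoid((mu - mean) ** 2 * dens, mu) / z
        return float(mean), float(var)


def make_toy_problem(
    n_obs: int = 25,
    true_mean: float = 0.3,
    noise_sd: float = 1.0,
    seed: int = 0,
    prior_bounds: tuple[float, float] = (-2.0, 2.0),
) -> ToyProblem:
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    rng = np.random.default_rng(seed)
    s_obs = float(rng.normal(true_mean, noise_sd, n_obs).mean())
    return ToyProblem(
        n_obs=n_obs,
        true_mean=true_mean,
        noise_sd=noise_sd,
        s_obs=s_obs,
        prior_low=prior_bounds[0],
        prior_high=prior_bounds[1],
        summary_variance=noise_sd**2 / n_obs,
    )
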