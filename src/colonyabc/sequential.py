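"""Sequential Bayesian learning across time periods and experimental
scenarios.

Two uses of an existing ABC posterior:

* **Period-specific parameters.**  To infer motility and adhesion for the
  24-48 h window, simulations run in two stages: stage-1 parameters are
  drawn (freshly, per simulation) from a bivariate normal fitted to the
  0-24 h posterior of (D, q); stage-2 parameters are the inference target,
  matched on the 48 h summaries.
* **Cross-scenario priors.**  The (D, q) posterior from a
  proliferation-suppressed experiment, refitted as a bivariate normal,
  becomes an informative prior — multiplied by a uniform prior on the
  proliferation rate — for the proliferating experiment.

Bivariate normality of a posterior is diagnosed with a Q-Q plot of
chi-square(2 df) quantiles against the ordered squared Mahalanobis
distances of the particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .abc_samplers import ParticleSystem, asmc, rescale_to_rates
from .colony_model import LatticeConfig, ModelParams, simulate
from .priors import BvnUniformPrior, UniformBoxPrior
from .summaries import SubRegionLayout, pilot_summary

__all__ = [
    "BivariateNormalPrior",
    "fit_bvn",
    "qq_mahalanobis",
    "TwoStagePilotSimulator",
    "infer_second_period",
    "scenario2_sequential",
]


@dataclass(frozen=True)
class BivariateNormalPrior:
    """Bivariate normal approximation of a joint posterior of two fields."""

    mean: np.ndarray
    cov: np.ndarray
    fields: tuple[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (2, 2) or not np.allclose(cov, cov.T, atol=1e-12):
            raise ValueError("covariance must be symmetric 2x2")
        if np.linalg.eigvalsh(cov).min() < -1e-9 * max(np.trace(cov), 1.0):
            raise ValueError("covariance must be positive semi-definite")

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        # PSD covariance allowed: a zero matrix degenerates to a point mass
        return rng.multivariate_normal(
            self.mean, self.cov, size=n, check_valid="ignore"
        )

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "fields": list(self.fields),
            "source": self.source,
        }


def fit_bvn(
    system: ParticleSystem,
    fields: tuple[str, str] = ("D", "q"),
    cfg: LatticeConfig | None = None,
    min_ess: float = 30.0,
    source: str = "",
) -> BivariateNormalPrior:
    """Weighted bivariate normal fit to two posterior coordinates.

    With a lattice config, particle coordinates are first rescaled to the
    (D, q, lambda) rate scale so the fit lives on the biological scale.
    """
    if system.ess < min_ess:
        raise ValueError(f"ESS={system.ess:.1f} below the minimum {min_ess}")
    if cfg is not None:
        values, names = rescale_to_rates(system, cfg)
    else:
        values = system.params
        names = system.param_names
    idx = [names.index(f) for f in fields]
    sub = values[:, idx]
    w = system.weights
    mean = w @ sub
    centred = sub - mean
    cov = (centred * w[:, None]).T @ centred
    # a point-mass posterior (all weight on one particle) has no spread to fit
    if not np.all(np.isfinite(cov)) or np.trace(cov) <= 1e-12 * (1.0 + mean @ mean):
        raise ValueError("degenerate posterior: weighted covariance is (numerically) zero")
    return BivariateNormalPrior(mean=mean, cov=cov, fields=fields, source=source)


def qq_mahalanobis(
    system: ParticleSystem,
    bvn: BivariateNormalPrior,
    cfg: LatticeConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Q-Q diagnostic of bivariate normality.

    Returns (theoretical chi-square(2) quantiles at weighted plotting
    positions, ordered squared Mahalanobis distances, linear correlation of
    the Q-Q points).  Correlations near 1 support the normal approximation;
    heavy-tailed posteriors push the upper-tail points above the identity.
    """
    if system.n_particles < 2:
        raise ValueError("need at least two particles for a Q-Q diagnostic")
    if cfg is not None:
        values, names = rescale_to_rates(system, cfg)
    else:
        values = system.params
        names = system.param_names
    idx = [names.index(f) for f in bvn.fields]
    sub = values[:, idx]
    inv = np.linalg.inv(bvn.cov)
    diff = sub - bvn.mean
    d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
    order = np.argsort(d2)
    d2_sorted = d2[order]
    w_sorted = system.weights[order]
    cum = np.cumsum(w_sorted)
    positions = np.clip(cum - w_sorted / 2.0, 1e-12, 1 - 1e-12)
    theo = stats.chi2.ppf(positions, df=2)
    corr = float(np.corrcoef(theo, d2_sorted)[0, 1])
    return theo, d2_sorted, corr


@dataclass
class TwoStagePilotSimulator:
    """theta -> 15-vector pilot summary for a two-period design.

    Each model simulation first draws stage-1 parameters from the fitted
    bivariate normal of the earlier period (a fresh draw per simulation, so
    stage-1 uncertainty is marginalised), runs the colony to the period
    boundary, then continues with the stage-2 parameters under inference
    until the terminal time.
    """

    cfg: LatticeConfig
    layout: SubRegionLayout
    stage1_prior: BivariateNormalPrior  # on the (D, q) rate scale
    boundary_h: float = 24.0
    terminal_h: float = 48.0
    n_replicates: int = 3
    param_names: tuple[str, ...] = ("Pm", "q")
    fixed: dict = field(default_factory=dict)
    closing_radius: int = 3
    max_stage1_rejection: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.boundary_h < self.terminal_h:
            raise ValueError("need 0 < boundary < terminal time")

    def _draw_stage1(self, rng: np.random.Generator) -> ModelParams:
        """Draw (D, q) from the bivariate normal and convert to per-step
        probabilities, rejecting draws outside the admissible range."""
        dq_max = self.cfg.max_diffusivity
        batch = self.stage1_prior.sample(rng, 200)
        ok = (
            (batch[:, 0] >= 0.0)
            & (batch[:, 0] <= dq_max)
            & (batch[:, 1] >= 0.0)
            & (batch[:, 1] <= 1.0)
        )
        if ok.mean() < 1.0 - self.max_stage1_rejection:
            raise ValueError(
                "stage-1 bivariate normal places most of its mass outside the "
                "admissible (D, q) range"
            )
        d, q = batch[ok][0]
        pm = 4.0 * d * self.cfg.step_h / self.cfg.spacing_um**2
        return ModelParams(
            motility_prob=pm,
            adhesion=q,
            proliferation_prob=self.fixed.get("Pp", 0.0),
        )

    def _stage2_params(self, theta: np.ndarray) -> ModelParams:
        vals = dict(self.fixed)
        for name, v in zip(self.param_names, np.asarray(theta, dtype=float)):
            vals[name] = float(min(1.0, max(0.0, v)))
        return ModelParams(
            motility_prob=vals.get("Pm", 0.0),
            adhesion=vals.get("q", 0.0),
            proliferation_prob=vals.get("Pp", 0.0),
        )

    def pilot_vector(self, theta: np.ndarray, seed: int) -> np.ndarray:
        stage2 = self._stage2_params(theta)
        ss = np.random.SeedSequence(seed)
        rng = np.random.default_rng(ss.spawn(1)[0])
        rep_seeds = ss.generate_state(self.n_replicates)
        states = []
        for s in rep_seeds:
            stage1 = self._draw_stage1(rng)
            schedule = [(self.boundary_h, stage1), (self.terminal_h, stage2)]
            states.append(simulate(schedule, self.cfg, int(s) % 2**31)[-1])
        return pilot_summary(
            states, self.layout, self.cfg, closing_radius=self.closing_radius
        ).as_vector()

    def __call__(self, theta: np.ndarray, seed: int) -> np.ndarray:
        return self.pilot_vector(theta, seed)


def infer_second_period(
    stage1_prior: BivariateNormalPrior,
    S_obs_terminal: np.ndarray,
    projection,
    W: np.ndarray,
    cfg: LatticeConfig,
    layout: SubRegionLayout,
    uniform_prior: UniformBoxPrior | None = None,
    boundary_h: float = 24.0,
    terminal_h: float = 48.0,
    n_replicates: int = 3,
    seed: int = 0,
    **asmc_kwargs,
) -> ParticleSystem:
    """Infer period-specific (P_m, q) for the second period with ASMC.

    ``S_obs_terminal`` are the observed derived summaries at the terminal
    time and ``projection`` the fitted projection model used for matching;
    stage-1 parameters are marginalised by fresh bivariate-normal draws.
    """
    if uniform_prior is None:
        uniform_prior = UniformBoxPrior((0.0, 0.0), (1.0, 1.0), ("Pm", "q"))
    two_stage = TwoStagePilotSimulator(
        cfg=cfg,
        layout=layout,
        stage1_prior=stage1_prior,
        boundary_h=boundary_h,
        terminal_h=terminal_h,
        n_replicates=n_replicates,
        param_names=uniform_prior.names or ("Pm", "q"),
    )

    def simulate_S(theta, sim_seed):
        return projection.project(two_stage.pilot_vector(theta, sim_seed))

    return asmc(S_obs_terminal, uniform_prior, simulate_S, W, seed=seed, **asmc_kwargs)


def scenario2_sequential(
    informative_prior,
    S_obs: np.ndarray,
    simulate_S,
    W: np.ndarray,
    seed: int = 0,
    **asmc_kwargs,
) -> ParticleSystem:
    """ASMC under the sequential-learning prior: a bivariate normal on
    motility and adhesion (carried over from the proliferation-suppressed
    scenario) times a uniform prior on the proliferation probability.

    ``informative_prior`` is typically a :class:`~colonyabc.priors.BvnUniformPrior`;
    any prior object works, and passing a flat uniform prior reduces this
    exactly to a plain ASMC run.
    """
    return asmc(S_obs, informative_prior, simulate_S, W, seed=seed, **asmc_kwargs)


def bvn_prior_on_probability_scale(
    bvn: BivariateNormalPrior,
    cfg: LatticeConfig,
    pp_bounds: tuple[float, float] = (0.0, 1.0),
) -> BvnUniformPrior:
    """Convert a (D, q)-scale bivariate normal into the (P_m, q, P_p)
    probability-scale prior used by the samplers: the linear map
    P_m = 4 tau D / Delta² transforms mean and covariance exactly; P_p gets
    an independent uniform prior and the whole prior is truncated to the
    admissible box."""
    a = 4.0 * cfg.step_h / cfg.spacing_um**2
    scale = np.diag([a, 1.0])
    mean = scale @ np.asarray(bvn.mean)
    cov = scale @ np.asarray(bvn.cov) @ scale.T
    return BvnUniformPrior(
        mean=(float(mean[0]), float(mean[1])),
        cov=tuple(map(tuple, cov)),
        lows=(0.0, 0.0, pp_bounds[0]),
        highs=(1.0, 1.0, pp_bounds[1]),
        names=("Pm", "q", "Pp"),
    )
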