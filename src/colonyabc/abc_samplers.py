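"""Sequential Monte Carlo ABC samplers.

All samplers target the ABC posterior pi(theta | rho(y_obs, y_sim) <= eps)
where rho is the squared Mahalanobis discrepancy between derived summary
vectors.  Implemented:

* ``rejection_abc`` — sample from the prior, keep the smallest-discrepancy
  fraction;
* ``asmc`` — adaptive SMC: tolerances are set automatically each iteration
  by dropping the worst-discrepancy fraction of particles, and the dropped
  particles are replenished by resample / Gaussian-perturb / simulate with
  importance re-weighting

      W_k  ∝  pi(theta_k) / sum_j W_j^{k-1} K_k(theta_k | theta_j^{k-1}),

  which avoids the duplicated particles of MCMC-kernel replenishment;
* ``rsmc`` — replenishment SMC baseline: same adaptive tolerances, but
  dropped particles are replaced by resampling and moving through repeated
  MCMC-ABC steps (equal weights throughout);
* ``apmc`` — adaptive population Monte Carlo baseline: one
  resample-perturb-simulate pass per iteration, merged with the current
  population keeping the best N by discrepancy, so the tolerance sequence
  may fluctuate.

The perturbation kernel throughout is Gaussian with covariance twice the
weighted empirical covariance of the current particles; proposals outside
the prior support are rejected before any model simulation is spent.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .semiauto import discrepancy

__all__ = [
    "ParticleSystem",
    "PosteriorSummary",
    "rejection_abc",
    "reweight",
    "asmc",
    "rsmc",
    "apmc",
    "ess_kish",
    "weighted_quantile",
    "posterior_summary",
]


@dataclass
class ParticleSystem:
    """N weighted parameter vectors with discrepancies and run metadata."""

    params: np.ndarray  # (N, J)
    weights: np.ndarray  # normalised to sum 1
    discrepancies: np.ndarray
    tolerance_history: list[float] = field(default_factory=list)
    simulation_count: int = 0
    iteration: int = 0
    complete: bool = True
    param_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        self.discrepancies = np.asarray(self.discrepancies, dtype=float)
        total = self.weights.sum()
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            self.weights = self.weights / total

    @property
    def n_particles(self) -> int:
        return self.params.shape[0]

    @property
    def ess(self) -> float:
        return ess_kish(self.weights)

    def to_csv(self, path, cfg=None) -> None:
        names = self.param_names or tuple(f"theta{j}" for j in range(self.params.shape[1]))
        df = pd.DataFrame(self.params, columns=list(names))
        if cfg is not None:
            if "Pm" in names:
                df["D"] = df["Pm"] * cfg.spacing_um**2 / (4 * cfg.step_h)
            if "Pp" in names:
                df["lambda"] = df["Pp"] / cfg.step_h
        df["weight"] = self.weights
        df["discrepancy"] = self.discrepancies
        df.to_csv(path, index=False)

    def sidecar(self) -> dict:
        return {
            "tolerance_history": list(map(float, self.tolerance_history)),
            "simulation_count": int(self.simulation_count),
            "iteration": int(self.iteration),
            "complete": bool(self.complete),
            "param_names": list(self.param_names),
        }


def ess_kish(weights: np.ndarray) -> float:
    """Kish's effective sample size 1 / sum(w_i^2) for normalised weights."""
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if not math.isclose(total, 1.0, rel_tol=1e-9):
        warnings.warn("weights were not normalised; normalising internally")
        w = w / total
    return float(1.0 / (w**2).sum())


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q) -> np.ndarray:
    """Left-continuous inverse of the weighted empirical CDF."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values)
    v = values[order]
    cw = np.cumsum(weights[order])
    cw = cw / cw[-1]
    q = np.atleast_1d(q)
    idx = np.searchsorted(cw, q, side="left")
    idx = np.clip(idx, 0, len(v) - 1)
    out = v[idx]
    return out if out.size > 1 else float(out[0])


def _simulate_rho(simulator, theta, seed, S_obs, W):
    S_sim = simulator(theta, seed)
    return discrepancy(S_obs, S_sim, W)


def rejection_abc(
    S_obs: np.ndarray,
    prior,
    simulator,
    W: np.ndarray,
    budget: int = 10_000,
    keep: float = 0.01,
    seed: int = 0,
    param_names: tuple[str, ...] = (),
) -> ParticleSystem:
    """Prior sampling; keep the fraction with the smallest discrepancy."""
    if not 0.0 < keep <= 1.0:
        raise ValueError("keep must be in (0, 1]")
    rng = np.random.default_rng(seed)
    thetas = prior.sample(rng, budget)
    seeds = rng.integers(0, 2**31, size=budget)
    rhos = np.array(
        [_simulate_rho(simulator, t, int(s), S_obs, W) for t, s in zip(thetas, seeds)]
    )
    n_keep = max(1, int(round(keep * budget)))
    order = np.argsort(rhos)[:n_keep]
    return ParticleSystem(
        params=thetas[order],
        weights=np.full(n_keep, 1.0 / n_keep),
        discrepancies=rhos[order],
        tolerance_history=[float(rhos[order].max())],
        simulation_count=budget,
        param_names=param_names or getattr(prior, "names", ()),
    )


def _kernel_cov(params: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Twice the weighted empirical covariance, floored to stay invertible."""
    mean = weights @ params
    centred = params - mean
    cov = (centred * weights[:, None]).T @ centred
    cov = 2.0 * cov
    J = cov.shape[0]
    floor = 1e-12 * max(np.trace(cov) / J, 1e-12)
    if np.linalg.eigvalsh(cov).min() < floor:
        cov = cov + floor * np.eye(J)
    return cov


def _mixture_density(theta: np.ndarray, particles: np.ndarray, weights: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Weighted Gaussian-kernel mixture density of ``theta`` rows."""
    theta = np.atleast_2d(theta)
    inv = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    d = cov.shape[0]
    # (n_theta, n_particles) pairwise quadratic forms
    diff = theta[:, None, :] - particles[None, :, :]
    quad = np.einsum("nij,jk,nik->ni", diff, inv, diff)
    log_kernel = -0.5 * (quad + logdet + d * np.log(2 * np.pi))
    return (np.exp(log_kernel) * weights[None, :]).sum(axis=1)


def reweight(
    theta_new: np.ndarray,
    prev_params: np.ndarray,
    prev_weights: np.ndarray,
    kernel_cov: np.ndarray,
    prior,
) -> np.ndarray:
    """Importance weights for freshly proposed particles:
    prior density over the weighted kernel-mixture density (unnormalised)."""
    theta_new = np.atleast_2d(theta_new)
    w = np.asarray(prev_weights, dtype=float)
    w = w / w.sum()
    prior_dens = np.atleast_1d(prior.pdf(theta_new)).astype(float)
    mix = _mixture_density(theta_new, np.atleast_2d(prev_params), w, kernel_cov)
    out = np.zeros(len(theta_new))
    ok = mix > 0
    if not ok.all():
        warnings.warn("zero kernel-mixture density encountered; weight set to 0")
    out[ok] = prior_dens[ok] / mix[ok]
    return out


def asmc(
    S_obs: np.ndarray,
    prior,
    simulator,
    W: np.ndarray,
    n_particles: int = 1000,
    drop_fraction: float = 0.5,
    eps_final: float = 0.1,
    stall_acceptance: float = 0.01,
    stall_window: int = 1000,
    max_simulations: int | None = None,
    seed: int = 0,
    param_names: tuple[str, ...] = (),
    verbose: bool = False,
) -> ParticleSystem:
    """Adaptive SMC-ABC with automatic tolerances and importance
    re-weighting of replenished particles.

    Each iteration drops the ``drop_fraction`` of particles with the
    largest discrepancy, sets the new tolerance to the largest surviving
    discrepancy, and replenishes by resampling survivors, perturbing with a
    Gaussian kernel (covariance twice the weighted survivor covariance),
    simulating, and accepting only proposals with rho <= eps_k.  New
    particles receive the mixture importance weights; iteration stops once
    eps_k <= ``eps_final`` (clamped to it for the final replenishment) or
    when the replenishment acceptance rate stalls.
    """
    rng = np.random.default_rng(seed)
    names = param_names or getattr(prior, "names", ())

    params = prior.sample(rng, n_particles)
    seeds = rng.integers(0, 2**31, size=n_particles)
    rhos = np.array(
        [_simulate_rho(simulator, t, int(s), S_obs, W) for t, s in zip(params, seeds)]
    )
    # raw importance ratios: prior draws have ratio 1; replenished particles
    # get prior/mixture from the re-weighting formula.  Normalised on use.
    raw_w = np.ones(n_particles)
    sim_count = n_particles
    tol_history: list[float] = []
    complete = True
    iteration = 0

    if np.isinf(eps_final):
        return ParticleSystem(
            params, raw_w, rhos, [float(rhos.max())], sim_count, 0, True, names
        )

    n_drop = int(round(drop_fraction * n_particles))
    n_keep = n_particles - n_drop

    while True:
        iteration += 1
        order = np.argsort(rhos)
        eps_k = float(rhos[order[n_keep - 1]])
        final_round = eps_k <= eps_final
        if final_round:
            eps_k = eps_final
            keep_mask = rhos <= eps_k
        else:
            keep_mask = np.zeros(n_particles, dtype=bool)
            keep_mask[order[:n_keep]] = True
        tol_history.append(eps_k)

        surv_params = params[keep_mask]
        surv_rhos = rhos[keep_mask]
        surv_raw = raw_w[keep_mask]
        surv_w = surv_raw / surv_raw.sum()
        n_new = n_particles - len(surv_params)
        if n_new == 0:
            params, rhos, raw_w = surv_params, surv_rhos, surv_raw
            break

        cov = _kernel_cov(surv_params, surv_w)
        new_params = np.empty((n_new, params.shape[1]))
        new_rhos = np.empty(n_new)
        filled = 0
        attempts = 0
        window_attempts = 0
        window_accepts = 0
        stalled = False
        lo, hi = prior.bounds
        chol = np.linalg.cholesky(cov)
        while filled < n_new:
            idx = rng.choice(len(surv_params), p=surv_w)
            proposal = surv_params[idx] + chol @ rng.standard_normal(params.shape[1])
            if np.any(proposal < lo) or np.any(proposal > hi) or prior.pdf(proposal)[0] <= 0:
                continue  # no simulation spent on inadmissible proposals
            attempts += 1
            window_attempts += 1
            rho = _simulate_rho(simulator, proposal, int(rng.integers(0, 2**31)), S_obs, W)
            sim_count += 1
            if rho <= eps_k:
                new_params[filled] = proposal
                new_rhos[filled] = rho
                filled += 1
                window_accepts += 1
            if window_attempts >= stall_window:
                if window_accepts / window_attempts < stall_acceptance:
                    stalled = True
                    break
                window_attempts = 0
                window_accepts = 0
            if max_simulations is not None and sim_count >= max_simulations:
                stalled = True
                break

        new_params = new_params[:filled]
        new_rhos = new_rhos[:filled]
        if filled:
            new_raw = reweight(new_params, surv_params, surv_w, cov, prior)
            params = np.vstack([surv_params, new_params])
            rhos = np.concatenate([surv_rhos, new_rhos])
            raw_w = np.concatenate([surv_raw, new_raw])
        else:
            params, rhos, raw_w = surv_params, surv_rhos, surv_raw

        if stalled:
            warnings.warn(
                f"ASMC stalled at eps={eps_k:.4g} before reaching eps_final={eps_final:.4g}"
            )
            complete = False
            break
        if verbose:
            acc = filled / max(attempts, 1)
            print(
                f"  ASMC iter {iteration}: eps={eps_k:.4g} acc={acc:.3f} "
                f"sims={sim_count} ESS={ess_kish(raw_w / raw_w.sum()):.0f}"
            )
        if final_round:
            break

    return ParticleSystem(
        params=params,
        weights=raw_w / raw_w.sum(),
        discrepancies=rhos,
        tolerance_history=tol_history or [float(rhos.max())],
        simulation_count=sim_count,
        iteration=iteration,
        complete=complete,
        param_names=names,
    )


def rsmc(
    S_obs: np.ndarray,
    prior,
    simulator,
    W: np.ndarray,
    n_particles: int = 1000,
    drop_fraction: float = 0.5,
    eps_final: float = 0.1,
    target_miss_prob: float = 0.01,
    min_acceptance: float = 0.01,
    max_simulations: int | None = None,
    forced_repeats: int | None = None,
    seed: int = 0,
    param_names: tuple[str, ...] = (),
    verbose: bool = False,
) -> ParticleSystem:
    """Replenishment SMC-ABC baseline (MCMC move kernel, equal weights).

    Dropped particles are replaced by uniform resampling from the survivors
    followed by R_t MCMC-ABC steps (Gaussian random-walk proposal, accept if
    within the prior and rho <= eps_k).  R_t = ceil(log(p_miss)/log(1-p_hat))
    is tuned from the acceptance rate of the first pass so a moved particle
    escapes its starting point with probability about 1 - p_miss; the
    duplicated-particle drawback reappears if ``forced_repeats=0``.
    """
    rng = np.random.default_rng(seed)
    names = param_names or getattr(prior, "names", ())
    lo, hi = prior.bounds

    params = prior.sample(rng, n_particles)
    seeds = rng.integers(0, 2**31, size=n_particles)
    rhos = np.array(
        [_simulate_rho(simulator, t, int(s), S_obs, W) for t, s in zip(params, seeds)]
    )
    sim_count = n_particles
    tol_history: list[float] = []
    complete = True
    iteration = 0
    n_drop = int(round(drop_fraction * n_particles))
    n_keep = n_particles - n_drop

    def mcmc_pass(idx_moving, eps_k, chol):
        """One MCMC-ABC step for each moving particle; returns acceptances."""
        nonlocal sim_count
        accepted = 0
        for i in idx_moving:
            proposal = params[i] + chol @ rng.standard_normal(params.shape[1])
            if np.any(proposal < lo) or np.any(proposal > hi):
                continue
            prior_ratio = prior.pdf(proposal)[0] / max(prior.pdf(params[i])[0], 1e-300)
            if rng.random() >= min(1.0, prior_ratio):
                continue
            rho = _simulate_rho(simulator, proposal, int(rng.integers(0, 2**31)), S_obs, W)
            sim_count += 1
            if rho <= eps_k:
                params[i] = proposal
                rhos[i] = rho
                accepted += 1
        return accepted

    while True:
        iteration += 1
        order = np.argsort(rhos)
        eps_k = float(rhos[order[n_keep - 1]])
        final_round = eps_k <= eps_final
        if final_round:
            eps_k = eps_final
        tol_history.append(eps_k)

        keep_idx = order[:n_keep]
        drop_idx = order[n_keep:]
        resampled = rng.choice(keep_idx, size=len(drop_idx), replace=True)
        params[drop_idx] = params[resampled]
        rhos[drop_idx] = rhos[resampled]

        cov = _kernel_cov(params, np.full(n_particles, 1.0 / n_particles))
        chol = np.linalg.cholesky(cov)
        moving = drop_idx
        accepted = mcmc_pass(moving, eps_k, chol)
        p_hat = accepted / max(len(moving), 1)
        if forced_repeats is not None:
            repeats = forced_repeats
        elif p_hat <= 0:
            repeats = 0
        else:
            repeats = max(0, math.ceil(math.log(target_miss_prob) / math.log(1 - min(p_hat, 1 - 1e-12))) - 1)
        for _ in range(repeats):
            accepted += mcmc_pass(moving, eps_k, chol)
            if max_simulations is not None and sim_count >= max_simulations:
                break

        total_moves = len(moving) * (1 + repeats)
        overall_acc = accepted / max(total_moves, 1)
        if verbose:
            print(
                f"  RSMC iter {iteration}: eps={eps_k:.4g} p_hat={p_hat:.3f} "
                f"R_t={1 + repeats} sims={sim_count}"
            )
        if final_round:
            break
        if overall_acc < min_acceptance and p_hat < min_acceptance:
            warnings.warn(
                f"RSMC stalled at eps={eps_k:.4g} before reaching eps_final={eps_final:.4g}"
            )
            complete = False
            break
        if max_simulations is not None and sim_count >= max_simulations:
            complete = False
            break

    return ParticleSystem(
        params=params,
        weights=np.full(n_particles, 1.0 / n_particles),
        discrepancies=rhos,
        tolerance_history=tol_history,
        simulation_count=sim_count,
        iteration=iteration,
        complete=complete,
        param_names=names,
    )


def apmc(
    S_obs: np.ndarray,
    prior,
    simulator,
    W: np.ndarray,
    n_particles: int = 1000,
    keep_fraction: float = 0.5,
    n_iterations: int = 10,
    max_simulations: int | None = None,
    seed: int = 0,
    param_names: tuple[str, ...] = (),
    verbose: bool = False,
) -> ParticleSystem:
    """Adaptive population Monte Carlo baseline.

    Per iteration, ``N * (1 - keep_fraction)`` proposals are generated by a
    single resample-perturb-simulate pass each (no acceptance test), merged
    with the current population, and the best N by discrepancy are kept
    with Eq-1-style importance weights for the newcomers.  The implied
    tolerance (the largest kept discrepancy) may fluctuate.
    """
    rng = np.random.default_rng(seed)
    names = param_names or getattr(prior, "names", ())
    lo, hi = prior.bounds

    params = prior.sample(rng, n_particles)
    seeds = rng.integers(0, 2**31, size=n_particles)
    rhos = np.array(
        [_simulate_rho(simulator, t, int(s), S_obs, W) for t, s in zip(params, seeds)]
    )
    raw_w = np.ones(n_particles)
    sim_count = n_particles
    tol_history = [float(rhos.max())]
    n_new = max(1, int(round((1.0 - keep_fraction) * n_particles)))

    for it in range(n_iterations):
        if max_simulations is not None and sim_count >= max_simulations:
            break
        norm_w = raw_w / raw_w.sum()
        cov = _kernel_cov(params, norm_w)
        chol = np.linalg.cholesky(cov)
        new_params = np.empty((n_new, params.shape[1]))
        filled = 0
        while filled < n_new:
            idx = rng.choice(n_particles, p=norm_w)
            proposal = params[idx] + chol @ rng.standard_normal(params.shape[1])
            if np.any(proposal < lo) or np.any(proposal > hi) or prior.pdf(proposal)[0] <= 0:
                continue
            new_params[filled] = proposal
            filled += 1
        new_rhos = np.array(
            [
                _simulate_rho(simulator, t, int(rng.integers(0, 2**31)), S_obs, W)
                for t in new_params
            ]
        )
        sim_count += n_new
        new_raw = reweight(new_params, params, norm_w, cov, prior)

        merged_params = np.vstack([params, new_params])
        merged_rhos = np.concatenate([rhos, new_rhos])
        merged_raw = np.concatenate([raw_w, new_raw])
        order = np.argsort(merged_rhos)[:n_particles]
        params = merged_params[order]
        rhos = merged_rhos[order]
        raw_w = merged_raw[order]
        if raw_w.sum() <= 0:
            raw_w = np.ones(n_particles)
        tol_history.append(float(rhos.max()))
        if verbose:
            print(
                f"  APMC iter {it + 1}: eps={tol_history[-1]:.4g} sims={sim_count} "
                f"ESS={ess_kish(raw_w / raw_w.sum()):.0f}"
            )

    return ParticleSystem(
        params=params,
        weights=raw_w / raw_w.sum(),
        discrepancies=rhos,
        tolerance_history=tol_history,
        simulation_count=sim_count,
        iteration=len(tol_history) - 1,
        complete=True,
        param_names=names,
    )


@dataclass(frozen=True)
class PosteriorSummary:
    """Weighted posterior summaries on the biological rate scale."""

    names: tuple[str, ...]
    means: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    sds: np.ndarray
    cvs: np.ndarray  # NaN where the mean is zero
    mcses: np.ndarray
    correlations: np.ndarray
    generalized_variance: float
    ess: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.names,
                "mean": self.means,
                "ci5": self.ci_low,
                "ci95": self.ci_high,
                "sd": self.sds,
                "cv_percent": 100 * self.cvs,
                "mcse": self.mcses,
            }
        )

    def to_json(self, path) -> None:
        obj = {
            "parameters": {
                n: {
                    "mean": float(m),
                    "ci90": [float(a), float(b)],
                    "sd": float(s),
                    "cv": None if np.isnan(c) else float(c),
                    "mcse": float(e),
                }
                for n, m, a, b, s, c, e in zip(
                    self.names, self.means, self.ci_low, self.ci_high, self.sds, self.cvs, self.mcses
                )
            },
            "correlations": self.correlations.tolist(),
            "generalized_variance": float(self.generalized_variance),
            "ess": float(self.ess),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def _weighted_cov(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    mean = weights @ values
    centred = values - mean
    return (centred * weights[:, None]).T @ centred


def rescale_to_rates(system: ParticleSystem, cfg) -> tuple[np.ndarray, tuple[str, ...]]:
    """Map particle coordinates named Pm / Pp onto D (µm² h⁻¹) and lambda
    (h⁻¹); other coordinates pass through unchanged."""
    names = system.param_names or tuple(f"theta{j}" for j in range(system.params.shape[1]))
    values = system.params.copy()
    out_names = list(names)
    for j, n in enumerate(names):
        if n == "Pm":
            values[:, j] = values[:, j] * cfg.spacing_um**2 / (4 * cfg.step_h)
            out_names[j] = "D"
        elif n == "Pp":
            values[:, j] = values[:, j] / cfg.step_h
            out_names[j] = "lambda"
    return values, tuple(out_names)


def posterior_summary(system: ParticleSystem, cfg=None) -> PosteriorSummary:
    """Weighted means, 90% credible intervals (5th/95th weighted
    percentiles), CV, MCSE = sd/sqrt(ESS), pairwise correlations and the
    generalized variance (determinant of the weighted covariance).

    With a lattice config, probability-scale coordinates are first rescaled
    to the biological rates D and lambda.
    """
    if cfg is not None:
        values, names = rescale_to_rates(system, cfg)
    else:
        values = system.params
        names = system.param_names or tuple(f"theta{j}" for j in range(values.shape[1]))
    w = system.weights
    means = w @ values
    cov = _weighted_cov(values, w)
    sds = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means != 0, sds / np.abs(means), np.nan)
    ess = ess_kish(w)
    mcses = sds / math.sqrt(ess)
    ci_low = np.array([weighted_quantile(values[:, j], w, 0.05) for j in range(values.shape[1])])
    ci_high = np.array([weighted_quantile(values[:, j], w, 0.95) for j in range(values.shape[1])])
    denom = np.outer(sds, sds)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, cov / denom, np.nan)
    gv = float(np.linalg.det(np.atleast_2d(cov)))
    return PosteriorSummary(
        names=names,
        means=means,
        ci_low=ci_low,
        ci_high=ci_high,
        sds=sds,
        cvs=cvs,
        mcses=mcses,
        correlations=corr,
        generalized_variance=gv,
        ess=ess,
    )
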