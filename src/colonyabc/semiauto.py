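"""Semi-automatic (regression-projected) summary statistics and the
Mahalanobis discrepancy.

The 15-dimensional pilot summary L is too high-dimensional for efficient
ABC matching, so it is projected down to one derived statistic per free
parameter:

1. a pilot rejection-ABC run on the raw pilot summaries locates the region
   of non-negligible posterior density;
2. M parameter vectors are drawn uniformly from that region, each with a
   simulated pilot summary L_i, forming a training set;
3. for each parameter j a linear model

       theta_{i,j} = alpha_j + beta_j' g_j(L_i) + xi_{i,j},
       g_j(L) = (L, L^2),

   is fitted by bidirectional stepwise selection under BIC; the derived
   statistic is S_j(y) = beta_j' g_j(L) (the intercept cancels in
   differences and is omitted, matching the definition used for matching).

Discrepancies between observed and simulated derived summaries are squared
Mahalanobis distances under a covariance W estimated from repeated
simulations at the regression-predicted posterior mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .priors import UniformBoxPrior

__all__ = [
    "PilotRegion",
    "TrainingSet",
    "ProjectionModel",
    "SummaryCovariance",
    "pilot_abc",
    "build_training_set",
    "fit_projection",
    "estimate_W",
    "calibrate_eps_final",
    "discrepancy",
]


@dataclass(frozen=True)
class PilotRegion:
    """Axis-aligned bounding box of the pilot-run acceptances."""

    lows: np.ndarray
    highs: np.ndarray
    accepted: np.ndarray  # (n_keep, J) accepted parameter vectors
    distances: np.ndarray

    def as_prior(self, names: tuple[str, ...] = ()) -> UniformBoxPrior:
        return UniformBoxPrior(tuple(self.lows), tuple(self.highs), names)


def pilot_abc(
    L_obs: np.ndarray,
    prior: UniformBoxPrior,
    simulator,
    budget: int = 2000,
    keep_fraction: float = 0.005,
    inflate: float = 0.1,
    rounds: int = 1,
    seed: int = 0,
) -> PilotRegion:
    """Rejection ABC on the raw pilot summaries.

    Distances are component-wise standardised Euclidean (each component
    scaled by its spread over the simulated pool; zero-spread components are
    dropped with a warning).  The ``keep_fraction`` smallest distances
    define the accepted sample, whose bounding box — optionally inflated by
    ``inflate`` on each side and clipped to the prior support — is the
    training region for the regression step.

    With ``rounds > 1`` the pilot is iterated: the simulation budget is
    split evenly and each round redraws uniformly inside the previous
    round's box.  Later rounds avoid the degenerate parameter regimes
    (e.g. lattice-saturating proliferation) where the summaries carry no
    gradient, sharpening the region at the same total cost.
    """
    if budget < 1:
        raise ValueError("budget must be positive")
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must be in (0, 1]")
    if rounds < 1:
        raise ValueError("rounds must be at least 1")
    L_obs = np.asarray(L_obs, dtype=float)
    region_prior = prior
    rng = np.random.default_rng(seed)
    per_round = budget // rounds
    region: PilotRegion | None = None
    for _ in range(rounds):
        region = _pilot_round(
            L_obs, region_prior, prior, simulator, per_round, keep_fraction, inflate, rng
        )
        region_prior = region.as_prior(getattr(prior, "names", ()))
    return region


def _pilot_round(
    L_obs: np.ndarray,
    sampling_prior: UniformBoxPrior,
    support_prior: UniformBoxPrior,
    simulator,
    budget: int,
    keep_fraction: float,
    inflate: float,
    rng: np.random.Generator,
) -> PilotRegion:
    thetas = sampling_prior.sample(rng, budget)
    sim_seeds = rng.integers(0, 2**31, size=budget)
    sims = np.array([simulator(t, int(s)) for t, s in zip(thetas, sim_seeds)])
    prior = support_prior

    spread = sims.std(axis=0)
    keep_cols = spread > 0
    if not keep_cols.all():
        warnings.warn(
            f"{int((~keep_cols).sum())} pilot summary component(s) with zero spread "
            "dropped from the pilot distance"
        )
    diffs = (sims[:, keep_cols] - L_obs[keep_cols]) / spread[keep_cols]
    dists = np.sqrt((diffs**2).sum(axis=1))

    n_keep = max(1, int(round(keep_fraction * budget)))
    order = np.argsort(dists)[:n_keep]
    accepted = thetas[order]
    lows = accepted.min(axis=0)
    highs = accepted.max(axis=0)
    pad = inflate * (highs - lows)
    prior_lo, prior_hi = prior.bounds
    lows = np.maximum(lows - pad, prior_lo)
    highs = np.minimum(highs + pad, prior_hi)
    # guard against a degenerate (zero-width) box on any axis
    width = highs - lows
    tiny = width <= 0
    if tiny.any():
        highs = np.where(tiny, np.minimum(highs + 1e-6, prior_hi), highs)
        lows = np.where(tiny, np.maximum(lows - 1e-6, prior_lo), lows)
    return PilotRegion(lows=lows, highs=highs, accepted=accepted, distances=dists[order])


@dataclass(frozen=True)
class TrainingSet:
    """Paired draws (theta_i, L_i) used to fit the projection regressions."""

    thetas: np.ndarray  # (M, J)
    summaries: np.ndarray  # (M, 15)
    region_lows: np.ndarray
    region_highs: np.ndarray
    param_names: tuple[str, ...] = ()

    @property
    def M(self) -> int:
        return self.thetas.shape[0]

    def to_frame(self) -> pd.DataFrame:
        names = self.param_names or tuple(f"theta{j}" for j in range(self.thetas.shape[1]))
        df = pd.DataFrame(self.thetas, columns=list(names))
        for k in range(self.summaries.shape[1]):
            df[f"L{k + 1}"] = self.summaries[:, k]
        return df


def build_training_set(
    region: PilotRegion | UniformBoxPrior,
    simulator,
    M: int = 5000,
    seed: int = 0,
    param_names: tuple[str, ...] = (),
) -> TrainingSet:
    """Draw M parameter vectors uniformly on the training region and
    simulate a pilot summary for each."""
    box = region.as_prior() if isinstance(region, PilotRegion) else region
    rng = np.random.default_rng(seed)
    thetas = box.sample(rng, M) if M > 0 else np.empty((0, box.dim))
    sim_seeds = rng.integers(0, 2**31, size=M)
    sims = np.array([simulator(t, int(s)) for t, s in zip(thetas, sim_seeds)])
    if M == 0:
        sims = sims.reshape(0, 0)
    lo, hi = box.bounds
    return TrainingSet(
        thetas=thetas,
        summaries=sims,
        region_lows=lo,
        region_highs=hi,
        param_names=param_names or getattr(box, "names", ()),
    )


def candidate_terms(L: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """The regression design g(L) = (L, L^2) with column labels."""
    L = np.atleast_2d(L)
    d = L.shape[1]
    names = [f"L{k + 1}" for k in range(d)] + [f"L{k + 1}^2" for k in range(d)]
    return np.hstack([L, L**2]), names


@dataclass(frozen=True)
class ProjectionModel:
    """Fitted per-parameter projections S_j(y) = beta_j' g_j(L)."""

    intercepts: np.ndarray  # (J,)
    coefs: tuple[np.ndarray, ...]  # per parameter, over its selected terms
    selected: tuple[tuple[int, ...], ...]  # candidate-term indices
    bic: np.ndarray
    term_names: tuple[str, ...]
    param_names: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return len(self.coefs)

    def project(self, L: np.ndarray) -> np.ndarray:
        """Derived summary vector S (no intercept, one entry per parameter)."""
        G, _ = candidate_terms(np.atleast_2d(np.asarray(L, dtype=float)))
        S = np.column_stack(
            [
                G[:, list(sel)] @ coef if len(sel) else np.zeros(G.shape[0])
                for sel, coef in zip(self.selected, self.coefs)
            ]
        )
        return S[0] if np.asarray(L).ndim == 1 else S

    def predict_mean(self, L: np.ndarray) -> np.ndarray:
        """Regression estimate of E[theta | L] = alpha + beta' g(L)."""
        return self.intercepts + self.project(L)

    def to_json(self, path) -> None:
        obj = {
            "param_names": list(self.param_names),
            "term_names": list(self.term_names),
            "models": [
                {
                    "intercept": float(a),
                    "selected": [self.term_names[i] for i in sel],
                    "selected_idx": list(sel),
                    "coefficients": list(map(float, coef)),
                    "bic": float(b),
                }
                for a, sel, coef, b in zip(self.intercepts, self.selected, self.coefs, self.bic)
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ProjectionModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            intercepts=np.array([m["intercept"] for m in obj["models"]]),
            coefs=tuple(np.array(m["coefficients"]) for m in obj["models"]),
            selected=tuple(tuple(m["selected_idx"]) for m in obj["models"]),
            bic=np.array([m["bic"] for m in obj["models"]]),
            term_names=tuple(obj["term_names"]),
            param_names=tuple(obj["param_names"]),
        )


def _ols_bic(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    """BIC and coefficients of an OLS fit with intercept prepended.

    BIC = n log(RSS/n) + k log(n) with the residual variance floored at a
    tiny multiple of var(y), so a numerically perfect fit cannot keep
    'improving' on rounding noise as further terms are added.
    """
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    res = sm.OLS(y, design).fit()
    floor = 1e-12 * max(float(np.var(y)), 1e-300)
    sigma2 = max(res.ssr / n, floor)
    bic = n * np.log(sigma2) + design.shape[1] * np.log(n)
    return float(bic), res.params


def fit_projection(train: TrainingSet, verbose: bool = False) -> ProjectionModel:
    """Bidirectional stepwise selection over the 30 candidate terms,
    started from the intercept-only model, minimising BIC for each
    parameter in turn."""
    G, names = candidate_terms(train.summaries)
    M = train.M
    n_candidates = G.shape[1]
    if M <= n_candidates:
        raise ValueError(
            f"training size M={M} must exceed the {n_candidates} candidate terms"
        )
    # exclude constant / duplicated columns, which cannot enter a full-rank fit
    usable = [k for k in range(n_candidates) if G[:, k].std() > 0]
    if len(usable) < n_candidates:
        warnings.warn(
            f"{n_candidates - len(usable)} constant candidate term(s) excluded from selection"
        )

    intercepts, coefs, selected, bics = [], [], [], []
    for j in range(train.thetas.shape[1]):
        y = train.thetas[:, j]
        current: list[int] = []
        best_bic, best_params = _ols_bic(y, G[:, current])
        improved = True
        while improved:
            improved = False
            best_move: tuple[str, int] | None = None
            move_bic, move_params = best_bic, best_params
            for k in usable:
                if k in current:
                    continue
                cols = current + [k]
                sub = G[:, cols]
                if np.linalg.matrix_rank(np.column_stack([np.ones(M), sub])) < len(cols) + 1:
                    continue
                b, p = _ols_bic(y, sub)
                if b < move_bic - 1e-9:
                    move_bic, move_params, best_move = b, p, ("add", k)
            for k in current:
                cols = [c for c in current if c != k]
                b, p = _ols_bic(y, G[:, cols])
                if b < move_bic - 1e-9:
                    move_bic, move_params, best_move = b, p, ("drop", k)
            if best_move is not None:
                op, k = best_move
                current = current + [k] if op == "add" else [c for c in current if c != k]
                current.sort()
                # refit on the sorted column order so coefficients align
                best_bic, best_params = _ols_bic(y, G[:, current])
                improved = True
                if verbose:
                    print(f"  theta[{j}] {op} {names[k]} -> BIC {best_bic:.2f}")
        intercepts.append(best_params[0])
        coefs.append(np.asarray(best_params[1:], dtype=float))
        selected.append(tuple(current))
        bics.append(best_bic)

    return ProjectionModel(
        intercepts=np.array(intercepts),
        coefs=tuple(coefs),
        selected=tuple(selected),
        bic=np.array(bics),
        term_names=tuple(names),
        param_names=train.param_names,
    )


@dataclass(frozen=True)
class SummaryCovariance:
    """Covariance W of the derived summaries, with provenance.

    ``calibration_summaries`` keeps the derived summary vectors of the
    calibration simulations; besides W itself they provide a natural
    reference scale for SMC tolerances (see :func:`calibrate_eps_final`).
    """

    W: np.ndarray
    theta_hat: np.ndarray
    n_calibration: int
    calibration_summaries: np.ndarray | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("W must be square and symmetric")

    def to_json(self, path) -> None:
        obj = {
            "W": self.W.tolist(),
            "theta_hat": self.theta_hat.tolist(),
            "n_calibration": self.n_calibration,
        }
        if self.calibration_summaries is not None:
            obj["calibration_summaries"] = self.calibration_summaries.tolist()
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SummaryCovariance":
        with open(path) as fh:
            obj = json.load(fh)
        cal = obj.get("calibration_summaries")
        return cls(
            W=np.array(obj["W"]),
            theta_hat=np.array(obj["theta_hat"]),
            n_calibration=obj["n_calibration"],
            calibration_summaries=None if cal is None else np.array(cal),
        )


def _condition(W: np.ndarray) -> np.ndarray:
    """Floor tiny/negative eigenvalues: add eps*I with
    eps = 1e-8 * trace(W)/J when the smallest eigenvalue is below that."""
    J = W.shape[0]
    eps = 1e-8 * max(np.trace(W) / J, 1e-300)
    lam_min = np.linalg.eigvalsh(W).min()
    if lam_min < eps:
        W = W + (eps - min(lam_min, 0.0)) * np.eye(J)
        if np.linalg.eigvalsh(W).min() <= 0:  # all-zero calibration output
            W = W + np.eye(J)
    return W


def estimate_W(
    model: ProjectionModel,
    L_obs: np.ndarray,
    simulator,
    support: tuple[np.ndarray, np.ndarray],
    n_cal: int = 100,
    seed: int = 0,
) -> SummaryCovariance:
    """Estimate the derived-summary covariance by simulating ``n_cal``
    datasets at the regression-predicted posterior mean (clipped into the
    prior support) and taking the sample covariance of their projections."""
    lo, hi = support
    theta_hat = model.predict_mean(np.asarray(L_obs, dtype=float))
    clipped = np.clip(theta_hat, lo, hi)
    if not np.allclose(clipped, theta_hat):
        warnings.warn(
            f"regression-predicted mean {theta_hat} clipped into the prior support"
        )
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31, size=n_cal)
    S = np.array([model.project(simulator(clipped, int(s))) for s in sim_seeds])
    W = np.cov(S, rowvar=False)
    W = np.atleast_2d(W)
    return SummaryCovariance(
        W=_condition(W),
        theta_hat=clipped,
        n_calibration=n_cal,
        calibration_summaries=S,
    )


def calibrate_eps_final(
    S_obs: np.ndarray, cov: SummaryCovariance, quantile: float = 0.5
) -> float:
    """Tolerance on the discrepancy scale that the calibration point can
    actually reach.

    The discrepancy between S_obs and each calibration simulation (run at
    the regression-predicted posterior mean) is computed under W; the
    requested quantile of those values is a target tolerance that is
    attainable by construction — simulations at a well-fitting parameter
    achieve it with probability ``quantile`` — while automatically tracking
    the scale of W and any bias in the calibration point.
    """
    if cov.calibration_summaries is None:
        raise ValueError("covariance estimate carries no calibration summaries")
    rhos = [discrepancy(S_obs, s, cov.W) for s in cov.calibration_summaries]
    return float(np.quantile(rhos, quantile))


def discrepancy(S_obs: np.ndarray, S_sim: np.ndarray, W: np.ndarray) -> float:
    """Squared Mahalanobis distance (S_obs - S_sim)' W^{-1} (S_obs - S_sim)."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    try:
        c = np.linalg.cholesky(W)
    except np.linalg.LinAlgError as exc:
        raise ValueError("W must be positive-definite") from exc
    d = np.atleast_1d(np.asarray(S_obs, dtype=float) - np.asarray(S_sim, dtype=float))
    z = np.linalg.solve(c, d)
    return float(z @ z)
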