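"""Prior distributions over model-parameter vectors.

Priors expose ``sample(rng, n)``, ``pdf(theta)`` (vectorised, up to an
arbitrary constant — only ratios matter in the particle re-weighting) and
``support`` bounds used to reject inadmissible perturbation proposals
before any model simulation is spent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["UniformBoxPrior", "BvnUniformPrior"]


@dataclass(frozen=True)
class UniformBoxPrior:
    """Independent uniform priors on an axis-aligned box."""

    lows: tuple[float, ...]
    highs: tuple[float, ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.lows) != len(self.highs):
            raise ValueError("lows and highs must have equal length")
        if any(h <= l for l, h in zip(self.lows, self.highs)):
            raise ValueError("each high must exceed its low")

    @property
    def dim(self) -> int:
        return len(self.lows)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lows, self.highs, size=(n, self.dim))

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lows) & (theta <= self.highs), axis=1)

    def pdf(self, theta: np.ndarray) -> np.ndarray:
        volume = float(np.prod(np.asarray(self.highs) - np.asarray(self.lows)))
        return self.contains(theta).astype(float) / volume

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lows), np.asarray(self.highs)


@dataclass(frozen=True)
class BvnUniformPrior:
    """Bivariate normal prior on the first two coordinates, uniform on the
    rest, truncated to an admissible box.

    Used for sequential Bayesian learning: the (D, q) posterior of a
    proliferation-suppressed experiment, refitted as a bivariate normal and
    expressed on the (P_m, q) probability scale, becomes the prior for the
    proliferating experiment; the remaining coordinates (P_p) keep a
    uniform prior.  Densities are unnormalised (truncation constant
    dropped), which is sufficient for importance re-weighting.
    """

    mean: tuple[float, float]
    cov: tuple[tuple[float, float], tuple[float, float]]
    lows: tuple[float, ...]
    highs: tuple[float, ...]
    names: tuple[str, ...] = ()
    max_rejection_rate: float = 0.5

    def __post_init__(self) -> None:
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (2, 2) or not np.allclose(c, c.T):
            raise ValueError("cov must be symmetric 2x2")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("cov must be positive-definite")

    @property
    def dim(self) -> int:
        return len(self.lows)

    def _mvn(self) -> stats._multivariate.multivariate_normal_frozen:
        cached = self.__dict__.get("_mvn_frozen")
        if cached is None:
            cached = stats.multivariate_normal(mean=self.mean, cov=np.asarray(self.cov))
            object.__setattr__(self, "_mvn_frozen", cached)
        return cached

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        return np.all((theta >= self.lows) & (theta <= self.highs), axis=1)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Rejection sampling into the box; errors out if most of the
        normal mass lies outside the admissible region."""
        mvn = self._mvn()
        out = np.empty((n, self.dim))
        filled = 0
        attempts = 0
        while filled < n:
            m = max(n - filled, 64)
            attempts += m
            first_two = mvn.rvs(size=m, random_state=rng).reshape(m, 2)
            rest = rng.uniform(self.lows[2:], self.highs[2:], size=(m, self.dim - 2))
            cand = np.hstack([first_two, rest])
            ok = self.contains(cand)
            take = min(int(ok.sum()), n - filled)
            out[filled : filled + take] = cand[ok][:take]
            filled += take
            if attempts >= 1000 and filled / attempts < 1.0 - self.max_rejection_rate:
                raise ValueError(
                    "bivariate normal prior places most of its mass outside the "
                    "admissible parameter box"
                )
        return out

    def _truncation_mass(self) -> float:
        """Monte Carlo estimate of the normal mass inside the box
        (deterministic: fixed internal seed, cached), so densities are
        properly normalised across generations of an SMC run."""
        cached = self.__dict__.get("_trunc_mass")
        if cached is not None:
            return cached
        rng = np.random.default_rng(1234567)
        draws = self._mvn().rvs(size=20_000, random_state=rng).reshape(-1, 2)
        inside = np.all(
            (draws >= np.asarray(self.lows[:2])) & (draws <= np.asarray(self.highs[:2])),
            axis=1,
        )
        mass = max(float(inside.mean()), 1e-6)
        object.__setattr__(self, "_trunc_mass", mass)
        return mass

    def pdf(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        dens = np.atleast_1d(self._mvn().pdf(theta[:, :2])).astype(float)
        rest_vol = float(
            np.prod(np.asarray(self.highs[2:]) - np.asarray(self.lows[2:]))
        ) if self.dim > 2 else 1.0
        dens = dens / (self._truncation_mass() * rest_vol)
        dens[~self.contains(theta)] = 0.0
        return dens

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.lows), np.asarray(self.highs)
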