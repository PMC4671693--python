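"""Lattice-based exclusion-process model of an expanding cell colony.

Agents live on a two-dimensional square lattice with at most one agent per
site.  Each time step of duration ``tau`` uses an approximate random
sequential update (RSU): ``C(t)`` motility candidates and, independently,
``C(t)`` proliferation candidates are drawn with replacement from the agents
present at the start of the step and resolved one at a time.  A sampled agent
moves to a uniformly chosen von Neumann neighbour with probability
``P_m * (1 - q)**n`` (``n`` = occupied nearest neighbours at decision time);
a proliferation candidate deposits a daughter on a uniformly chosen
neighbour with probability ``P_p``.  Any event targeting an occupied site or
a site off the lattice is aborted, and daughters only become eligible for
sampling from the next step.

The per-step probabilities map onto population-scale rates through
``D = P_m * Delta**2 / (4 * tau)`` (cell diffusivity, µm² h⁻¹) and
``lambda = P_p / tau`` (proliferation rate, h⁻¹), with ``Delta`` the lattice
spacing in µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "LatticeConfig",
    "ModelParams",
    "RateParams",
    "ColonyState",
    "rates_from_params",
    "params_from_rates",
    "init_colony",
    "motility_probability",
    "rsu_step",
    "simulate",
]


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry and time discretisation of a barrier-assay simulation.

    Defaults correspond to a 24-well plate well of diameter 15.6 mm at a
    lattice spacing of 18 µm (one cell-nucleus diameter): 15600/18 = 867
    sites across, with 20,000 cells seeded inside a disc of radius 177 sites.
    """

    width_sites: int = 867
    spacing_um: float = 18.0
    step_h: float = 0.04
    initial_count: int = 20_000
    initial_radius_sites: int = 177
    observation_times_h: tuple[float, ...] = (24.0,)

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.step_h <= 0:
            raise ValueError("step_h must be positive")
        if self.width_sites < 2 * self.initial_radius_sites:
            raise ValueError(
                "lattice must be at least twice the initial colony radius"
            )
        for t in self.observation_times_h:
            if t < 0:
                raise ValueError("observation times must be nonnegative")
            if _steps_or_none(t, self.step_h) is None:
                raise ValueError(
                    f"observation time {t} h is not a multiple of step_h={self.step_h} h"
                )

    @property
    def max_diffusivity(self) -> float:
        """Upper bound of D reachable with P_m = 1 (µm² h⁻¹)."""
        return self.spacing_um**2 / (4.0 * self.step_h)

    @property
    def max_proliferation_rate(self) -> float:
        """Upper bound of lambda reachable with P_p = 1 (h⁻¹)."""
        return 1.0 / self.step_h


@dataclass(frozen=True)
class ModelParams:
    """Per-step probabilities (P_m, q, P_p), each in [0, 1]."""

    motility_prob: float
    adhesion: float = 0.0
    proliferation_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("motility_prob", "adhesion", "proliferation_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class RateParams:
    """Biological-scale parameters: D (µm² h⁻¹), lambda (h⁻¹), q."""

    diffusivity: float
    proliferation_rate: float = 0.0
    adhesion: float = 0.0


@dataclass
class ColonyState:
    """Binary occupancy grid plus elapsed time."""

    occupancy: np.ndarray
    time_h: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.ascontiguousarray(self.occupancy, dtype=np.uint8)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be a 2-D grid")
        if not np.isin(self.occupancy, (0, 1)).all():
            raise ValueError("occupancy must be binary")

    @property
    def agent_count(self) -> int:
        return int(self.occupancy.sum())

    def copy(self) -> "ColonyState":
        return ColonyState(self.occupancy.copy(), self.time_h)

    def coordinates(self) -> np.ndarray:
        """Occupied-site (row, col) pairs, lexicographically ordered."""
        return np.argwhere(self.occupancy == 1)


def save_grid(state: ColonyState, path) -> None:
    """Write the occupancy grid (compressed) with its elapsed time."""
    np.savez_compressed(path, occupancy=state.occupancy, time_h=state.time_h)


def load_grid(path) -> ColonyState:
    with np.load(path) as data:
        return ColonyState(data["occupancy"], float(data["time_h"]))


def rates_from_params(params: ModelParams, cfg: LatticeConfig) -> RateParams:
    """Convert (P_m, q, P_p) to (D, q, lambda) for the given Delta, tau."""
    d = params.motility_prob * cfg.spacing_um**2 / (4.0 * cfg.step_h)
    lam = params.proliferation_prob / cfg.step_h
    return RateParams(diffusivity=d, proliferation_rate=lam, adhesion=params.adhesion)


def params_from_rates(rates: RateParams, cfg: LatticeConfig) -> ModelParams:
    """Convert (D, q, lambda) back to per-step probabilities.

    Raises ``ValueError`` if the requested rates exceed what a single step
    can represent (probability above 1).
    """
    pm = 4.0 * rates.diffusivity * cfg.step_h / cfg.spacing_um**2
    pp = rates.proliferation_rate * cfg.step_h
    if not 0.0 <= pm <= 1.0:
        raise ValueError(
            f"D={rates.diffusivity} outside [0, {cfg.max_diffusivity}] µm²/h for this lattice"
        )
    if not 0.0 <= pp <= 1.0:
        raise ValueError(
            f"lambda={rates.proliferation_rate} outside [0, {cfg.max_proliferation_rate}]/h"
        )
    return ModelParams(motility_prob=pm, adhesion=rates.adhesion, proliferation_prob=pp)


def motility_probability(motility_prob: float, adhesion: float, n_neighbours: int) -> float:
    """Probability that an agent with ``n_neighbours`` occupied nearest
    neighbours moves when sampled: P_m * (1 - q)**n."""
    if n_neighbours not in (0, 1, 2, 3, 4):
        raise ValueError("neighbour count must be in 0..4")
    return motility_prob * (1.0 - adhesion) ** n_neighbours


def disc_site_coordinates(cfg: LatticeConfig) -> np.ndarray:
    """(row, col) pairs of all sites within the initial seeding disc."""
    w = cfg.width_sites
    c = (w - 1) / 2.0
    rows, cols = np.mgrid[0:w, 0:w]
    mask = (rows - c) ** 2 + (cols - c) ** 2 <= cfg.initial_radius_sites**2
    return np.argwhere(mask)


def init_colony(cfg: LatticeConfig, seed: int | np.random.Generator) -> ColonyState:
    """Place ``initial_count`` agents uniformly at random (without
    replacement) on the sites within the seeding disc."""
    rng = np.random.default_rng(seed)
    sites = disc_site_coordinates(cfg)
    if cfg.initial_count > len(sites):
        raise ValueError(
            f"initial_count={cfg.initial_count} exceeds the {len(sites)} sites "
            f"inside a disc of radius {cfg.initial_radius_sites}"
        )
    occ = np.zeros((cfg.width_sites, cfg.width_sites), dtype=np.uint8)
    if cfg.initial_count > 0:
        chosen = rng.choice(len(sites), size=cfg.initial_count, replace=False)
        occ[sites[chosen, 0], sites[chosen, 1]] = 1
    return ColonyState(occ, time_h=0.0)


@njit(inline="always")
def _mix64(z):  # pragma: no cover
    """splitmix64 finaliser: expands a step seed into generator state."""
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return z ^ (z >> np.uint64(31))


@njit(inline="always")
def _xs_next(state):  # pragma: no cover
    """xorshift64* step; returns (new_state, uint64 output)."""
    x = state
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    x ^= x >> np.uint64(27)
    out = (x * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return x, out


@njit(cache=True)
def _rsu_kernel(occ, xs, ys, count, step_seeds, pm, q, pp):  # pragma: no cover
    """Advance the colony by len(step_seeds) RSU steps in place.

    ``xs``/``ys`` hold agent coordinates (first ``count`` entries live) and
    have capacity for every lattice site.  Each step is seeded from
    ``step_seeds`` so that a run sliced into sub-runs at step boundaries
    reproduces the identical event stream.

    The C(t) Bernoulli(P_m) motility opportunities (and likewise the
    Bernoulli(P_p) proliferation opportunities) are drawn as a single
    binomial count followed by that many uniformly chosen agents — an exact
    reformulation of per-draw thinning that skips the draws which would
    fail the constant-probability gate.  Per-event randomness comes from a
    fast xorshift64* stream (re-derived from each step's seed), platform
    independent and cheap enough for saturated colonies; agents whose four
    neighbouring targets are all blocked are skipped without spending draws
    (such events always abort).
    """
    w = occ.shape[0]
    inv53 = 1.0 / 9007199254740992.0  # 2^-53
    # adhesion factor (1-q)^n for n = 0..4 occupied neighbours
    adh = np.empty(5)
    adh[0] = 1.0
    for n in range(1, 5):
        adh[n] = adh[n - 1] * (1.0 - q)
    n_sites = w * w
    for s in range(step_seeds.shape[0]):
        if count == n_sites:
            break  # fully saturated lattice: every future event aborts
        seed = np.uint64(step_seeds[s])
        np.random.seed(step_seeds[s])  # binomial counts use the numpy stream
        state = _mix64(seed)
        c0 = count
        if c0 == 0:
            continue
        # motility sweep over the agents present at the step start
        n_move = np.random.binomial(c0, pm) if pm < 1.0 else c0
        for _ in range(n_move):
            state, r = _xs_next(state)
            i = int(r % np.uint64(c0))
            x = xs[i]
            y = ys[i]
            n = 0
            if x > 0 and occ[x - 1, y] == 1:
                n += 1
            if x < w - 1 and occ[x + 1, y] == 1:
                n += 1
            if y > 0 and occ[x, y - 1] == 1:
                n += 1
            if y < w - 1 and occ[x, y + 1] == 1:
                n += 1
            if n == 4:
                continue  # every target occupied: the event must abort
            if n > 0:
                state, r = _xs_next(state)
                if (r >> np.uint64(11)) * inv53 >= adh[n]:
                    continue
            state, r = _xs_next(state)
            d = int(r & np.uint64(3))
            nx = x
            ny = y
            if d == 0:
                nx = x - 1
            elif d == 1:
                nx = x + 1
            elif d == 2:
                ny = y - 1
            else:
                ny = y + 1
            if 0 <= nx < w and 0 <= ny < w and occ[nx, ny] == 0:
                occ[x, y] = 0
                occ[nx, ny] = 1
                xs[i] = nx
                ys[i] = ny
        # proliferation sweep: daughters join the pool only next step
        if pp > 0.0:
            n_prolif = np.random.binomial(c0, pp) if pp < 1.0 else c0
            for _ in range(n_prolif):
                state, r = _xs_next(state)
                i = int(r % np.uint64(c0))
                x = xs[i]
                y = ys[i]
                n = 0
                if x > 0 and occ[x - 1, y] == 1:
                    n += 1
                if x < w - 1 and occ[x + 1, y] == 1:
                    n += 1
                if y > 0 and occ[x, y - 1] == 1:
                    n += 1
                if y < w - 1 and occ[x, y + 1] == 1:
                    n += 1
                if n == 4:
                    continue
                state, r = _xs_next(state)
                d = int(r & np.uint64(3))
                nx = x
                ny = y
                if d == 0:
                    nx = x - 1
                elif d == 1:
                    nx = x + 1
                elif d == 2:
                    ny = y - 1
                else:
                    ny = y + 1
                if 0 <= nx < w and 0 <= ny < w and occ[nx, ny] == 0:
                    occ[nx, ny] = 1
                    xs[count] = nx
                    ys[count] = ny
                    count += 1
    return count


def _steps_or_none(duration_h: float, step_h: float, rel_tol: float = 1e-9) -> int | None:
    k = duration_h / step_h
    k_round = round(k)
    if abs(k - k_round) > rel_tol * max(1.0, abs(k)):
        return None
    return int(k_round)


def _step_seeds(seed: int, n_steps: int) -> np.ndarray:
    """Per-step 32-bit seeds; step ``k`` of a run always gets the same seed
    regardless of how the run is sliced into kernel calls."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_steps, dtype=np.uint32).astype(np.int64)


class _AgentBuffer:
    """Mutable (occupancy, agent list) pair shared across kernel calls so
    that the agent index ordering — and hence the seeded event stream — is
    independent of where a run is split into segments."""

    def __init__(self, occupancy: np.ndarray):
        self.occ = np.ascontiguousarray(occupancy, dtype=np.uint8).copy()
        coords = np.argwhere(self.occ == 1)
        capacity = self.occ.shape[0] * self.occ.shape[1]
        self.xs = np.zeros(capacity, dtype=np.int64)
        self.ys = np.zeros(capacity, dtype=np.int64)
        self.xs[: len(coords)] = coords[:, 0]
        self.ys[: len(coords)] = coords[:, 1]
        self.count = len(coords)

    def advance(self, params: ModelParams, seeds: np.ndarray) -> None:
        self.count = _rsu_kernel(
            self.occ,
            self.xs,
            self.ys,
            self.count,
            np.asarray(seeds, dtype=np.int64),
            params.motility_prob,
            params.adhesion,
            params.proliferation_prob,
        )


def rsu_step(
    state: ColonyState,
    params: ModelParams,
    rng: int | np.random.Generator,
    step_h: float = 0.04,
) -> ColonyState:
    """Apply a single random-sequential-update step and advance time by tau."""
    if isinstance(rng, np.random.Generator):
        seed = int(rng.integers(0, 2**31))
    else:
        seed = int(rng)
    buf = _AgentBuffer(state.occupancy)
    buf.advance(params, _step_seeds(seed, 1))
    return ColonyState(buf.occ, time_h=state.time_h + step_h)


def simulate(
    schedule: list[tuple[float, ModelParams]],
    cfg: LatticeConfig,
    seed: int,
    initial_state: ColonyState | None = None,
) -> list[ColonyState]:
    """Run the colony model under a piecewise-constant parameter schedule.

    ``schedule`` is a list of ``(end_time_h, params)`` stages with strictly
    increasing end times; the last end time must cover every observation
    time in ``cfg``.  Returns one recorded state per observation time.
    The event stream is a deterministic function of ``seed`` and is
    invariant to how the run is split into stages with equal parameters.
    """
    if not schedule:
        raise ValueError("schedule must contain at least one stage")
    ends = [end for end, _ in schedule]
    if any(b <= a for a, b in zip(ends, ends[1:])):
        raise ValueError("schedule end times must be strictly increasing")
    obs_times = sorted(cfg.observation_times_h)
    if obs_times and obs_times[-1] > ends[-1] + 1e-9:
        raise ValueError("last schedule stage must cover all observation times")
    for end in ends:
        if _steps_or_none(end, cfg.step_h) is None:
            raise ValueError(f"stage boundary {end} h is not a multiple of tau")

    state = initial_state.copy() if initial_state is not None else init_colony(cfg, np.random.SeedSequence(seed).spawn(1)[0])
    total_steps = _steps_or_none(ends[-1], cfg.step_h)
    seeds = _step_seeds(seed, total_steps)

    # breakpoints (in steps) where we must pause: observations + stage ends
    breaks = sorted(
        {_steps_or_none(t, cfg.step_h) for t in obs_times}
        | {_steps_or_none(end, cfg.step_h) for end in ends}
    )
    obs_steps = {_steps_or_none(t, cfg.step_h): t for t in obs_times}

    recorded: dict[int, ColonyState] = {}
    start_step = _steps_or_none(state.time_h, cfg.step_h)
    if start_step is None:
        raise ValueError("initial state time must be a multiple of tau")
    if start_step in obs_steps:
        recorded[start_step] = state.copy()
        recorded[start_step].time_h = obs_steps[start_step]

    buf = _AgentBuffer(state.occupancy)
    cur = start_step
    stage_idx = 0
    for brk in breaks:
        if brk <= cur:
            continue
        while cur < brk:
            # current stage covers steps up to its end
            while stage_idx < len(ends) and _steps_or_none(ends[stage_idx], cfg.step_h) <= cur:
                stage_idx += 1
            stage_end = _steps_or_none(ends[stage_idx], cfg.step_h)
            seg_end = min(brk, stage_end)
            params = schedule[stage_idx][1]
            buf.advance(params, seeds[cur:seg_end])
            cur = seg_end
        if cur in obs_steps:
            recorded[cur] = ColonyState(buf.occ.copy(), time_h=obs_steps[cur])

    return [recorded[_steps_or_none(t, cfg.step_h)] for t in obs_times]
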