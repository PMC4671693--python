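"""Unit and property tests for the lattice exclusion-process simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonyabc.colony_model import (
    ColonyState,
    LatticeConfig,
    ModelParams,
    RateParams,
    disc_site_coordinates,
    init_colony,
    motility_probability,
    params_from_rates,
    rates_from_params,
    rsu_step,
    simulate,
)

DEFAULT = LatticeConfig()


class TestParameterMappings:
    @pytest.mark.parametrize(
        "pm, pp, expected_d, expected_lam",
        [
            (0.1, 0.0012, 202.5, 0.03),  # validation triple
            (0.0, 0.0, 0.0, 0.0),
            (1.0, 1.0, 2025.0, 25.0),  # uniform-prior upper bounds
        ],
    )
    def test_rates_from_params(self, pm, pp, expected_d, expected_lam):
        rates = rates_from_params(ModelParams(pm, 0.2, pp), DEFAULT)
        assert rates.diffusivity == pytest.approx(expected_d)
        assert rates.proliferation_rate == pytest.approx(expected_lam)
        assert rates.adhesion == 0.2

    def test_params_from_rates_examples(self):
        p = params_from_rates(RateParams(220.0, 0.0, 0.0), DEFAULT)
        assert p.motility_prob == pytest.approx(4 * 220 * 0.04 / 18**2)
        p = params_from_rates(RateParams(202.5, 0.03, 0.2), DEFAULT)
        assert p.motility_prob == pytest.approx(0.1)
        assert p.proliferation_prob == pytest.approx(0.0012)
        p = params_from_rates(RateParams(0.0, 0.0, 0.0), DEFAULT)
        assert (p.motility_prob, p.proliferation_prob) == (0.0, 0.0)

    def test_params_from_rates_rejects_unreachable_rates(self):
        with pytest.raises(ValueError):
            params_from_rates(RateParams(2026.0, 0.0, 0.0), DEFAULT)
        with pytest.raises(ValueError):
            params_from_rates(RateParams(100.0, 26.0, 0.0), DEFAULT)

    @given(
        d=st.floats(0, 2025),
        lam=st.floats(0, 25),
        q=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, d, lam, q):
        rates = RateParams(d, lam, q)
        back = rates_from_params(params_from_rates(rates, DEFAULT), DEFAULT)
        assert back.diffusivity == pytest.approx(d, abs=1e-9)
        assert back.proliferation_rate == pytest.approx(lam, abs=1e-9)

    def test_well_and_subregion_site_arithmetic(self):
        # 15.6 mm well at 18 µm spacing; 700 µm sub-region width
        assert round(15_600 / DEFAULT.spacing_um) == 867
        assert round(700 / DEFAULT.spacing_um) == 39


class TestMotilityProbability:
    @pytest.mark.parametrize(
        "pm, q, n, expected",
        [(0.1, 0.0, 3, 0.1), (0.1, 0.2, 2, 0.064), (0.7, 1.0, 1, 0.0), (0.5, 0.3, 0, 0.5)],
    )
    def test_values(self, pm, q, n, expected):
        assert motility_probability(pm, q, n) == pytest.approx(expected)

    def test_monotone_in_crowding(self):
        probs = [motility_probability(0.8, 0.35, n) for n in range(5)]
        assert all(b <= a for a, b in zip(probs, probs[1:]))

    def test_rejects_bad_neighbour_count(self):
        with pytest.raises(ValueError):
            motility_probability(0.1, 0.2, 5)


class TestInitColony:
    def test_count_and_radius(self, small_cfg):
        state = init_colony(small_cfg, seed=0)
        assert state.agent_count == small_cfg.initial_count
        centre = (small_cfg.width_sites - 1) / 2
        coords = state.coordinates()
        dist = np.hypot(coords[:, 0] - centre, coords[:, 1] - centre)
        assert (dist <= small_cfg.initial_radius_sites).all()

    def test_empty_and_saturated_disc(self):
        cfg = LatticeConfig(
            width_sites=21, initial_count=0, initial_radius_sites=5, observation_times_h=()
        )
        assert init_colony(cfg, 1).agent_count == 0
        capacity = len(disc_site_coordinates(cfg))
        full_cfg = LatticeConfig(
            width_sites=21,
            initial_count=capacity,
            initial_radius_sites=5,
            observation_times_h=(),
        )
        assert init_colony(full_cfg, 1).agent_count == capacity
        with pytest.raises(ValueError):
            over = LatticeConfig(
                width_sites=21,
                initial_count=capacity + 1,
                initial_radius_sites=5,
                observation_times_h=(),
            )
            init_colony(over, 1)


class TestRsuStep:
    def test_frozen_dynamics_leave_state_unchanged(self, small_cfg):
        state = init_colony(small_cfg, seed=3)
        nxt = rsu_step(state, ModelParams(0.0, 0.0, 0.0), rng=1, step_h=small_cfg.step_h)
        assert np.array_equal(nxt.occupancy, state.occupancy)
        assert nxt.time_h == pytest.approx(state.time_h + small_cfg.step_h)

    def test_single_agent_moves_to_neighbour(self):
        occ = np.zeros((11, 11), dtype=np.uint8)
        occ[5, 5] = 1
        landed = set()
        for seed in range(200):
            nxt = rsu_step(ColonyState(occ), ModelParams(1.0, 0.0, 0.0), rng=seed)
            pos = tuple(nxt.coordinates()[0])
            landed.add(pos)
        # the agent is sampled C(t)=1 time; it moves to one of the 4 neighbours
        assert landed <= {(4, 5), (6, 5), (5, 4), (5, 6), (5, 5)}
        assert len(landed & {(4, 5), (6, 5), (5, 4), (5, 6)}) == 4

    def test_fully_surrounded_agent_cannot_move_or_deposit(self):
        occ = np.ones((5, 5), dtype=np.uint8)
        nxt = rsu_step(ColonyState(occ), ModelParams(1.0, 0.0, 1.0), rng=7)
        assert np.array_equal(nxt.occupancy, occ)

    def test_exclusion_and_binary_occupancy_hold_over_many_steps(self, small_cfg):
        state = init_colony(small_cfg, seed=11)
        params = ModelParams(0.9, 0.1, 0.05)
        for seed in range(50):
            state = rsu_step(state, params, rng=seed)
            assert set(np.unique(state.occupancy)) <= {0, 1}

    def test_agent_count_never_decreases(self, small_cfg):
        state = init_colony(small_cfg, seed=2)
        params = ModelParams(0.5, 0.0, 0.2)
        counts = [state.agent_count]
        for seed in range(30):
            state = rsu_step(state, params, rng=seed)
            counts.append(state.agent_count)
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestSimulate:
    def test_conservation_without_proliferation(self, small_cfg):
        params = ModelParams(0.8, 0.3, 0.0)
        final = simulate([(0.4, params)], small_cfg, seed=5)[-1]
        assert final.agent_count == small_cfg.initial_count

    def test_deterministic_replay(self, small_cfg, validation_params):
        a = simulate([(0.4, validation_params)], small_cfg, seed=9)[-1]
        b = simulate([(0.4, validation_params)], small_cfg, seed=9)[-1]
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_two_stage_equals_one_stage_with_equal_params(self, small_cfg):
        params = ModelParams(0.4, 0.2, 0.02)
        one = simulate([(0.4, params)], small_cfg, seed=13)[-1]
        two = simulate([(0.2, params), (0.4, params)], small_cfg, seed=13)[-1]
        assert np.array_equal(one.occupancy, two.occupancy)

    def test_observation_times_recorded_in_order(self, validation_params):
        cfg = LatticeConfig(
            width_sites=41,
            initial_count=60,
            initial_radius_sites=8,
            observation_times_h=(0.2, 0.4),
        )
        states = simulate([(0.4, validation_params)], cfg, seed=1)
        assert [s.time_h for s in states] == [0.2, 0.4]

    def test_invalid_schedules_rejected(self, small_cfg, validation_params):
        with pytest.raises(ValueError):
            simulate([], small_cfg, seed=1)
        with pytest.raises(ValueError):
            simulate([(0.4, validation_params), (0.2, validation_params)], small_cfg, 1)
        with pytest.raises(ValueError):
            simulate([(0.2, validation_params)], small_cfg, 1)  # obs at 0.4 uncovered

    def test_observation_time_must_align_with_step(self):
        with pytest.raises(ValueError):
            LatticeConfig(
                width_sites=41,
                initial_count=10,
                initial_radius_sites=8,
                observation_times_h=(0.05,),
                step_h=0.04,
            )


class TestFreeDiffusionLimit:
    def test_single_agent_msd_matches_4dt(self):
        """Mean squared displacement of an isolated walker equals
        k * P_m * Delta^2 = 4 D t within 3 standard errors."""
        pm, k, n_walkers = 0.5, 50, 10_000
        width = 81
        occ0 = np.zeros((width, width), dtype=np.uint8)
        occ0[40, 40] = 1
        cfg = LatticeConfig(
            width_sites=width,
            initial_count=1,
            initial_radius_sites=1,
            observation_times_h=(k * 0.04,),
        )
        sq = np.empty(n_walkers)
        for s in range(n_walkers):
            st = simulate(
                [(k * 0.04, ModelParams(pm, 0.0, 0.0))],
                cfg,
                seed=s,
                initial_state=ColonyState(occ0),
            )[0]
            r, c = st.coordinates()[0]
            sq[s] = (r - 40) ** 2 + (c - 40) ** 2
        expected = k * pm  # in units of Delta^2
        se = sq.std() / np.sqrt(n_walkers)
        assert abs(sq.mean() - expected) < 3 * se


class TestTimeStepRobustness:
    def test_summary_distributions_agree_between_tau_values(self):
        """At fixed D (and lambda), halving tau while rescaling P_m and P_p
        leaves the summary distributions statistically unchanged."""
        from scipy import stats as sstats

        from colonyabc.summaries import default_layout, pilot_summary

        reps = 12
        samples = {}
        for tau in (0.04, 0.02):
            cfg = LatticeConfig(
                width_sites=109, spacing_um=18.0, step_h=tau,
                initial_count=310, initial_radius_sites=22,
                observation_times_h=(4.0,),
            )
            params = params_from_rates(RateParams(220.0, 0.03, 0.2), cfg)
            layout = default_layout(cfg, window_width=5, window_height=4)
            vecs = []
            for seed in range(reps):
                state = simulate([(4.0, params)], cfg, seed=seed)[-1]
                vecs.append(pilot_summary([state], layout, cfg).as_vector())
            samples[tau] = np.array(vecs)
        radii_p = sstats.ks_2samp(samples[0.04][:, 0], samples[0.02][:, 0]).pvalue
        counts_p = sstats.ks_2samp(
            samples[0.04][:, 1:7].sum(axis=1), samples[0.02][:, 1:7].sum(axis=1)
        ).pvalue
        assert radii_p > 0.01
        assert counts_p > 0.01


class TestAdhesionMonotonicity:
    def test_expected_movement_decreases_with_adhesion(self):
        """In a crowded colony, higher adhesion means fewer realised moves
        (measured by displaced occupancy mass, averaged over replicates)."""
        cfg = LatticeConfig(
            width_sites=41,
            initial_count=150,
            initial_radius_sites=8,
            observation_times_h=(0.4,),
        )
        moved = []
        for q in (0.0, 0.5, 0.9):
            deltas = []
            for seed in range(25):
                start = init_colony(cfg, seed=seed)
                end = simulate(
                    [(0.4, ModelParams(0.8, q, 0.0))], cfg, seed=seed,
                    initial_state=start,
                )[0]
                deltas.append(int((start.occupancy != end.occupancy).sum()))
            moved.append(np.mean(deltas))
        assert moved[0] > moved[1] > moved[2]
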