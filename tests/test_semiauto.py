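"""Tests for the regression-projected summaries and the discrepancy."""

import numpy as np
import pytest

from colonyabc.priors import UniformBoxPrior
from colonyabc.semiauto import (
    TrainingSet,
    build_training_set,
    candidate_terms,
    discrepancy,
    estimate_W,
    fit_projection,
    pilot_abc,
)


def linear_simulator(coef_row=None, noise_sd=0.0, dim=15):
    """Fake 'colony' simulator: L is a linear-Gaussian image of theta, so
    the regression has a known exact answer."""
    rng_mat = np.random.default_rng(99)
    A = rng_mat.normal(size=(dim, 3))

    def sim(theta, seed):
        rng = np.random.default_rng(seed)
        return A @ np.asarray(theta) + noise_sd * rng.normal(size=dim)

    return sim, A


class TestPilotAbc:
    PRIOR = UniformBoxPrior((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), ("Pm", "q", "Pp"))

    def test_keep_everything_recovers_prior_support(self):
        sim, _ = linear_simulator(noise_sd=0.2)
        L_obs = sim(np.array([0.5, 0.5, 0.5]), seed=1)
        region = pilot_abc(L_obs, self.PRIOR, sim, budget=400, keep_fraction=1.0, seed=2)
        assert region.lows == pytest.approx([0, 0, 0], abs=0.05)
        assert region.highs == pytest.approx([1, 1, 1], abs=0.05)

    def test_keep_fraction_arithmetic(self):
        sim, _ = linear_simulator(noise_sd=0.2)
        L_obs = sim(np.array([0.5, 0.5, 0.5]), seed=1)
        region = pilot_abc(L_obs, self.PRIOR, sim, budget=1000, keep_fraction=0.005, seed=2)
        assert len(region.accepted) == 5

    def test_region_contains_the_generating_parameters(self):
        truth = np.array([0.3, 0.6, 0.2])
        sim, _ = linear_simulator(noise_sd=0.05)
        L_obs = sim(truth, seed=7)
        hits = 0
        for seed in range(5):
            region = pilot_abc(L_obs, self.PRIOR, sim, budget=800, keep_fraction=0.02,
                               seed=seed)
            if np.all(region.lows <= truth) and np.all(truth <= region.highs):
                hits += 1
        assert hits >= 4

    def test_zero_spread_component_dropped_with_warning(self):
        def sim(theta, seed):
            out = np.ones(15)
            out[0] = theta[0] + 0.1 * np.random.default_rng(seed).normal()
            return out

        L_obs = np.ones(15)
        L_obs[0] = 0.4
        with pytest.warns(UserWarning, match="zero spread"):
            pilot_abc(L_obs, self.PRIOR, sim, budget=100, keep_fraction=0.1, seed=0)


class TestBuildTrainingSet:
    def test_deterministic_and_shaped(self):
        sim, _ = linear_simulator(noise_sd=0.1)
        box = UniformBoxPrior((0.1, 0.1, 0.0), (0.5, 0.9, 0.1), ("Pm", "q", "Pp"))
        a = build_training_set(box, sim, M=50, seed=5)
        b = build_training_set(box, sim, M=50, seed=5)
        assert np.array_equal(a.thetas, b.thetas)
        assert np.array_equal(a.summaries, b.summaries)
        assert a.thetas.shape == (50, 3)
        assert a.summaries.shape == (50, 15)
        assert (a.thetas >= box.bounds[0]).all() and (a.thetas <= box.bounds[1]).all()

    def test_empty_set_fails_cleanly_downstream(self):
        sim, _ = linear_simulator()
        box = UniformBoxPrior((0.0,) * 3, (1.0,) * 3)
        train = build_training_set(box, sim, M=0, seed=1)
        with pytest.raises(ValueError):
            fit_projection(train)


class TestFitProjection:
    def test_noiseless_linear_recovery(self):
        """theta = 2 + 3 * L1 is recovered exactly: the selected model is
        {L1} with coefficient 3 and intercept 2."""
        rng = np.random.default_rng(0)
        L = rng.uniform(0, 1, size=(200, 15))
        theta = 2.0 + 3.0 * L[:, 0]
        train = TrainingSet(
            thetas=theta[:, None], summaries=L,
            region_lows=np.zeros(1), region_highs=np.ones(1),
        )
        model = fit_projection(train)
        assert model.selected[0] == (0,)
        assert model.coefs[0][0] == pytest.approx(3.0, abs=1e-8)
        assert model.intercepts[0] == pytest.approx(2.0, abs=1e-8)

    def test_quadratic_term_found(self):
        rng = np.random.default_rng(1)
        L = rng.uniform(-1, 1, size=(300, 15))
        theta = 1.5 * L[:, 2] ** 2 - 0.5
        train = TrainingSet(theta[:, None], L, np.zeros(1), np.ones(1))
        model = fit_projection(train)
        assert model.selected[0] == (17,)  # L3^2 among (L, L^2) terms

    def test_pure_noise_selects_intercept_only(self):
        """With theta independent of L, BIC should retain no terms."""
        rng = np.random.default_rng(42)
        L = rng.uniform(0, 1, size=(5000, 15))
        theta = rng.normal(size=5000)
        train = TrainingSet(theta[:, None], L, np.zeros(1), np.ones(1))
        model = fit_projection(train)
        assert model.selected[0] == ()

    def test_projection_definition_and_linearity(self):
        sim, A = linear_simulator(noise_sd=0.05)
        box = UniformBoxPrior((0.0,) * 3, (1.0,) * 3, ("Pm", "q", "Pp"))
        train = build_training_set(box, sim, M=300, seed=2, param_names=box.names)
        model = fit_projection(train)
        L = train.summaries[0]
        G, _ = candidate_terms(L[None, :])
        for j in range(3):
            manual = G[0, list(model.selected[j])] @ model.coefs[j]
            assert model.project(L)[j] == pytest.approx(manual)
        # linear in g(L): projecting a sum of g-vectors is not defined, but
        # scaling L scales the linear terms accordingly for a linear model
        zero = np.zeros(15)
        assert model.project(zero) == pytest.approx(np.zeros(3), abs=1e-12)

    def test_fitted_values_reproduced(self):
        rng = np.random.default_rng(3)
        L = rng.uniform(0, 1, size=(200, 15))
        theta = 0.5 + 2.0 * L[:, 4] + 0.1 * rng.normal(size=200)
        train = TrainingSet(theta[:, None], L, np.zeros(1), np.ones(1))
        model = fit_projection(train)
        pred = model.predict_mean(L[10])
        assert pred[0] == pytest.approx(
            model.intercepts[0] + model.project(L[10])[0]
        )


class TestEstimateW:
    def test_toy_variance_of_a_mean(self):
        """Simulator returns the mean of n Bernoulli(p) draws scaled by a
        known coefficient; W must match the analytic variance b² p(1-p)/n."""
        n, p, b = 400, 0.3, 2.5

        def sim(theta, seed):
            rng = np.random.default_rng(seed)
            out = np.zeros(15)
            out[0] = rng.binomial(n, p) / n
            return out

        model_train = TrainingSet(
            thetas=np.linspace(0, 1, 40)[:, None],
            summaries=np.tile(np.arange(15.0), (40, 1)),
            region_lows=np.zeros(1),
            region_highs=np.ones(1),
        )
        from colonyabc.semiauto import ProjectionModel

        model = ProjectionModel(
            intercepts=np.array([0.0]),
            coefs=(np.array([b]),),
            selected=((0,),),
            bic=np.array([0.0]),
            term_names=tuple(f"t{i}" for i in range(30)),
        )
        W = estimate_W(model, np.zeros(15), sim, (np.zeros(1), np.ones(1)),
                       n_cal=2000, seed=0)
        analytic = b**2 * p * (1 - p) / n
        assert W.W[0, 0] == pytest.approx(analytic, rel=0.15)

    def test_degenerate_calibration_is_conditioned(self):
        def sim(theta, seed):
            return np.zeros(15)

        from colonyabc.semiauto import ProjectionModel

        model = ProjectionModel(
            intercepts=np.zeros(2),
            coefs=(np.array([1.0]), np.array([1.0])),
            selected=((0,), (1,)),
            bic=np.zeros(2),
            term_names=tuple(f"t{i}" for i in range(30)),
        )
        W = estimate_W(model, np.zeros(15), sim, (np.zeros(2), np.ones(2)),
                       n_cal=20, seed=0)
        assert np.linalg.eigvalsh(W.W).min() > 0
        # the conditioned W still feeds a finite discrepancy
        assert discrepancy(np.array([1.0, 0.0]), np.zeros(2), W.W) > 0

    def test_out_of_support_mean_clipped_with_warning(self):
        def sim(theta, seed):
            rng = np.random.default_rng(seed)
            out = np.zeros(15)
            out[0] = rng.normal()
            return out

        from colonyabc.semiauto import ProjectionModel

        model = ProjectionModel(
            intercepts=np.array([5.0]),  # predicted mean far above support
            coefs=(np.array([1.0]),),
            selected=((0,),),
            bic=np.zeros(1),
            term_names=tuple(f"t{i}" for i in range(30)),
        )
        with pytest.warns(UserWarning, match="clipped"):
            W = estimate_W(model, np.zeros(15), sim, (np.zeros(1), np.ones(1)),
                           n_cal=30, seed=1)
        assert W.theta_hat[0] == 1.0


class TestDiscrepancy:
    def test_hand_values(self):
        assert discrepancy(np.array([3.0, 4.0]), np.zeros(2), np.eye(2)) == pytest.approx(25)
        assert discrepancy(np.ones(3), np.ones(3), np.eye(3)) == 0.0
        assert discrepancy(
            np.array([2.0, 0.0]), np.zeros(2), np.diag([4.0, 1.0])
        ) == pytest.approx(1.0)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=3), rng.normal(size=3)
            M = rng.normal(size=(3, 3))
            W = M @ M.T + 0.1 * np.eye(3)
            assert discrepancy(a, b, W) == pytest.approx(discrepancy(b, a, W))
            assert discrepancy(a, b, W) >= 0

    def test_invariance_under_linear_maps(self):
        """rho is unchanged by any invertible linear map of the summaries
        with W transformed as A W A'."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            a, b = rng.normal(size=3), rng.normal(size=3)
            M = rng.normal(size=(3, 3))
            W = M @ M.T + 0.2 * np.eye(3)
            A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
            lhs = discrepancy(a, b, W)
            rhs = discrepancy(A @ a, A @ b, A @ W @ A.T)
            assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(ValueError):
            discrepancy(np.ones(2), np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))
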