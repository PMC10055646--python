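"""Tests for the prior model, the regularized loss, fitting, lambda tuning,
and transition-pair splitting."""

import numpy as np
import pytest

import hillode as h
from conftest import decay_theta, random_theta


class TestPriorPredict:
    def test_identity_prior_is_zero_map(self, rng):
        prior = h.PriorModel(np.eye(4))
        np.testing.assert_array_equal(
            h.prior_predict(rng.uniform(0, 1, 4), prior), np.zeros(4)
        )

    def test_empty_prior_is_negative_state(self):
        prior = h.PriorModel(np.zeros((2, 2)))
        np.testing.assert_allclose(
            h.prior_predict(np.array([0.2, 0.4]), prior), [-0.2, -0.4]
        )

    def test_matches_double_loop(self, rng):
        n = 6
        A = rng.choice([-1.0, 0.0, 1.0], size=(n, n))
        prior = h.PriorModel(A)
        gam = rng.uniform(0, 1, n)
        expected = np.array(
            [sum((A[i, j] - (i == j)) * gam[j] for j in range(n)) for i in range(n)]
        )
        np.testing.assert_allclose(h.prior_predict(gam, prior), expected, rtol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            h.prior_predict(np.zeros(3), h.PriorModel(np.zeros((2, 2))))

    def test_invalid_entries_rejected(self):
        with pytest.raises(ValueError):
            h.PriorModel(np.full((2, 2), 0.5))


class TestGhostVectors:
    def test_deterministic_under_seed(self):
        a = h.sample_ghost_vectors(3, 2, seed=42)
        b = h.sample_ghost_vectors(3, 2, seed=42)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (3, 2)

    def test_mean_near_half(self):
        g = h.sample_ghost_vectors(10000, 1, seed=0)
        assert 0.49 <= g.mean() <= 0.51

    def test_single_vector(self):
        assert h.sample_ghost_vectors(1, 5, seed=0).shape == (1, 5)

    def test_invalid_K(self):
        with pytest.raises(ValueError):
            h.sample_ghost_vectors(0, 3, seed=0)


def _linear_pairs(n_pairs, rng, rate=1.0, dt=1.0):
    """Transition pairs from the closed-form 1-gene decay dg/dt = -g."""
    pairs = []
    for _ in range(n_pairs):
        g0 = rng.uniform(0.2, 1.0)
        pairs.append(h.TransitionPair(0.0, dt, [g0], [g0 * np.exp(-rate * dt)]))
    return pairs


class TestLossMod:
    def test_data_only_limit(self, rng):
        pairs = _linear_pairs(5, rng)
        theta = random_theta(1, 1, seed=1)
        cfg = h.TrainConfig(lambda_prior=0.0)
        prior = h.PriorModel(np.zeros((1, 1)))
        with_prior = h.loss_mod(pairs, theta, prior, cfg)
        without = h.loss_mod(pairs, theta, None, cfg)
        assert with_prior == without  # prior ignored at lambda_prior = 0

    def test_prior_term_zero_for_exactly_matching_theta(self):
        # identity prior predicts zero velocity; closed gates realize it
        n = 3
        theta = random_theta(n, 2, seed=2)
        theta.v = np.zeros(n)
        prior = h.PriorModel(np.eye(n))
        cfg = h.TrainConfig(lambda_prior=1.0, K=16, seed=0)
        pairs = [h.TransitionPair(0, 1, np.full(n, 0.4), np.full(n, 0.4))]
        assert h.loss_mod(pairs, theta, prior, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_decay_prior_term_zero(self):
        # A = 0 prior predicts -g; the zero-block network realizes it exactly
        n = 2
        theta = decay_theta(n)
        prior = h.PriorModel(np.zeros((n, n)))
        cfg = h.TrainConfig(lambda_prior=1.0, K=16, seed=0)
        pairs = [h.TransitionPair(0, 1, np.full(n, 0.4), np.full(n, 0.4))]
        assert h.loss_mod(pairs, theta, prior, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_self_consistent_pairs_give_tiny_loss(self, rng):
        theta = random_theta(3, 3, seed=3)
        pairs = []
        for _ in range(4):
            g0 = rng.uniform(0, 1, 3)
            tr = h.solve(g0, np.array([0.0, 1.0]), theta,
                         h.SolverConfig(rtol=1e-10, atol=1e-12))
            pairs.append(h.TransitionPair(0.0, 1.0, g0, tr.values[-1]))
        cfg = h.TrainConfig(lambda_prior=0.0)
        assert h.loss_mod(pairs, theta, None, cfg) < 1e-6

    def test_continuous_and_convex_combination_in_lambda(self, rng):
        pairs = _linear_pairs(4, rng)
        theta = random_theta(1, 1, seed=4)
        prior = h.PriorModel(np.zeros((1, 1)))
        ghosts = h.sample_ghost_vectors(16, 1, seed=5)
        l0 = h.loss_mod(pairs, theta, prior, h.TrainConfig(lambda_prior=0.0), ghosts)
        l1 = h.loss_mod(pairs, theta, prior, h.TrainConfig(lambda_prior=1.0), ghosts)
        lmid = h.loss_mod(pairs, theta, prior, h.TrainConfig(lambda_prior=0.3), ghosts)
        assert lmid == pytest.approx(0.7 * l0 + 0.3 * l1, rel=1e-10)
        assert min(l0, l1, lmid) >= 0.0

    def test_empty_pairs_error(self):
        with pytest.raises(ValueError):
            h.loss_mod([], random_theta(1, 1), None, h.TrainConfig())


class TestFit:
    def test_recovers_exponential_decay(self, rng):
        pairs = _linear_pairs(20, rng)
        res = h.fit(pairs, None, h.TrainConfig(epochs=400, seed=0))
        t_grid = np.linspace(0, 3, 7)
        tr = h.solve(np.array([1.0]), t_grid, res.theta)
        mse = np.mean((tr.values[:, 0] - np.exp(-t_grid)) ** 2)
        assert mse < 1e-3

    def test_prior_only_limit_recovers_linear_dynamics(self):
        n = 5
        A = np.zeros((n, n))
        for i, j, s in [(0, 1, 1), (1, 2, -1), (2, 3, 1), (3, 4, -1), (4, 0, 1)]:
            A[i, j] = s
        prior = h.PriorModel(A)
        dummy = [h.TransitionPair(0, 1, np.full(n, 0.5), np.full(n, 0.5))]
        res = h.fit(dummy, prior, h.TrainConfig(lambda_prior=1.0, epochs=2000, K=64, seed=0))
        gam = np.random.default_rng(99).uniform(0, 1, (200, n))
        mse = np.mean((h.velocity(gam, res.theta) - h.prior_predict(gam, prior)) ** 2)
        assert mse < 1e-3

    def test_loss_decreases(self, rng):
        pairs = _linear_pairs(10, rng)
        res = h.fit(pairs, None, h.TrainConfig(epochs=100, seed=0))
        assert res.train_loss_history.min() <= res.train_loss_history[0]
        assert np.all(np.isfinite(res.train_loss_history))

    def test_reproducible_histories(self, rng):
        pairs = _linear_pairs(8, rng)
        cfg = h.TrainConfig(epochs=50, seed=3)
        a = h.fit(pairs, None, cfg)
        b = h.fit(pairs, None, cfg)
        np.testing.assert_array_equal(a.train_loss_history, b.train_loss_history)

    def test_smoke_benchmark_improves_validation(self, tiny_sim):
        cfg, truth, trajs = tiny_sim
        train, val = trajs[:24], trajs[24:]
        init = h.init_params(cfg.n_genes, cfg.n_genes, 0, weight_scale=0.1)
        from hillode.estimator import data_loss

        before = data_loss(val, init)
        est = h.HillODE(epochs=250, random_state=0).fit(train, validation=val)
        after = min(est.val_loss_history_)
        assert after <= before / 10.0

    def test_prior_required_when_weighted(self, rng):
        with pytest.raises(ValueError):
            h.HillODE(lambda_prior=0.5).fit(_linear_pairs(3, rng))

    def test_empty_data_error(self):
        with pytest.raises(ValueError):
            h.HillODE().fit([])


class TestTuneLambda:
    def test_single_candidate(self, rng):
        pairs = _linear_pairs(6, rng)
        cfg = h.TrainConfig(epochs=20, seed=0)
        assert h.tune_lambda(pairs[:4], pairs[4:], None, cfg, [0.0]) == 0.0

    def test_selection_minimizes_validation_mse(self, rng):
        # data generated exactly by the prior's linear dynamics: both the
        # data-only and the prior-only fits should do well; the selected
        # candidate must be within 2x of the best validation MSE
        pairs = _linear_pairs(24, rng)
        prior = h.PriorModel(np.zeros((1, 1)))  # A=0 encodes dg/dt=-g
        cfg = h.TrainConfig(epochs=250, K=32, seed=0)
        lam, details = h.tune_lambda(
            pairs[:20], pairs[20:], prior, cfg, [0.0, 1.0], return_details=True
        )
        assert details[lam] <= 2.0 * min(details.values())

    def test_crafted_monotone_case_returns_smallest(self, rng):
        # inject a fit routine whose validation loss increases with lambda
        pairs = _linear_pairs(6, rng)
        theta_good = decay_theta(1)

        def fake_fit(train, prior, cfg, validation=None):
            bad = h.init_params(1, 1, 1, weight_scale=5.0 * cfg.lambda_prior + 0.01)
            theta = theta_good if cfg.lambda_prior == 0.05 else bad
            return h.FitResult(theta, np.zeros(1), None, cfg.lambda_prior)

        lam = h.tune_lambda(
            pairs[:4], pairs[4:], None, h.TrainConfig(epochs=1),
            [0.05, 0.3, 0.8], fit_fn=fake_fit,
        )
        assert lam == 0.05

    def test_empty_candidates_error(self, rng):
        with pytest.raises(ValueError):
            h.tune_lambda([], [], None, h.TrainConfig(), [])


class TestSplitTransitionPairs:
    @pytest.mark.parametrize(
        "n_pairs,fractions,expected",
        [
            (46, (40 / 46, 3 / 46, 3 / 46), (40, 3, 3)),
            (185, (170 / 185, 8 / 185, 7 / 185), (170, 8, 7)),
        ],
    )
    def test_reported_split_sizes(self, rng, n_pairs, fractions, expected):
        pairs = _linear_pairs(n_pairs, rng)
        tr, va, te = h.split_transition_pairs(pairs, fractions, seed=0)
        assert (len(tr), len(va), len(te)) == expected

    def test_partition_is_exact(self, rng):
        pairs = _linear_pairs(20, rng)
        tr, va, te = h.split_transition_pairs(pairs, (0.5, 0.25, 0.25), seed=1)
        ids = [id(p) for p in tr + va + te]
        assert sorted(ids) == sorted(id(p) for p in pairs)

    def test_too_few_pairs_error(self, rng):
        with pytest.raises(ValueError):
            h.split_transition_pairs(_linear_pairs(2, rng), (0.5, 0.25, 0.25), seed=0)

    def test_reproducible(self, rng):
        pairs = _linear_pairs(12, rng)
        a = h.split_transition_pairs(pairs, (0.5, 0.25, 0.25), seed=9)
        b = h.split_transition_pairs(pairs, (0.5, 0.25, 0.25), seed=9)
        assert [id(p) for p in a[0]] == [id(p) for p in b[0]]

    def test_trajectory_input_decomposed(self, tiny_sim):
        _, _, trajs = tiny_sim
        tr, va, te = h.split_transition_pairs(trajs[:5], (0.5, 0.25, 0.25), seed=0)
        assert len(tr) + len(va) + len(te) == 5 * 4
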