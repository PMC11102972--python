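"""Diffusion core: schedule algebra, forward/posterior closed forms against
independent oracles, training behaviour and reverse-chain classification."""

import dataclasses

import numpy as np
import pytest

from cdloop.diffusion import (DiffusionSchedule, EpsNet, ScoredPrediction,
                              forward_sample, make_schedule, posterior_step,
                              reverse_classify, reverse_classify_batch,
                              train_diffusion)
from cdloop.prior import build_prior_net
from conftest import make_separable_fixture


class TestSchedule:
    @pytest.mark.parametrize("T", [10, 100, 1000])
    def test_gamma_coefficients_sum_to_one(self, T):
        s = make_schedule(T)
        assert np.abs(s.gamma0 + s.gamma1 + s.gamma2 - 1.0).max() < 1e-10

    def test_random_schedules_gamma_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            T = int(rng.choice([10, 100, 1000]))
            b0 = float(rng.uniform(1e-5, 5e-3))
            b1 = float(rng.uniform(b0, 0.3))
            s = make_schedule(T, b0, b1)
            assert np.abs(s.gamma0 + s.gamma1 + s.gamma2 - 1.0).max() < 1e-10

    def test_invariants(self):
        s = make_schedule(100)
        assert np.all((s.beta > 0) & (s.beta < 1))
        assert np.all(np.diff(s.alpha_bar) < 0)
        assert np.all((s.beta_tilde >= 0) & (s.beta_tilde <= s.beta))
        assert s.beta_tilde[0] == 0.0  # abar_0 = 1 convention

    def test_constant_beta_alpha_bar_product(self):
        s = make_schedule(3, 0.1, 0.1)
        assert np.allclose(s.alpha_bar, [0.9, 0.81, 0.729])

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_schedule(1)
        for b in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                make_schedule(10, beta_start=b)


class TestForwardSample:
    def test_deep_t_approaches_prior_endpoint(self):
        s = make_schedule(1000)
        assert s.alpha_bar[-1] < 1e-4
        y0 = np.array([1.0, 0.0])
        f = np.array([0.3, 0.7])
        eps = np.array([0.5, -0.5])
        y_T = forward_sample(y0, f, s.T, s, eps)
        assert np.allclose(y_T, f + eps, atol=0.05)

    def test_shallow_t_stays_near_label(self):
        s = make_schedule(1000, 1e-6, 0.02)
        y0 = np.array([1.0, 0.0])
        f = np.array([0.5, 0.5])
        y1 = forward_sample(y0, f, 1, s, np.zeros(2))
        assert np.allclose(y1, y0, atol=1e-3)

    def test_stepwise_chain_matches_closed_form_moments(self):
        # simulate q(y_t | y_{t-1}, f) step by step for t=1..5 and compare
        # mean/variance with the closed form over many draws
        s = make_schedule(5, 0.05, 0.3)
        rng = np.random.default_rng(1)
        n = 100_000
        y0 = np.array([1.0, 0.0])
        f = np.array([0.2, 0.8])
        y = np.tile(y0, (n, 1))
        for t in range(1, 6):
            a = s.alpha[t - 1]
            b = s.beta[t - 1]
            y = (np.sqrt(a) * y + (1 - np.sqrt(a)) * f
                 + np.sqrt(b) * rng.standard_normal((n, 2)))
        ab = s.alpha_bar[-1]
        exp_mean = np.sqrt(ab) * y0 + (1 - np.sqrt(ab)) * f
        exp_var = 1 - ab
        se_mean = np.sqrt(exp_var / n)
        se_var = exp_var * np.sqrt(2.0 / (n - 1))
        assert np.all(np.abs(y.mean(axis=0) - exp_mean) < 3 * se_mean)
        assert np.all(np.abs(y.var(axis=0) - exp_var) < 3 * se_var)

    def test_t_out_of_range(self):
        s = make_schedule(10)
        with pytest.raises(ValueError):
            forward_sample(np.zeros(2), np.zeros(2), 11, s, np.zeros(2))


class TestPosteriorStep:
    def test_constant_inputs_are_fixed_point(self):
        s = make_schedule(50)
        c = np.array([0.4, 0.6])
        for t in (1, 10, 50):
            mu = posterior_step(c, c, c, t, s, noise=None)
            assert np.allclose(mu, c, atol=1e-12)

    def test_f_zero_reduces_to_standard_ddpm(self):
        # independent oracle: the textbook DDPM posterior mean written directly
        s = make_schedule(200)
        rng = np.random.default_rng(2)
        for t in (1, 7, 99, 200):
            ab = s.alpha_bar[t - 1]
            ab_prev = 1.0 if t == 1 else s.alpha_bar[t - 2]
            a = s.alpha[t - 1]
            b = s.beta[t - 1]
            y_t = rng.standard_normal(2)
            y0 = rng.standard_normal(2)
            ddpm = (b * np.sqrt(ab_prev) / (1 - ab) * y0
                    + (1 - ab_prev) * np.sqrt(a) / (1 - ab) * y_t)
            ours = posterior_step(y_t, y0, np.zeros(2), t, s, noise=None)
            assert np.abs(ours - ddpm).max() < 1e-12

    def test_f_zero_forward_marginal_is_standard_ddpm(self):
        s = make_schedule(100)
        rng = np.random.default_rng(3)
        y0 = rng.standard_normal(2)
        eps = rng.standard_normal(2)
        for t in (1, 50, 100):
            ab = s.alpha_bar[t - 1]
            ddpm = np.sqrt(ab) * y0 + np.sqrt(1 - ab) * eps
            ours = forward_sample(y0, np.zeros(2), t, s, eps)
            assert np.abs(ours - ddpm).max() < 1e-12

    def test_final_step_deterministic(self):
        s = make_schedule(50)
        rng = np.random.default_rng(4)
        y1 = rng.standard_normal(2)
        y0 = rng.standard_normal(2)
        f = rng.standard_normal(2)
        with_noise = posterior_step(y1, y0, f, 1, s, noise=rng.standard_normal(2))
        without = posterior_step(y1, y0, f, 1, s, noise=None)
        assert np.array_equal(with_noise, without)


class TestTraining:
    def test_loss_decreases_and_is_seeded(self, trained_diffusion):
        _, history = trained_diffusion
        losses = [h["train_loss"] for h in history]
        assert losses[-1] < losses[0]

    def test_fixed_seed_reproduces_loss_trajectory(self, trained_prior,
                                                   small_schedule):
        x, y = make_separable_fixture(60, seed=4)
        pnet, _ = trained_prior
        h = []
        for _ in range(2):
            enet = EpsNet(width=64, seed=1)
            _, hist = train_diffusion(enet, pnet, x, y, small_schedule,
                                      epochs=2, seed=11)
            h.append([r["train_loss"] for r in hist])
        assert h[0] == h[1]

    def test_single_timestep_degenerate_schedule_trains(self, trained_prior):
        # a one-step schedule built by hand (make_schedule requires T >= 2)
        beta = np.array([0.02])
        alpha = 1 - beta
        ab = alpha.copy()
        one = np.ones(1)
        sched = DiffusionSchedule(T=1, beta=beta, alpha=alpha, alpha_bar=ab,
                                  beta_tilde=np.zeros(1), gamma0=one.copy(),
                                  gamma1=np.zeros(1), gamma2=np.zeros(1))
        x, y = make_separable_fixture(30, seed=5)
        pnet, _ = trained_prior
        enet = EpsNet(width=32, seed=0)
        _, hist = train_diffusion(enet, pnet, x, y, sched, epochs=1, seed=0)
        assert len(hist) == 1

    def test_empty_sample_set_rejected(self, trained_prior, small_schedule):
        pnet, _ = trained_prior
        with pytest.raises(ValueError, match="empty"):
            train_diffusion(EpsNet(width=32, seed=0), pnet,
                            np.zeros((0, 28, 28)), np.zeros(0), small_schedule)


class TestReverseClassify:
    def test_fixture_scores_separate_classes(self, separable_fixture,
                                             trained_prior, trained_diffusion,
                                             small_schedule):
        x, y = separable_fixture
        pnet, _ = trained_prior
        enet, _ = trained_diffusion
        preds = reverse_classify_batch(x, pnet, enet, small_schedule,
                                       n_draws=10, seed=0)
        scores = np.array([p.score for p in preds])
        assert scores[y == 1].mean() > scores[y == 0].mean()
        acc = np.mean((scores > 0.5).astype(int) == y)
        assert acc >= 0.9

    def test_reverse_does_not_destroy_prior_information(self, separable_fixture,
                                                        trained_prior,
                                                        trained_diffusion,
                                                        small_schedule):
        from cdloop.prior import predict_prior

        x, y = separable_fixture
        pnet, _ = trained_prior
        enet, _ = trained_diffusion
        prior_acc = np.mean(predict_prior(pnet, x).argmax(axis=1) == y)
        preds = reverse_classify_batch(x, pnet, enet, small_schedule,
                                       n_draws=10, seed=0)
        scores = np.array([p.score for p in preds])
        diff_acc = np.mean((scores > 0.5).astype(int) == y)
        assert diff_acc >= prior_acc - 0.02

    def test_ci_brackets_score_and_pvalue_in_range(self, separable_fixture,
                                                   trained_prior,
                                                   trained_diffusion,
                                                   small_schedule):
        x, _ = separable_fixture
        pnet, _ = trained_prior
        enet, _ = trained_diffusion
        preds = reverse_classify_batch(x[:20], pnet, enet, small_schedule,
                                       n_draws=10, seed=1)
        for p in preds:
            assert p.ci_low <= p.score <= p.ci_high
            assert 0.0 <= p.score <= 1.0
            assert 0.0 <= p.t_pvalue <= 1.0

    def test_seeded_draws_bit_identical(self, separable_fixture, trained_prior,
                                        trained_diffusion, small_schedule):
        x, _ = separable_fixture
        pnet, _ = trained_prior
        enet, _ = trained_diffusion
        a = reverse_classify_batch(x[:10], pnet, enet, small_schedule, 5, seed=3)
        b = reverse_classify_batch(x[:10], pnet, enet, small_schedule, 5, seed=3)
        assert [p.score for p in a] == [p.score for p in b]
        assert [p.t_pvalue for p in a] == [p.t_pvalue for p in b]

    def test_single_draw_returns_undefined_markers(self, separable_fixture,
                                                   trained_prior,
                                                   trained_diffusion,
                                                   small_schedule):
        x, _ = separable_fixture
        pnet, _ = trained_prior
        enet, _ = trained_diffusion
        p = reverse_classify(x[0], pnet, enet, small_schedule, n_draws=1, seed=0)
        assert isinstance(p, ScoredPrediction)
        assert 0.0 <= p.score <= 1.0
        assert np.isnan(p.ci_low) and np.isnan(p.ci_high) and np.isnan(p.t_pvalue)


def test_eps_checkpoint_roundtrip(tmp_path, trained_diffusion, trained_prior,
                                  separable_fixture, small_schedule):
    enet, _ = trained_diffusion
    pnet, _ = trained_prior
    x, _ = separable_fixture
    path = tmp_path / "eps.npz"
    enet.save(path)
    enet2 = EpsNet.load(path)
    a = reverse_classify_batch(x[:5], pnet, enet, small_schedule, 3, seed=0)
    b = reverse_classify_batch(x[:5], pnet, enet2, small_schedule, 3, seed=0)
    assert [p.score for p in a] == [p.score for p in b]
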