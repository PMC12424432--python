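"""Model densities, Gibbs full conditionals and the fit surface."""

import warnings

import numpy as np
import pytest

from somnalr.model import (
    CompositionalMixedLM,
    ConvergenceWarning,
    McmcConfig,
    ParamState,
    PosteriorDraws,
    PriorSpec,
    fit as fit_frame,
    gibbs_sweep,
    log_likelihood,
    log_posterior,
)
from somnalr.preprocess import ModelFrame


def make_frame(n=40, p=3, K=2, J=5, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    codes = rng.integers(0, J, n)
    codes[:J] = np.arange(J)  # every subject observed
    Y = rng.standard_normal((n, K))
    return ModelFrame(
        Y=Y,
        X=X,
        subject_codes=codes,
        subject_ids=tuple(f"S{j}" for j in range(J)),
        coef_labels=tuple(f"x{a}" for a in range(p)),
        outcome_labels=tuple(f"y{d}" for d in range(K)),
    )


def state_for(frame, beta=None, sigma=1.0):
    p, K, J = frame.n_coef, frame.n_outcomes, frame.n_subjects
    return ParamState(
        beta=np.zeros((p, K)) if beta is None else beta,
        u=np.zeros((J, K)),
        sigma_u=np.full(K, sigma),
        sigma_e=np.full(K, sigma),
    )


class TestDensities:
    def test_scalar_gaussian_likelihood(self):
        frame = ModelFrame(
            Y=np.array([[1.0]]),
            X=np.array([[1.0]]),
            subject_codes=np.array([0]),
            subject_ids=("S0",),
            coef_labels=("x0",),
            outcome_labels=("y0",),
        )
        state = ParamState(
            beta=np.zeros((1, 1)),
            u=np.zeros((0, 1)),
            sigma_u=np.array([1.0]),
            sigma_e=np.array([1.0]),
        )
        ll = log_likelihood(state, frame)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi) - 0.5, abs=1e-6)

    def test_duplicated_rows_double_the_likelihood(self):
        frame = make_frame(n=25)
        state = state_for(frame)
        double = ModelFrame(
            Y=np.vstack([frame.Y, frame.Y]),
            X=np.vstack([frame.X, frame.X]),
            subject_codes=np.concatenate([frame.subject_codes] * 2),
            subject_ids=frame.subject_ids,
            coef_labels=frame.coef_labels,
            outcome_labels=frame.outcome_labels,
        )
        assert log_likelihood(state, double) == pytest.approx(
            2 * log_likelihood(state, frame)
        )

    def test_nonpositive_sigma_gives_minus_inf(self):
        frame = make_frame()
        state = state_for(frame)
        state.sigma_e = np.array([1.0, -0.5])
        assert log_posterior(state, frame, PriorSpec()) == -np.inf

    def test_gradient_vanishes_at_conjugate_mode(self):
        # no random effects, known variance: the posterior over beta is
        # Gaussian with mean (V0^-1 + X'X/s2)^-1 (X'y/s2); check the numeric
        # gradient of the log posterior is ~0 there
        rng = np.random.default_rng(4)
        n, p = 50, 3
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
        y = X @ np.array([1.0, -0.5, 0.2]) + rng.standard_normal(n)
        frame = ModelFrame(
            Y=y[:, None],
            X=X,
            subject_codes=np.zeros(n, dtype=int),
            subject_ids=("S0",),
            coef_labels=("a", "b", "c"),
            outcome_labels=("y0",),
        )
        priors = PriorSpec(beta_sd=10.0)
        s2 = 1.0
        A = X.T @ X / s2 + np.eye(p) / 100.0
        mode = np.linalg.solve(A, X.T @ y / s2)

        def lp(beta_vec):
            st = ParamState(
                beta=beta_vec[:, None],
                u=np.zeros((0, 1)),
                sigma_u=np.array([1.0]),
                sigma_e=np.array([1.0]),
            )
            return log_posterior(st, frame, priors)

        eps = 1e-5
        for a in range(p):
            e = np.zeros(p)
            e[a] = eps
            grad = (lp(mode + e) - lp(mode - e)) / (2 * eps)
            assert abs(grad) < 1e-4


class TestGibbs:
    def test_beta_conditional_matches_closed_form(self):
        # fixed variances, no random effect: long-run mean of the sampled
        # beta equals (V0^-1 + X'X/s2)^-1 (V0^-1 m0 + X'Y/s2)
        rng = np.random.default_rng(7)
        n, p = 30, 2
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = X @ np.array([0.8, -1.2]) + 0.5 * rng.standard_normal(n)
        frame = ModelFrame(
            Y=y[:, None],
            X=X,
            subject_codes=np.zeros(n, dtype=int),
            subject_ids=("S0",),
            coef_labels=("a", "b"),
            outcome_labels=("y0",),
        )
        priors = PriorSpec(beta_sd=10.0)
        s2 = 0.25
        A = np.eye(p) / 100.0 + X.T @ X / s2
        expected = np.linalg.solve(A, X.T @ y / s2)
        rng_s = np.random.default_rng(1)
        state = ParamState(
            beta=np.zeros((p, 1)),
            u=np.zeros((0, 1)),
            sigma_u=np.array([0.0]),
            sigma_e=np.array([0.5]),
        )
        draws = []
        for _ in range(5000):
            state = gibbs_sweep(
                state, frame, priors, rng_s, sigma_u_fixed=0.0, sigma_e_fixed=0.5
            )
            draws.append(state.beta[:, 0].copy())
        draws = np.array(draws)
        mcse = draws.std(axis=0, ddof=1) / np.sqrt(len(draws))
        np.testing.assert_array_less(np.abs(draws.mean(axis=0) - expected), 4 * mcse)

    def test_sweep_is_deterministic_given_rng(self):
        frame = make_frame()
        priors = PriorSpec()
        state = state_for(frame)
        out1 = gibbs_sweep(state.copy(), frame, priors, np.random.default_rng(42))
        out2 = gibbs_sweep(state.copy(), frame, priors, np.random.default_rng(42))
        np.testing.assert_array_equal(out1.beta, out2.beta)
        np.testing.assert_array_equal(out1.u, out2.u)
        np.testing.assert_array_equal(out1.sigma_e, out2.sigma_e)


class TestFit:
    def test_default_config_retains_12500_draws(self):
        frame = make_frame(n=30, p=2, K=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            draws = fit_frame(frame, config=McmcConfig(seed=0))
        assert draws.n_chains == 5 and draws.n_draws == 2500
        assert draws.pooled_beta().shape[0] == 12500

    def test_prior_dominance(self):
        frame = make_frame(n=60, p=3, K=2, seed=2)
        priors = PriorSpec(beta_mean=1.5, beta_sd=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = CompositionalMixedLM.from_frame(frame).fit(
                priors, McmcConfig(n_chains=2, n_iter=500, seed=3)
            )
        assert np.all(np.abs(res.effect_estimates.to_numpy() - 1.5) < 0.01)

    def test_chain_permutation_leaves_summaries_unchanged(self):
        frame = make_frame(n=50, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = CompositionalMixedLM.from_frame(frame).fit(
                config=McmcConfig(n_chains=3, n_iter=400, seed=6)
            )
        d = res.draws
        perm = PosteriorDraws(
            beta=d.beta[[2, 0, 1]],
            u=d.u[[2, 0, 1]],
            sigma_u=d.sigma_u[[2, 0, 1]],
            sigma_e=d.sigma_e[[2, 0, 1]],
            coef_labels=d.coef_labels,
            outcome_labels=d.outcome_labels,
            subject_ids=d.subject_ids,
            config=d.config,
        )
        from somnalr import inference

        np.testing.assert_allclose(
            inference.effect_estimates(d).to_numpy(),
            inference.effect_estimates(perm).to_numpy(),
        )

    def test_row_permutation_invariance_of_posterior(self):
        # shuffling observations leaves the posterior unchanged up to MC error
        frame = make_frame(n=80, p=3, K=1, seed=8)
        rng = np.random.default_rng(0)
        order = rng.permutation(frame.n_obs)
        shuffled = ModelFrame(
            Y=frame.Y[order],
            X=frame.X[order],
            subject_codes=frame.subject_codes[order],
            subject_ids=frame.subject_ids,
            coef_labels=frame.coef_labels,
            outcome_labels=frame.outcome_labels,
        )
        cfg = McmcConfig(n_chains=2, n_iter=2000, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            e1 = CompositionalMixedLM.from_frame(frame).fit(config=cfg).effect_estimates
            e2 = (
                CompositionalMixedLM.from_frame(shuffled)
                .fit(config=cfg)
                .effect_estimates
            )
        np.testing.assert_allclose(e1.to_numpy(), e2.to_numpy(), atol=0.08)

    def test_convergence_warning_on_disjoint_chains(self):
        frame = make_frame(n=30, p=2, K=1)
        model = CompositionalMixedLM.from_frame(frame)
        C, S = 2, 100
        beta = np.random.default_rng(0).standard_normal((C, S, 2, 1)) * 0.01
        beta[1] += 10.0  # second chain far away
        draws = PosteriorDraws(
            beta=beta,
            u=np.zeros((C, S, 5, 1)),
            sigma_u=np.ones((C, S, 1)),
            sigma_e=np.ones((C, S, 1)),
            coef_labels=frame.coef_labels,
            outcome_labels=frame.outcome_labels,
            subject_ids=frame.subject_ids,
            config=McmcConfig(n_chains=2, n_iter=200, seed=0),
        )
        with pytest.warns(ConvergenceWarning):
            model._attach_diagnostics(draws)
        assert draws.metadata["converged"] is False

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_chains=1)
        with pytest.raises(ValueError):
            McmcConfig(warmup_fraction=1.0)
        with pytest.raises(ValueError):
            McmcConfig(sampler="metropolis")
        with pytest.raises(ValueError):
            PriorSpec(beta_sd=0.0)
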