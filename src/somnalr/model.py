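"""Bayesian multivariate linear mixed model with subject random intercepts.

The model, fitted to each ALR outcome dimension d = 1..K independently but
jointly housed in one object, is

    y_{ij,d} = x_{ij}' beta_d + u_{i,d} + eps_{ij,d},
    u_{i,d}   ~ N(0, sigma_u_d^2),
    eps_{ij,d} ~ N(0, sigma_e_d^2),

for subject i and day j, with conjugate priors: beta_d ~ N(m0, V0) with
V0 diagonal, and inverse-gamma priors on both variances.  Conjugacy makes
every full conditional exact, so the reference sampler is a plain Gibbs
sweep over (beta, u, sigma_u^2, sigma_e^2); an optional ensemble-MCMC
backend (emcee) samples the identical log posterior through an
algorithmically independent route and serves as a cross-check.

Usage follows the statsmodels idiom::

    model = CompositionalMixedLM.from_frame(frame)
    res = model.fit(config=McmcConfig(seed=1))
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from . import inference as _inference
from .diagnostics import effective_sample_size, split_rhat
from .preprocess import ModelFrame

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "ParamState",
    "PosteriorDraws",
    "ConvergenceWarning",
    "CompositionalMixedLM",
    "MixedLMResults",
    "log_likelihood",
    "log_posterior",
    "gibbs_sweep",
    "fit",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PriorSpec:
    """Conjugate priors: normal on beta, inverse-gamma on the variances.

    ``beta_sd`` is the prior SD of every fixed effect (scalar or per-entry
    array); the inverse-gamma priors are parameterised by (shape, scale)
    and placed on the *variances* sigma_u^2 and sigma_e^2.
    """

    beta_mean: float | np.ndarray = 0.0
    beta_sd: float | np.ndarray = 10.0
    sigma_u_shape: float = 2.0
    sigma_u_scale: float = 1.0
    sigma_e_shape: float = 2.0
    sigma_e_scale: float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.beta_sd) <= 0):
            raise ValueError("beta_sd must be strictly positive")
        for name in ("sigma_u_shape", "sigma_u_scale", "sigma_e_shape", "sigma_e_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings: 5 chains of 5,000 iterations with the first half
    used as warm-up, random initialization, Gibbs backend by default."""

    n_chains: int = 5
    n_iter: int = 5000
    warmup_fraction: float = 0.5
    sampler: str = "gibbs"
    seed: Optional[int] = None
    init: str = "random"

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if not 0 < self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must lie in (0, 1)")
        if self.sampler not in ("gibbs", "ensemble"):
            raise ValueError("sampler must be 'gibbs' or 'ensemble'")
        if self.init not in ("random", "zero"):
            raise ValueError("init must be 'random' or 'zero'")

    @property
    def n_warmup(self) -> int:
        return int(self.n_iter * self.warmup_fraction)

    @property
    def n_keep(self) -> int:
        return self.n_iter - self.n_warmup


@dataclass
class ParamState:
    """One point in parameter space: fixed effects (p x K), random
    intercepts (J x K) and the two SD vectors (K,)."""

    beta: np.ndarray
    u: np.ndarray
    sigma_u: np.ndarray
    sigma_e: np.ndarray

    def copy(self) -> "ParamState":
        return ParamState(
            self.beta.copy(), self.u.copy(), self.sigma_u.copy(), self.sigma_e.copy()
        )


@dataclass(frozen=True)
class PosteriorDraws:
    """Chain-indexed post-warmup MCMC draws with labels and metadata.

    Array shapes: beta (C, S, p, K); u (C, S, J, K); sigma_u and sigma_e
    (C, S, K), where C chains, S retained draws per chain.
    """

    beta: np.ndarray
    u: np.ndarray
    sigma_u: np.ndarray
    sigma_e: np.ndarray
    coef_labels: tuple[str, ...]
    outcome_labels: tuple[str, ...]
    subject_ids: tuple[str, ...]
    config: McmcConfig
    metadata: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def pooled_beta(self) -> np.ndarray:
        """Draws pooled across chains: (C*S, p, K)."""
        C, S, p, K = self.beta.shape
        return self.beta.reshape(C * S, p, K)

    def scalar_series(self) -> dict[str, np.ndarray]:
        """Per-scalar-parameter (C, S) series for beta and the SDs."""
        out: dict[str, np.ndarray] = {}
        for a, coef in enumerate(self.coef_labels):
            for d, outc in enumerate(self.outcome_labels):
                out[f"beta[{coef}, {outc}]"] = self.beta[:, :, a, d]
        for d, outc in enumerate(self.outcome_labels):
            if self.sigma_u.shape[-1] == len(self.outcome_labels):
                out[f"sigma_u[{outc}]"] = self.sigma_u[:, :, d]
            if self.sigma_e.shape[-1] == len(self.outcome_labels):
                out[f"sigma_e[{outc}]"] = self.sigma_e[:, :, d]
        return out


# ---------------------------------------------------------------------------
# densities


def _log_invgamma(v: np.ndarray, shape: float, scale: float) -> np.ndarray:
    from scipy.stats import invgamma

    return invgamma.logpdf(v, shape, scale=scale)


def log_likelihood(state: ParamState, frame: ModelFrame) -> float:
    """Gaussian log-likelihood of Y given the current parameters."""
    sigma_e = np.asarray(state.sigma_e, dtype=float)
    if np.any(sigma_e <= 0):
        return -np.inf
    mu = frame.X @ state.beta
    if state.u.size:
        mu = mu + state.u[frame.subject_codes]
    resid = frame.Y - mu
    n = frame.n_obs
    ll = -0.5 * n * frame.n_outcomes * np.log(2 * np.pi)
    ll -= n * np.log(sigma_e).sum()
    ll -= 0.5 * (resid**2 / sigma_e**2).sum()
    return float(ll)


def log_posterior(state: ParamState, frame: ModelFrame, priors: PriorSpec) -> float:
    """Unnormalised log posterior density; -inf for non-positive SDs."""
    sigma_u = np.asarray(state.sigma_u, dtype=float)
    sigma_e = np.asarray(state.sigma_e, dtype=float)
    if np.any(sigma_e <= 0) or (sigma_u.size and np.any(sigma_u <= 0)):
        return -np.inf
    lp = log_likelihood(state, frame)
    m0 = np.broadcast_to(np.asarray(priors.beta_mean, float), state.beta.shape)
    s0 = np.broadcast_to(np.asarray(priors.beta_sd, float), state.beta.shape)
    lp += float(
        np.sum(
            -0.5 * np.log(2 * np.pi)
            - np.log(s0)
            - 0.5 * ((state.beta - m0) / s0) ** 2
        )
    )
    if state.u.size:
        lp += float(
            np.sum(
                -0.5 * np.log(2 * np.pi)
                - np.log(sigma_u)
                - 0.5 * (state.u / sigma_u) ** 2
            )
        )
        lp += float(
            np.sum(_log_invgamma(sigma_u**2, priors.sigma_u_shape, priors.sigma_u_scale))
        )
    lp += float(
        np.sum(_log_invgamma(sigma_e**2, priors.sigma_e_shape, priors.sigma_e_scale))
    )
    return lp


# ---------------------------------------------------------------------------
# Gibbs kernel


class _GibbsKernel:
    """Cached sufficient statistics and exact full-conditional updates."""

    def __init__(
        self,
        frame: ModelFrame,
        priors: PriorSpec,
        sigma_u_fixed: Optional[float] = None,
        sigma_e_fixed: Optional[float] = None,
    ):
        self.frame = frame
        self.priors = priors
        self.sigma_u_fixed = sigma_u_fixed
        self.sigma_e_fixed = sigma_e_fixed
        self.X = frame.X
        self.Y = frame.Y
        self.codes = frame.subject_codes
        self.J = frame.n_subjects
        self.K = frame.n_outcomes
        self.p = frame.n_coef
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.Y  # (p, K)
        self.group_sizes = np.bincount(self.codes, minlength=self.J).astype(float)
        # per-subject row sums of X and Y, i.e. Z'X and Z'Y
        self.GX = np.zeros((self.J, self.p))
        np.add.at(self.GX, self.codes, self.X)
        self.GY = np.zeros((self.J, self.K))
        np.add.at(self.GY, self.codes, self.Y)
        m0 = np.broadcast_to(np.asarray(priors.beta_mean, float), (self.p, self.K))
        s0 = np.broadcast_to(np.asarray(priors.beta_sd, float), (self.p, self.K))
        self.m0 = np.array(m0)
        self.prior_prec = 1.0 / np.array(s0) ** 2  # diagonal of V0^-1, per dim
        self.has_re = self.J > 0 and not (sigma_u_fixed == 0.0)

    def sweep(self, state: ParamState, rng: np.random.Generator) -> ParamState:
        X, Y, codes = self.X, self.Y, self.codes
        beta = state.beta.copy()
        u = state.u.copy()
        sigma_u = state.sigma_u.copy()
        sigma_e = state.sigma_e.copy()
        pr = self.priors
        for d in range(self.K):
            se2 = sigma_e[d] ** 2
            # beta_d with u marginalised out: a blocked (beta, u) update.
            # V = se2*I + su2*ZZ'; by Woodbury X'V^-1 X = X'X/se2 - GX' diag(g) GX / se2^2
            # with g_j = 1 / (1/su2 + n_j/se2).  Collapsing u removes the strong
            # intercept-random-effect anticorrelation that slows plain Gibbs.
            A = self.XtX / se2
            b = self.Xty[:, d] / se2
            if self.has_re:
                su2 = sigma_u[d] ** 2
                g = 1.0 / (1.0 / su2 + self.group_sizes / se2)
                A -= (self.GX.T * g) @ self.GX / se2**2
                b -= self.GX.T @ (g * self.GY[:, d]) / se2**2
            A[np.diag_indices_from(A)] += self.prior_prec[:, d]
            b += self.prior_prec[:, d] * self.m0[:, d]
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"singular full-conditional precision for beta (dim {d})"
                ) from exc
            w = solve_triangular(L, b, lower=True, check_finite=False)
            z = rng.standard_normal(self.p)
            # mean + A^{-1/2} z in one back-substitution: A^{-1} = L^{-T} L^{-1}
            beta[:, d] = solve_triangular(
                L, w + z, trans="T", lower=True, check_finite=False
            )
            # u_{., d} | beta, sigmas: independent normals per subject
            if self.has_re:
                sums = self.GY[:, d] - self.GX @ beta[:, d]
                prec = self.group_sizes / se2 + 1.0 / su2
                u[:, d] = (sums / se2) / prec + rng.standard_normal(self.J) / np.sqrt(prec)
                # sigma_u_d^2 | u ~ IG(a + J/2, b + sum u^2 / 2)
                if self.sigma_u_fixed is None:
                    shape = pr.sigma_u_shape + 0.5 * self.J
                    scale = pr.sigma_u_scale + 0.5 * np.sum(u[:, d] ** 2)
                    sigma_u[d] = np.sqrt(scale / rng.gamma(shape))
            # sigma_e_d^2 | rest ~ IG(a + n/2, b + SSR/2)
            if self.sigma_e_fixed is None:
                r = Y[:, d] - X @ beta[:, d] - (u[codes, d] if u.size else 0.0)
                shape = pr.sigma_e_shape + 0.5 * len(r)
                scale = pr.sigma_e_scale + 0.5 * np.sum(r**2)
                sigma_e[d] = np.sqrt(scale / rng.gamma(shape))
        return ParamState(beta, u, sigma_u, sigma_e)


def gibbs_sweep(
    state: ParamState,
    frame: ModelFrame,
    priors: PriorSpec,
    rng: np.random.Generator,
    sigma_u_fixed: Optional[float] = None,
    sigma_e_fixed: Optional[float] = None,
) -> ParamState:
    """One full Gibbs sweep: each block drawn from its exact full conditional."""
    kernel = _GibbsKernel(frame, priors, sigma_u_fixed, sigma_e_fixed)
    return kernel.sweep(state, rng)


# ---------------------------------------------------------------------------
# model / results


class CompositionalMixedLM:
    """Multivariate random-intercept linear model on ALR outcomes.

    Parameters
    ----------
    Y : (n, K) outcome matrix (one column per ALR dimension).
    X : (n, p) fixed-effect design, leading intercept column.
    groups : (n,) subject codes (contiguous 0..J-1), or None for a model
        without random intercepts.
    """

    def __init__(
        self,
        Y: np.ndarray,
        X: np.ndarray,
        groups: Optional[np.ndarray] = None,
        *,
        coef_labels=None,
        outcome_labels=None,
        subject_ids=None,
    ):
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        if Y.shape[0] == 1 and Y.shape[1] > 1 and np.asarray(X).shape[0] > 1:
            Y = Y.T
        X = np.asarray(X, dtype=float)
        n = Y.shape[0]
        if groups is None:
            groups = np.zeros(n, dtype=int)
            subject_ids = ("_pooled",)
            self._has_re = False
        else:
            groups = np.asarray(groups, dtype=int)
            self._has_re = True
            if subject_ids is None:
                subject_ids = tuple(f"S{i + 1}" for i in range(groups.max() + 1))
        if coef_labels is None:
            coef_labels = tuple(f"x{j}" for j in range(X.shape[1]))
        if outcome_labels is None:
            outcome_labels = tuple(f"y{d}" for d in range(Y.shape[1]))
        self.frame = ModelFrame(
            Y=Y,
            X=X,
            subject_codes=groups,
            subject_ids=subject_ids,
            coef_labels=coef_labels,
            outcome_labels=outcome_labels,
        )

    @classmethod
    def from_frame(cls, frame: ModelFrame) -> "CompositionalMixedLM":
        model = cls.__new__(cls)
        model.frame = frame
        model._has_re = True
        return model

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome_cols,
        predictor_cols,
        group_col: str,
        add_intercept: bool = True,
    ) -> "CompositionalMixedLM":
        Y = data[list(outcome_cols)].to_numpy(float)
        X = data[list(predictor_cols)].to_numpy(float)
        labels = list(predictor_cols)
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            labels = ["(Intercept)"] + labels
        ids = list(dict.fromkeys(data[group_col]))
        codes = data[group_col].map({s: i for i, s in enumerate(ids)}).to_numpy(int)
        return cls(
            Y,
            X,
            codes,
            coef_labels=tuple(labels),
            outcome_labels=tuple(outcome_cols),
            subject_ids=tuple(str(s) for s in ids),
        )

    # -- densities ---------------------------------------------------------

    def log_likelihood(self, state: ParamState) -> float:
        return log_likelihood(state, self.frame)

    def log_posterior(self, state: ParamState, priors: PriorSpec) -> float:
        return log_posterior(state, self.frame, priors)

    # -- sampling ----------------------------------------------------------

    def _initial_state(
        self, rng: np.random.Generator, config: McmcConfig, sigma_u_fixed, sigma_e_fixed
    ) -> ParamState:
        p, K, J = self.frame.n_coef, self.frame.n_outcomes, self.frame.n_subjects
        if config.init == "random":
            beta = rng.standard_normal((p, K))
        else:
            beta = np.zeros((p, K))
        u = np.zeros((J, K)) if self._has_re else np.zeros((0, K))
        su = np.full(K, 1.0 if sigma_u_fixed is None else sigma_u_fixed)
        se = np.full(K, 1.0 if sigma_e_fixed is None else sigma_e_fixed)
        return ParamState(beta, u, su, se)

    def fit(
        self,
        priors: Optional[PriorSpec] = None,
        config: Optional[McmcConfig] = None,
        *,
        sigma_u_fixed: Optional[float] = None,
        sigma_e_fixed: Optional[float] = None,
    ) -> "MixedLMResults":
        """Run MCMC and return a results object with draws and diagnostics.

        ``sigma_u_fixed`` / ``sigma_e_fixed`` clamp the corresponding SDs
        (e.g. ``sigma_u_fixed=0`` drops the random intercept, the setting
        under which the Gibbs draws are exact i.i.d. samples from the
        closed-form conjugate posterior).
        """
        priors = priors or PriorSpec()
        config = config or McmcConfig()
        if config.sampler == "ensemble":
            draws = self._fit_ensemble(priors, config, sigma_u_fixed, sigma_e_fixed)
        else:
            draws = self._fit_gibbs(priors, config, sigma_u_fixed, sigma_e_fixed)
        return MixedLMResults(self, draws, priors)

    def _fit_gibbs(self, priors, config, sigma_u_fixed, sigma_e_fixed) -> PosteriorDraws:
        frame = self.frame
        if not self._has_re and sigma_u_fixed is None:
            sigma_u_fixed = 0.0
        kernel = _GibbsKernel(frame, priors, sigma_u_fixed, sigma_e_fixed)
        p, K, J = frame.n_coef, frame.n_outcomes, frame.n_subjects
        C, S = config.n_chains, config.n_keep
        beta = np.empty((C, S, p, K))
        u = np.empty((C, S, J if self._has_re else 0, K))
        sigma_u = np.empty((C, S, K))
        sigma_e = np.empty((C, S, K))
        seeds = np.random.SeedSequence(config.seed).spawn(C)
        for c in range(C):
            rng = np.random.default_rng(seeds[c])
            state = self._initial_state(rng, config, sigma_u_fixed, sigma_e_fixed)
            for it in range(config.n_iter):
                state = kernel.sweep(state, rng)
                k = it - config.n_warmup
                if k >= 0:
                    beta[c, k] = state.beta
                    u[c, k] = state.u
                    sigma_u[c, k] = state.sigma_u
                    sigma_e[c, k] = state.sigma_e
        draws = PosteriorDraws(
            beta=beta,
            u=u,
            sigma_u=sigma_u if self._has_re and sigma_u_fixed is None else sigma_u[:, :, :0],
            sigma_e=sigma_e if sigma_e_fixed is None else sigma_e[:, :, :0],
            coef_labels=frame.coef_labels,
            outcome_labels=frame.outcome_labels,
            subject_ids=frame.subject_ids,
            config=config,
            metadata={"sampler": "gibbs", "seed": config.seed},
        )
        return self._attach_diagnostics(draws)

    def _fit_ensemble(self, priors, config, sigma_u_fixed, sigma_e_fixed) -> PosteriorDraws:
        """Affine-invariant ensemble MCMC (emcee) over the same log posterior.

        Parameters are flattened as (beta, u, log sigma_u, log sigma_e) with
        the log-scale Jacobian folded into the target density.  Walkers are
        grouped into ``n_chains`` pseudo-chains for the diagnostics.
        """
        import emcee

        frame = self.frame
        p, K = frame.n_coef, frame.n_outcomes
        J = frame.n_subjects if self._has_re else 0
        if not self._has_re and sigma_u_fixed is None:
            sigma_u_fixed = 0.0
        free_su = sigma_u_fixed is None
        free_se = sigma_e_fixed is None
        ndim = p * K + J * K + (K if free_su else 0) + (K if free_se else 0)

        def unpack(theta: np.ndarray) -> tuple[ParamState, float]:
            i = 0
            beta = theta[i : i + p * K].reshape(p, K)
            i += p * K
            uu = theta[i : i + J * K].reshape(J, K)
            i += J * K
            jac = 0.0
            if free_su:
                t = theta[i : i + K]
                i += K
                su = np.exp(t)
                jac += np.sum(np.log(2.0) + 2.0 * t)  # d sigma^2 / d log sigma
            else:
                su = np.full(K, sigma_u_fixed)
            if free_se:
                t = theta[i : i + K]
                se = np.exp(t)
                jac += np.sum(np.log(2.0) + 2.0 * t)
            else:
                se = np.full(K, sigma_e_fixed)
            return ParamState(beta, uu, su, se), jac

        def log_prob(theta: np.ndarray) -> float:
            state, jac = unpack(theta)
            lp = log_posterior(state, frame, priors)
            return lp + jac if np.isfinite(lp) else -np.inf

        rng = np.random.default_rng(config.seed)
        n_walkers = max(2 * ndim + 2, 4 * config.n_chains)
        n_walkers += n_walkers % config.n_chains  # divisible into pseudo-chains
        p0 = 0.1 * rng.standard_normal((n_walkers, ndim))
        sampler = emcee.EnsembleSampler(n_walkers, ndim, log_prob)
        sampler.random_state = np.random.RandomState(
            np.random.SeedSequence(config.seed).generate_state(1)[0]
        ).get_state()
        sampler.run_mcmc(p0, config.n_iter, progress=False)
        chain = sampler.get_chain(discard=config.n_warmup)  # (S, walkers, ndim)
        S = chain.shape[0]
        C = config.n_chains
        per = n_walkers // C
        beta = np.empty((C, S * per, p, K))
        u = np.empty((C, S * per, J, K))
        sigma_u = np.empty((C, S * per, K))
        sigma_e = np.empty((C, S * per, K))
        for c in range(C):
            # walker-major ordering keeps each walker's trajectory contiguous,
            # so autocorrelation-based diagnostics see the true mixing speed
            block = (
                chain[:, c * per : (c + 1) * per, :]
                .transpose(1, 0, 2)
                .reshape(S * per, ndim)
            )
            for k, theta in enumerate(block):
                st, _ = unpack(theta)
                beta[c, k] = st.beta
                u[c, k] = st.u
                sigma_u[c, k] = st.sigma_u
                sigma_e[c, k] = st.sigma_e
        draws = PosteriorDraws(
            beta=beta,
            u=u,
            sigma_u=sigma_u if (self._has_re and free_su) else sigma_u[:, :, :0],
            sigma_e=sigma_e if free_se else sigma_e[:, :, :0],
            coef_labels=frame.coef_labels,
            outcome_labels=frame.outcome_labels,
            subject_ids=frame.subject_ids,
            config=config,
            metadata={"sampler": "ensemble", "seed": config.seed, "n_walkers": n_walkers},
        )
        return self._attach_diagnostics(draws)

    def _attach_diagnostics(self, draws: PosteriorDraws) -> PosteriorDraws:
        rhat = {}
        ess = {}
        for name, series in draws.scalar_series().items():
            rhat[name] = split_rhat(series)
            ess[name] = effective_sample_size(series)
        max_rhat = max(rhat.values()) if rhat else 1.0
        draws.metadata.update(
            {"rhat": rhat, "ess": ess, "max_rhat": max_rhat, "converged": max_rhat <= 1.05}
        )
        if max_rhat > 1.05:
            worst = max(rhat, key=rhat.get)
            warnings.warn(
                f"MCMC convergence suspect: max split-Rhat {max_rhat:.3f} ({worst}); "
                "inspect diagnostics before interpreting the posterior",
                ConvergenceWarning,
                stacklevel=3,
            )
        return draws


def fit(
    frame: ModelFrame,
    priors: Optional[PriorSpec] = None,
    config: Optional[McmcConfig] = None,
    **kwargs,
) -> PosteriorDraws:
    """Functional front-end: fit a frame, return the posterior draws."""
    return CompositionalMixedLM.from_frame(frame).fit(priors, config, **kwargs).draws


class MixedLMResults:
    """Posterior summaries, diagnostics and reports for a fitted model."""

    def __init__(self, model: CompositionalMixedLM, draws: PosteriorDraws, priors: PriorSpec):
        self.model = model
        self.draws = draws
        self.priors = priors

    @property
    def frame(self) -> ModelFrame:
        return self.model.frame

    @property
    def effect_estimates(self) -> pd.DataFrame:
        return _inference.effect_estimates(self.draws)

    @property
    def pod(self) -> pd.DataFrame:
        return _inference.probability_of_direction(self.draws)

    def credible_interval(self, level: float = 0.95):
        return _inference.credible_interval(self.draws, level)

    @property
    def random_intercept_sd(self) -> pd.Series:
        """Posterior median of sigma_u per ALR outcome dimension."""
        if not self.draws.sigma_u.size:
            return pd.Series(dtype=float)
        med = np.median(
            self.draws.sigma_u.reshape(-1, self.draws.sigma_u.shape[-1]), axis=0
        )
        return pd.Series(med, index=list(self.draws.outcome_labels), name="sigma_u")

    @property
    def rhat(self) -> pd.Series:
        return pd.Series(self.draws.metadata["rhat"], name="rhat")

    @property
    def ess(self) -> pd.Series:
        return pd.Series(self.draws.metadata["ess"], name="ess")

    def summary_frame(self) -> pd.DataFrame:
        return _inference.summary_table(self.draws)

    def summary(self) -> str:
        return _inference.render_summary(self.draws, self.frame)

    def residuals(self, plot_path=None):
        return _inference.residual_matrix(self.draws, self.frame, plot_path=plot_path)

    def recovery(self, truth) -> pd.DataFrame:
        return _inference.recovery_report(self.draws, truth)

    def plot_effect_posteriors(self, coefficients, path):
        return _inference.plot_effect_posteriors(self.draws, coefficients, path)
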