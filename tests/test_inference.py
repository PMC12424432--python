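"""Posterior summaries: medians, PoD, intervals, report tables, residuals."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from somnalr import inference
from somnalr.inference import (
    credible_interval,
    effect_estimates,
    interval,
    pod,
    pod_to_posterior_odds,
    posterior_median,
    probability_of_direction,
    recovery_report,
    residual_matrix,
    summary_table,
)
from somnalr.model import CompositionalMixedLM, ConvergenceWarning, McmcConfig, PosteriorDraws
from somnalr.preprocess import ModelFrame


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(10)
    n, p, K, J = 120, 3, 2, 8
    X = np.column_stack([np.ones(n), rng.standard_normal((n, p - 1))])
    codes = np.repeat(np.arange(J), n // J)
    beta = np.array([[1.0, -0.5], [0.8, 0.0], [-0.3, 0.4]])
    u = rng.standard_normal((J, K)) * 0.5
    Y = X @ beta + u[codes] + rng.standard_normal((n, K)) * 0.4
    frame = ModelFrame(
        Y=Y,
        X=X,
        subject_codes=codes,
        subject_ids=tuple(f"S{j}" for j in range(J)),
        coef_labels=("(Intercept)", "b", "c"),
        outcome_labels=("y0", "y1"),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        res = CompositionalMixedLM.from_frame(frame).fit(
            config=McmcConfig(n_chains=2, n_iter=1500, seed=11)
        )
    return res


class TestScalarSummaries:
    def test_median_conventions(self):
        assert posterior_median([1, 2, 3]) == 2
        assert posterior_median([1, 2, 3, 4]) == 2.5
        assert effect_estimates(np.array([3, 1, 2])) == 2

    def test_median_invariant_to_concatenation_order(self):
        a, b = np.arange(10.0), np.arange(10.0, 20.0)
        assert posterior_median(np.concatenate([a, b])) == posterior_median(
            np.concatenate([b, a])
        )

    def test_pod_examples(self):
        assert pod([1, 2, 3]) == 1.0
        assert pod([1, 2, 3, -1]) == 0.75
        assert pod([-2, -1, 1, 2]) == 0.5
        assert probability_of_direction(np.array([-1.0, -2.0, 3.0])) == pytest.approx(
            2 / 3
        )

    def test_pod_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500) + 0.3
        assert pod(x) == pod(x * 17.3)

    def test_pod_zero_draws_counted_in_neither_sign(self):
        assert pod([0.0, 0.0, 1.0, 2.0, -1.0]) == 0.4

    def test_pod_gaussian_limit(self):
        # for a Gaussian posterior PoD -> Phi(|mean| / sd)
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 1.0, size=400_000)
        assert pod(x) == pytest.approx(norm.cdf(0.5), abs=0.005)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            pod(np.array([]))
        with pytest.raises(ValueError):
            posterior_median(np.array([]))

    def test_interval_conventions(self):
        assert interval(np.full(50, 2.5), 0.95) == (2.5, 2.5)
        draws = np.arange(1.0, 101.0)
        lo, hi = interval(draws, 0.95)
        q = np.quantile(draws, [0.025, 0.975], method="linear")
        assert lo == pytest.approx(q[0], rel=1e-12)
        assert hi == pytest.approx(q[1], rel=1e-12)

    def test_interval_nesting(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1000)
        lo89, hi89 = interval(x, 0.89)
        lo95, hi95 = interval(x, 0.95)
        assert lo95 <= lo89 <= hi89 <= hi95

    def test_pod_to_odds(self):
        assert pod_to_posterior_odds(0.75) == 3.0
        assert pod_to_posterior_odds(0.5) == 1.0
        assert pod_to_posterior_odds(0.9) == pytest.approx(9.0)
        assert pod_to_posterior_odds(1.0) == np.inf
        with pytest.raises(ValueError):
            pod_to_posterior_odds(0.4)

    def test_odds_strictly_increasing(self):
        grid = np.linspace(0.5, 0.99, 50)
        odds = [pod_to_posterior_odds(p) for p in grid]
        assert np.all(np.diff(odds) > 0)


class TestSummaryTable:
    def test_shape_and_highlight_rule(self, fitted):
        table = summary_table(fitted.draws, fitted.frame)
        assert len(table) == 3 * 2
        recomputed = (table.pod > 0.75) & (table.coefficient != "(Intercept)")
        pd.testing.assert_series_equal(
            table.highlighted, recomputed, check_names=False
        )

    def test_intercept_never_highlighted(self, fitted):
        table = summary_table(fitted.draws)
        assert not table[table.coefficient == "(Intercept)"].highlighted.any()

    def test_estimates_inside_their_intervals(self, fitted):
        table = summary_table(fitted.draws)
        assert ((table.ci95_low <= table.ee) & (table.ee <= table.ci95_high)).all()
        assert ((table.ci95_low <= table.ci89_low) & (table.ci89_high <= table.ci95_high)).all()

    def test_label_mismatch_rejected(self, fitted):
        other = ModelFrame(
            Y=fitted.frame.Y,
            X=fitted.frame.X,
            subject_codes=fitted.frame.subject_codes,
            subject_ids=fitted.frame.subject_ids,
            coef_labels=("(Intercept)", "other", "c"),
            outcome_labels=fitted.frame.outcome_labels,
        )
        with pytest.raises(ValueError, match="labels"):
            summary_table(fitted.draws, other)

    def test_render_summary_text(self, fitted):
        text = fitted.summary()
        assert "Coefficient" in text and "PoD" in text
        assert "(Intercept)" in text


class TestResiduals:
    def test_exact_fit_gives_zero_residuals(self):
        # draws concentrated at the generating parameters -> residuals 0
        rng = np.random.default_rng(5)
        n, p, K, J = 30, 2, 1, 3
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        codes = np.repeat(np.arange(J), n // J)
        beta = np.array([[0.7], [-0.2]])
        u = rng.standard_normal((J, K))
        Y = X @ beta + u[codes]
        frame = ModelFrame(
            Y=Y, X=X, subject_codes=codes,
            subject_ids=("a", "b", "c"), coef_labels=("i", "x"),
            outcome_labels=("y0",),
        )
        draws = PosteriorDraws(
            beta=np.broadcast_to(beta, (2, 10, p, K)).copy(),
            u=np.broadcast_to(u, (2, 10, J, K)).copy(),
            sigma_u=np.ones((2, 10, K)),
            sigma_e=np.ones((2, 10, K)),
            coef_labels=frame.coef_labels,
            outcome_labels=frame.outcome_labels,
            subject_ids=frame.subject_ids,
            config=McmcConfig(seed=0),
        )
        resid, diag = residual_matrix(draws, frame)
        np.testing.assert_allclose(resid, 0.0, atol=1e-10)

    def test_wellspecified_fit_residual_moments(self):
        rng = np.random.default_rng(6)
        n, J = 450, 30
        X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
        codes = np.repeat(np.arange(J), n // J)
        beta = np.array([[0.5], [0.3], [-0.4]])
        u = 0.6 * rng.standard_normal((J, 1))
        Y = X @ beta + u[codes] + 0.5 * rng.standard_normal((n, 1))
        frame = ModelFrame(
            Y=Y, X=X, subject_codes=codes,
            subject_ids=tuple(f"S{j}" for j in range(J)),
            coef_labels=("i", "x1", "x2"), outcome_labels=("y0",),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = CompositionalMixedLM.from_frame(frame).fit(
                config=McmcConfig(n_chains=2, n_iter=1000, seed=7)
            )
        resid, diag = res.residuals()
        assert abs(diag["mean"].iloc[0]) < 0.1 * diag["sd"].iloc[0]
        assert abs(diag["skewness"].iloc[0]) < 0.5
        assert abs(diag["excess_kurtosis"].iloc[0]) < 1.0

    def test_residual_plot_written(self, fitted, tmp_path):
        path = tmp_path / "resid.png"
        fitted.residuals(plot_path=path)
        assert path.exists() and path.stat().st_size > 0


class TestRecovery:
    def test_bias_zero_when_truth_equals_median(self, fitted):
        class T:
            beta_true = effect_estimates(fitted.draws).to_numpy()

        rep = recovery_report(fitted.draws, T())
        np.testing.assert_allclose(rep.bias, 0.0, atol=1e-12)
        assert len(rep) == 3 * 2

    def test_zero_truth_has_no_sign_agreement(self, fitted):
        class T:
            beta_true = np.zeros((3, 2))

        rep = recovery_report(fitted.draws, T())
        assert rep.sign_agree.isna().all()

    def test_dimension_mismatch_rejected(self, fitted):
        class T:
            beta_true = np.zeros((4, 2))

        with pytest.raises(ValueError, match="shape"):
            recovery_report(fitted.draws, T())


class TestPlots:
    def test_effect_posterior_panels_written(self, fitted, tmp_path):
        path = tmp_path / "effects.png"
        fitted.plot_effect_posteriors(["b", "c"], path)
        assert path.exists() and path.stat().st_size > 0


class TestCredibleIntervalDispatch:
    def test_frame_output_for_posterior_draws(self, fitted):
        lo, hi = credible_interval(fitted.draws, 0.95)
        assert lo.shape == (3, 2)
        assert (lo.to_numpy() <= hi.to_numpy()).all()
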