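"""Posterior summarisation and reporting.

Effect estimates are posterior medians of the pooled (across-chain) draws;
the probability of direction (PoD) is the share of pooled draws sharing the
sign of the median — an index of how certain the *direction* of an effect
is, with PoD > 0.75 corresponding to posterior odds > 3 ("substantial"
evidence).  Credible intervals are equal-tailed posterior quantile
intervals, reported at both 89% and 95%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectSummary",
    "posterior_median",
    "pod",
    "interval",
    "effect_estimates",
    "probability_of_direction",
    "credible_interval",
    "pod_to_posterior_odds",
    "summary_table",
    "render_summary",
    "residual_matrix",
    "recovery_report",
    "plot_effect_posteriors",
]

POD_HIGHLIGHT_THRESHOLD = 0.75


@dataclass(frozen=True)
class EffectSummary:
    """One coefficient x outcome cell of the report table."""

    coefficient: str
    outcome: str
    ee: float
    pod: float
    ci95_low: float
    ci95_high: float
    ci89_low: float
    ci89_high: float
    highlighted: bool


# -- scalar draw helpers -----------------------------------------------------


def posterior_median(samples: np.ndarray) -> float:
    """Median of pooled draws (linear interpolation at even counts)."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty draws")
    return float(np.median(samples))


def pod(samples: np.ndarray) -> float:
    """Probability of direction of one scalar parameter.

    Share of draws with the same sign as the pooled median; draws exactly
    at zero count toward neither sign.  If the median itself is exactly
    zero the larger of the two signed shares is returned.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty draws")
    med = np.median(samples)
    pos = np.mean(samples > 0)
    neg = np.mean(samples < 0)
    if med > 0:
        return float(pos)
    if med < 0:
        return float(neg)
    return float(max(pos, neg))


def interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval of pooled draws."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise ValueError("empty draws")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def pod_to_posterior_odds(p: float) -> float:
    """Map a probability of direction to posterior odds, p / (1 - p).

    At the reporting threshold 0.75 this equals 3, the conventional bound
    for substantial evidence.
    """
    if p < 0.5:
        raise ValueError("PoD is bounded below by 0.5")
    if p >= 1.0:
        if p == 1.0:
            return float("inf")
        raise ValueError("PoD cannot exceed 1")
    return p / (1.0 - p)


# -- PosteriorDraws-level summaries ------------------------------------------


def _beta_frame(draws, fn) -> pd.DataFrame:
    pooled = draws.pooled_beta()  # (N, p, K)
    p, K = pooled.shape[1], pooled.shape[2]
    out = np.empty((p, K))
    for a in range(p):
        for d in range(K):
            out[a, d] = fn(pooled[:, a, d])
    return pd.DataFrame(
        out, index=list(draws.coef_labels), columns=list(draws.outcome_labels)
    )


def effect_estimates(draws):
    """Posterior median of every fixed effect (coefficients x outcomes);
    a raw draw array yields its scalar pooled median."""
    if isinstance(draws, (np.ndarray, list, tuple)):
        return posterior_median(np.asarray(draws))
    return _beta_frame(draws, posterior_median)


def probability_of_direction(draws) -> pd.DataFrame:
    """PoD of every fixed effect (coefficients x outcomes)."""
    if isinstance(draws, (np.ndarray, list, tuple)):
        return pod(np.asarray(draws))
    return _beta_frame(draws, pod)


def credible_interval(draws, level: float = 0.95):
    """Equal-tailed interval; accepts raw draws or a PosteriorDraws object."""
    if isinstance(draws, (np.ndarray, list, tuple)):
        return interval(np.asarray(draws), level)
    lo = _beta_frame(draws, lambda s: interval(s, level)[0])
    hi = _beta_frame(draws, lambda s: interval(s, level)[1])
    return lo, hi


def summary_table(draws, frame=None) -> pd.DataFrame:
    """Long-format report: EE, PoD and 89/95% intervals per coefficient and
    outcome, with the highlight flag (PoD > 0.75, intercept excluded)."""
    if frame is not None:
        if tuple(frame.coef_labels) != tuple(draws.coef_labels) or tuple(
            frame.outcome_labels
        ) != tuple(draws.outcome_labels):
            raise ValueError("draws and frame labels do not match")
    pooled = draws.pooled_beta()
    rows = []
    for a, coef in enumerate(draws.coef_labels):
        for d, outc in enumerate(draws.outcome_labels):
            s = pooled[:, a, d]
            ee = posterior_median(s)
            p_dir = pod(s)
            lo95, hi95 = interval(s, 0.95)
            lo89, hi89 = interval(s, 0.89)
            rows.append(
                EffectSummary(
                    coefficient=coef,
                    outcome=outc,
                    ee=ee,
                    pod=p_dir,
                    ci95_low=lo95,
                    ci95_high=hi95,
                    ci89_low=lo89,
                    ci89_high=hi89,
                    highlighted=bool(
                        p_dir > POD_HIGHLIGHT_THRESHOLD and coef != "(Intercept)"
                    ),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def render_summary(draws, frame=None) -> str:
    """Text report in the style of the study tables: one row per
    coefficient, EE and PoD per ALR outcome, highlights marked with ``*``
    and rendered to two decimals."""
    table = summary_table(draws, frame)
    coefs = list(dict.fromkeys(table["coefficient"]))
    outcomes = list(dict.fromkeys(table["outcome"]))
    lines = []
    header = f"{'Coefficient':<28}" + "".join(
        f"{o + ' EE':>16}{'PoD':>8}" for o in outcomes
    )
    lines.append("Estimated median fixed effects (posterior medians and PoD)")
    lines.append("=" * len(header))
    lines.append(header)
    lines.append("-" * len(header))
    for coef in coefs:
        cells = []
        for outc in outcomes:
            row = table[(table.coefficient == coef) & (table.outcome == outc)].iloc[0]
            star = "*" if row.highlighted else " "
            cells.append(f"{row.ee:>15.2f} {row.pod:>6.2f}{star}")
        lines.append(f"{coef:<28}" + "".join(cells))
    lines.append("-" * len(header))
    lines.append("* PoD > 0.75 (posterior odds > 3), intercept never flagged")
    meta = draws.metadata
    lines.append(
        f"sampler: {meta.get('sampler')}  chains: {draws.n_chains}  "
        f"draws/chain: {draws.n_draws}  max split-Rhat: {meta.get('max_rhat', float('nan')):.3f}"
    )
    return "\n".join(lines)


# -- residual diagnostics ----------------------------------------------------


def residual_matrix(draws, frame, plot_path=None):
    """Residuals at the posterior-median parameters, with moment diagnostics.

    Residuals are Y - X beta_hat - u_hat[subject], computed per ALR
    dimension from the pooled posterior medians.  The diagnostics report
    per-dimension mean, SD, skewness and excess kurtosis; if ``plot_path``
    is given a residual-vs-fitted panel is written there.
    """
    from scipy import stats

    pooled_beta = np.median(draws.pooled_beta(), axis=0)  # (p, K)
    fitted = frame.X @ pooled_beta
    if draws.u.size:
        C, S, J, K = draws.u.shape
        u_hat = np.median(draws.u.reshape(C * S, J, K), axis=0)
        fitted = fitted + u_hat[frame.subject_codes]
    resid = frame.Y - fitted
    diag = pd.DataFrame(
        {
            "outcome": list(draws.outcome_labels),
            "mean": resid.mean(axis=0),
            "sd": resid.std(axis=0, ddof=1),
            "skewness": stats.skew(resid, axis=0),
            "excess_kurtosis": stats.kurtosis(resid, axis=0),
        }
    )
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        K = resid.shape[1]
        fig, axes = plt.subplots(1, K, figsize=(4 * K, 3.2), squeeze=False)
        for d in range(K):
            ax = axes[0, d]
            ax.scatter(fitted[:, d], resid[:, d], s=8, alpha=0.6)
            ax.axhline(0.0, color="grey", lw=0.8)
            ax.set_xlabel("fitted")
            ax.set_ylabel("residual")
            ax.set_title(draws.outcome_labels[d])
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return resid, diag


# -- parameter recovery ------------------------------------------------------


def recovery_report(draws, truth) -> pd.DataFrame:
    """Score the fit against known generating parameters.

    One row per fixed-effect entry: bias (median - truth), absolute error,
    95% credible-interval coverage indicator, PoD and whether the PoD
    direction agrees with the true sign (NaN where the truth is exactly 0,
    which has no sign).
    """
    beta_true = np.asarray(truth.beta_true, dtype=float)
    pooled = draws.pooled_beta()
    p, K = pooled.shape[1], pooled.shape[2]
    if beta_true.shape != (p, K):
        raise ValueError(
            f"truth shape {beta_true.shape} does not match draws ({p}, {K})"
        )
    rows = []
    for a, coef in enumerate(draws.coef_labels):
        for d, outc in enumerate(draws.outcome_labels):
            s = pooled[:, a, d]
            ee = posterior_median(s)
            lo, hi = interval(s, 0.95)
            p_dir = pod(s)
            t = beta_true[a, d]
            sign_agree = np.nan if t == 0 else float(np.sign(ee) == np.sign(t))
            rows.append(
                {
                    "coefficient": coef,
                    "outcome": outc,
                    "truth": t,
                    "ee": ee,
                    "bias": ee - t,
                    "abs_error": abs(ee - t),
                    "ci95_low": lo,
                    "ci95_high": hi,
                    "covered": bool(lo <= t <= hi),
                    "pod": p_dir,
                    "sign_agree": sign_agree,
                }
            )
    return pd.DataFrame(rows)


# -- plots -------------------------------------------------------------------


def plot_effect_posteriors(draws, coefficients: Sequence[str], path):
    """Posterior density panels with median, 95% and 89% interval marks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats

    pooled = draws.pooled_beta()
    coefs = list(coefficients)
    outcomes = list(draws.outcome_labels)
    fig, axes = plt.subplots(
        len(coefs), len(outcomes), figsize=(3.6 * len(outcomes), 2.6 * len(coefs)),
        squeeze=False,
    )
    for i, coef in enumerate(coefs):
        a = list(draws.coef_labels).index(coef)
        for d, outc in enumerate(outcomes):
            ax = axes[i, d]
            s = pooled[:, a, d]
            grid = np.linspace(s.min(), s.max(), 256)
            dens = stats.gaussian_kde(s)(grid)
            ax.plot(grid, dens, color="C0")
            lo89, hi89 = interval(s, 0.89)
            band = (grid >= lo89) & (grid <= hi89)
            ax.fill_between(grid[band], dens[band], alpha=0.3, color="C0")
            for q in interval(s, 0.95):
                ax.axvline(q, color="navy", lw=1.0)
            ax.axvline(posterior_median(s), color="C1", lw=1.2)
            if i == 0:
                ax.set_title(outc)
            if d == 0:
                ax.set_ylabel(coef, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
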