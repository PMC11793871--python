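"""Gene-level empirical-Bayes moderated t-test, FDR, and hit calling.

Each gene's residual effects (one observation per retained guide per
biological replicate) are summarized by their mean ``beta`` and sample
variance ``s²``.  With only a handful of observations per gene, raw
variances are noisy, so they are shrunk toward a genome-wide prior
estimated by empirical Bayes: sample variances are modeled as scaled
chi-square draws around gene variances that follow a scaled inverse
chi-square prior with ``d0`` degrees of freedom and scale ``s0²``.  The
posterior variance

    s̃² = (d0·s0² + df·s²) / (d0 + df)

replaces s² in a one-sample t-statistic with ``d0 + df`` degrees of
freedom.  The prior is fitted by the standard method of moments on
log-variances (matching moments of the log chi-square distribution via
digamma/trigamma functions).  Benjamini–Hochberg step-up converts the
two-sided p-values into FDRs, and hits are called by joint effect-size
and FDR thresholds, both strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

#: Stand-in degrees of freedom when the prior is effectively infinite.
DF_CAP = 1e6

SUMMARY_COLUMNS = ["gene", "beta", "s_sq", "df", "n_obs"]


@dataclass(frozen=True)
class EBayesPrior:
    """Prior degrees of freedom and variance of the moderation model."""

    d0: float  # may be math.inf; 0 is the no-moderation limit (ordinary t)
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValidationError(f"prior d0 must be non-negative, got {self.d0}")
        if not self.s0_sq > 0:
            raise ValidationError(f"prior s0_sq must be positive, got {self.s0_sq}")


def summarize_genes(effects: pd.DataFrame, min_obs: int = 2) -> pd.DataFrame:
    """Per-gene mean, unbiased variance, and df of the residual effects.

    Genes with fewer than ``min_obs`` observations are returned with NaN
    variance and df 0; downstream they receive call NONE and no p-value.
    """
    grouped = effects.groupby("gene", sort=True)["residual"]
    summary = grouped.agg(beta="mean", s_sq="var", n_obs="count").reset_index()
    summary["df"] = summary["n_obs"] - 1
    too_few = summary["n_obs"] < min_obs
    summary.loc[too_few, ["s_sq"]] = np.nan
    summary.loc[too_few, "df"] = 0
    return summary[SUMMARY_COLUMNS]


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValidationError("trigamma inverse requires a positive argument")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + step
        if abs(step) < tol * x:
            break
    return float(x)


def fit_ebayes_prior(summaries: pd.DataFrame, min_genes: int = 100) -> EBayesPrior:
    """Method-of-moments fit of (d0, s0²) from per-gene sample variances.

    With z_j = log s_j² and residual df d_j, the centered values
    e_j = z_j − ψ(d_j/2) + log(d_j/2) are unbiased for log σ_j² up to a
    constant; their excess spread over the chi-square contribution,

        mean_j[(e_j − ē)² · n/(n−1) − ψ'(d_j/2)] = ψ'(d0/2),

    identifies d0 through the trigamma inverse, and
    s0² = exp(ē + ψ(d0/2) − log(d0/2)).  A non-positive left-hand side
    means the variances spread no more than chi-square sampling alone:
    d0 = ∞ and s0² = exp(ē).

    Genes with zero or missing variance or df < 1 are excluded from the
    fit (they still receive moderated statistics afterwards).
    """
    usable = summaries[(summaries["df"] >= 1) & (summaries["s_sq"] > 0)]
    n = len(usable)
    if n < min_genes:
        import warnings

        warnings.warn(
            f"only {n} genes with positive variance (< {min_genes}); "
            "falling back to a pooled-variance prior (d0 = inf)",
            stacklevel=2,
        )
        if n == 0:
            raise ValidationError("no genes with positive variance")
        s_sq = usable["s_sq"].to_numpy(dtype=float)
        dfs = usable["df"].to_numpy(dtype=float)
        e = np.log(s_sq) - special.digamma(dfs / 2) + np.log(dfs / 2)
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(e.mean())))

    s_sq = usable["s_sq"].to_numpy(dtype=float)
    dfs = usable["df"].to_numpy(dtype=float)
    z = np.log(s_sq)
    e = z - special.digamma(dfs / 2) + np.log(dfs / 2)
    e_bar = e.mean()
    excess = float(
        np.mean((e - e_bar) ** 2 * n / (n - 1) - special.polygamma(1, dfs / 2))
    )
    if excess <= 0:
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(e_bar)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def posterior_variance(
    s_sq: np.ndarray, df: np.ndarray, prior: EBayesPrior
) -> np.ndarray:
    """Shrunken variance s̃² = (d0·s0² + df·s²)/(d0 + df); s0² if d0 = ∞."""
    s_sq = np.nan_to_num(np.asarray(s_sq, dtype=float), nan=0.0)
    df = np.asarray(df, dtype=float)
    if np.isinf(prior.d0):
        return np.full_like(s_sq, prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s_sq) / (prior.d0 + df)


def moderated_t(
    summaries: pd.DataFrame, prior: EBayesPrior
) -> pd.DataFrame:
    """Moderated t statistics, total df, and two-sided p per gene.

    Genes with df 0 (a single observation) get NaN statistics.  ``d0 = 0``
    is admitted as a limit and reduces to the ordinary one-sample t.
    """
    out = summaries.copy()
    df = out["df"].to_numpy(dtype=float)
    s_tilde = posterior_variance(out["s_sq"].to_numpy(), df, prior)
    if (s_tilde <= 0).any():
        raise ValidationError("posterior variance is zero; prior invalid")
    n = out["n_obs"].to_numpy(dtype=float)
    t = out["beta"].to_numpy(dtype=float) / np.sqrt(s_tilde / n)
    df_total = np.minimum(prior.d0 + df, DF_CAP)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    scored = df >= 1
    out["t_mod"] = np.where(scored, t, np.nan)
    out["df_total"] = np.where(scored, df_total, np.nan)
    out["p_value"] = np.where(scored, p, np.nan)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_hits(
    results: pd.DataFrame,
    effect_threshold: float = 0.5,
    fdr_threshold: float = 0.4,
) -> pd.DataFrame:
    """Threshold-based hit calls; both inequalities strict.

    RESISTANCE when fdr < fdr_threshold and effect > +effect_threshold;
    SENSITIVITY when fdr < fdr_threshold and effect < −effect_threshold;
    otherwise NONE.
    """
    out = results.copy()
    sig = out["fdr"] < fdr_threshold
    call = np.where(
        sig & (out["effect"] > effect_threshold),
        "RESISTANCE",
        np.where(sig & (out["effect"] < -effect_threshold), "SENSITIVITY", "NONE"),
    )
    out["call"] = np.where(out["fdr"].isna(), "NONE", call)
    return out


def score_genes(
    effects: pd.DataFrame,
    prior: EBayesPrior | None = None,
    effect_threshold: float = 0.5,
    fdr_threshold: float = 0.4,
    min_obs: int = 2,
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Residual effects → scored gene results for one compound contrast.

    FDR is computed across all scored genes of this contrast.  Returns
    the result table (columns gene, effect, n_obs, t_mod, df_total,
    p_value, fdr, call) and the fitted prior.
    """
    summaries = summarize_genes(effects, min_obs=min_obs)
    if prior is None:
        prior = fit_ebayes_prior(summaries)
    scored = moderated_t(summaries, prior)
    scored = scored.rename(columns={"beta": "effect"})
    has_p = scored["p_value"].notna()
    fdr = np.full(len(scored), np.nan)
    fdr[has_p.to_numpy()] = bh_adjust(scored.loc[has_p, "p_value"].to_numpy())
    scored["fdr"] = fdr
    scored = call_hits(scored, effect_threshold, fdr_threshold)
    cols = ["gene", "effect", "n_obs", "t_mod", "df_total", "p_value", "fdr", "call"]
    return scored[cols], prior
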