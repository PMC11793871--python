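"""Treated-vs-mock residual effects via M-A transformation and Loess.

For every guide with both a treated and a mock log2 fold change in a
biological replicate, the pair is reparameterized as a difference
M = lfc_treated − lfc_mock and an average A = (lfc_treated + lfc_mock)/2.
Any smooth intensity-dependent skew (M drifting with A, e.g. from
abundance-dependent PCR or growth artifacts) is then removed by a robust
locally weighted linear regression of M on A; the residuals are the
normalized per-guide effects handed to the gene-level moderated t-test.
Positive residual = enrichment under drug = resistance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError
from .io import GuideLibrary

EFFECT_COLUMNS = ["guide_id", "gene", "bio_rep", "M", "A", "fitted", "residual"]

#: Minimum points per Loess stratum; below this the local fit is unstable.
MIN_STRATUM = 50

#: Outlier exclusion threshold (MADs from the robust linear pre-fit).
GUARD_MADS = 3.0


def average_technical_replicates(lfcs: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to their arithmetic-mean LFC.

    Returns one record per (guide_id, condition, bio_rep); groups with a
    single technical replicate pass through unchanged.
    """
    out = (
        lfcs.groupby(["guide_id", "condition", "bio_rep"], sort=False)["lfc"]
        .mean()
        .reset_index()
    )
    return out


def ma_transform(treated_lfc, mock_lfc):
    """M-A reparameterization: M = treated − mock, A = their mean."""
    treated = np.asarray(treated_lfc, dtype=float)
    mock = np.asarray(mock_lfc, dtype=float)
    return treated - mock, (treated + mock) / 2.0


def loess_fit(
    a: np.ndarray,
    m: np.ndarray,
    span: float = 0.3,
    robust_iters: int = 3,
    guard_mads: float | None = GUARD_MADS,
) -> np.ndarray:
    """Fitted values of a robust degree-1 Loess of M on A at the data points.

    Tricube-weighted local linear regression with ``span`` of the data in
    each window and ``robust_iters`` bisquare reweighting passes to damp
    outliers.  Interpolation between fit points is used on large inputs
    (delta = 1% of the A range), standard practice for Loess at screen scale.

    A local smoother tracks whatever dominates a neighborhood, so guides
    under strong selection — which pile up at the extremes of A — would
    have their signal absorbed into the "trend" and erased.  To prevent
    this, the fit is guarded: a global robust linear pre-fit (Tukey
    bisquare), which a concentrated minority cannot hijack, flags points
    farther than ``guard_mads`` MADs from it; flagged points are excluded
    from the Loess fit and receive the trend interpolated from their
    neighbors.  Set ``guard_mads=None`` for a plain Loess.
    """
    if not 0 < span <= 1:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    keep = np.ones(len(a), dtype=bool)
    # skip the guard when an ordinary linear fit is already (near-)exact:
    # RLM degenerates there and there is nothing to protect
    ols_resid = m - np.polyval(np.polyfit(a, m, 1), a)
    ols_mad = np.median(np.abs(ols_resid - np.median(ols_resid)))
    if guard_mads is not None and len(a) >= MIN_STRATUM and ols_mad > 1e-9:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pre = sm.RLM(
                m, sm.add_constant(a), M=sm.robust.norms.TukeyBiweight()
            ).fit()
        r = m - np.asarray(pre.fittedvalues)
        med = np.median(r)
        mad = 1.4826 * np.median(np.abs(r - med))
        if np.isfinite(r).all() and mad > 0:
            keep = np.abs(r - med) < guard_mads * mad

    delta = 0.01 * float(np.ptp(a[keep])) if keep.sum() > 500 else 0.0
    if keep.all():
        return lowess(
            m, a, frac=span, it=robust_iters, delta=delta, return_sorted=False
        )
    fit = lowess(m[keep], a[keep], frac=span, it=robust_iters, delta=delta)
    # excluded points take the trend of their neighbors (constant beyond
    # the kept range); duplicate abscissae are fine for interp
    return np.interp(a, fit[:, 0], fit[:, 1])


def loess_normalize(
    points: pd.DataFrame,
    span: float = 0.3,
    robust_iters: int = 3,
    stratify: str = "replicate",
    min_stratum: int = MIN_STRATUM,
    guard_mads: float | None = GUARD_MADS,
) -> pd.DataFrame:
    """Remove the Loess trend of M on A; residuals are the guide effects.

    ``stratify='replicate'`` fits one trend per biological replicate (the
    default: treated/mock pairing is within replicate); ``'pooled'`` fits
    a single trend to all points.

    Input must carry columns guide_id, bio_rep, M, A (gene optional);
    output adds ``fitted`` and ``residual``.
    """
    if stratify not in ("replicate", "pooled"):
        raise ValidationError(f"unknown stratify mode {stratify!r}")
    for col in ("M", "A"):
        vals = points[col].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError(f"non-finite {col} values in M-A input")

    groups = (
        points.groupby("bio_rep", sort=False)
        if stratify == "replicate"
        else [(None, points)]
    )
    pieces = []
    for key, grp in groups:
        if len(grp) < min_stratum:
            raise ValidationError(
                f"Loess stratum {key!r} has {len(grp)} points "
                f"(minimum {min_stratum}); pool strata with stratify='pooled'"
            )
        a = grp["A"].to_numpy(dtype=float)
        m = grp["M"].to_numpy(dtype=float)
        fitted = loess_fit(
            a, m, span=span, robust_iters=robust_iters, guard_mads=guard_mads
        )
        out = grp.copy()
        out["fitted"] = fitted
        out["residual"] = m - fitted
        pieces.append(out)
    return pd.concat(pieces, ignore_index=True)


def pair_treated_mock(
    lfcs: pd.DataFrame, compound: str
) -> pd.DataFrame:
    """Join treated and mock LFCs per (guide, bio_rep) and M-A transform.

    Guides lacking either member of the pair in a replicate (e.g. filtered
    from one replicate's T0) contribute no observation for that replicate.
    """
    treated = lfcs[lfcs["condition"] == compound]
    mock = lfcs[lfcs["condition"] == "MOCK"]
    if treated.empty:
        raise ValidationError(f"condition not found in LFC table: {compound!r}")
    if mock.empty:
        raise ValidationError("no MOCK samples in LFC table")
    merged = treated.merge(
        mock,
        on=["guide_id", "bio_rep"],
        suffixes=("_treated", "_mock"),
        how="inner",
    )
    if merged.empty:
        raise ValidationError(
            f"no shared biological replicate between {compound!r} and MOCK"
        )
    m, a = ma_transform(
        merged["lfc_treated"].to_numpy(), merged["lfc_mock"].to_numpy()
    )
    return pd.DataFrame(
        {
            "guide_id": merged["guide_id"],
            "bio_rep": merged["bio_rep"],
            "M": m,
            "A": a,
        }
    )


def compute_residual_effects(
    lfcs: pd.DataFrame,
    compound: str,
    library: GuideLibrary,
    span: float = 0.3,
    robust_iters: int = 3,
    stratify: str = "replicate",
    min_stratum: int = MIN_STRATUM,
    guard_mads: float | None = GUARD_MADS,
) -> pd.DataFrame:
    """Full residual-effect chain for one compound contrast.

    Averages technical replicates, pairs treated with mock per
    (guide, bio_rep), M-A transforms, and Loess-normalizes.  Returns one
    record per (guide, bio_rep) with columns guide_id, gene, bio_rep, M,
    A, fitted, residual.
    """
    averaged = average_technical_replicates(lfcs)
    points = pair_treated_mock(averaged, compound)
    effects = loess_normalize(
        points,
        span=span,
        robust_iters=robust_iters,
        stratify=stratify,
        min_stratum=min_stratum,
        guard_mads=guard_mads,
    )
    effects["gene"] = library.gene_of.reindex(effects["guide_id"]).to_numpy()
    return effects[EFFECT_COLUMNS]
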