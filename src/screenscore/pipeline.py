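"""End-to-end scoring of one compound contrast.

Chain: T0-depth guide filter → reads-per-million normalization → per-guide
log2 fold change vs matched T0 → technical-replicate averaging →
treated-vs-mock M-A Loess residuals → gene-level moderated t → BH FDR →
hit calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd

from .errors import ValidationError
from .io import CountTable, GuideLibrary, SampleSheet
from .lfc import compute_guide_lfc, filter_guides, normalize_depth
from .residuals import MIN_STRATUM, compute_residual_effects
from .stats import EBayesPrior, score_genes


@dataclass(frozen=True)
class ScoreConfig:
    """All tunable parameters of the scoring chain (log2 scale throughout)."""

    pseudocount: float = 0.5
    min_t0_count: int = 30
    min_guides_per_gene: int = 3
    filter_mode: str = "replicate"  # or "global"
    span: float = 0.3
    robust_iters: int = 3
    guard_mads: float | None = 3.0  # signal-guard threshold; None = plain Loess
    loess_stratify: str = "replicate"  # or "pooled"
    min_stratum: int = MIN_STRATUM
    effect_threshold: float = 0.5
    fdr_threshold: float = 0.4


@dataclass
class ScoreResult:
    """Scored gene table plus the run's fitted prior and filter report."""

    results: pd.DataFrame
    prior: EBayesPrior
    filter_report: dict
    effects: pd.DataFrame  # per-(guide, bio_rep) diagnostic table
    config: ScoreConfig

    @property
    def hit_tally(self) -> dict:
        counts = self.results["call"].value_counts()
        return {
            "RESISTANCE": int(counts.get("RESISTANCE", 0)),
            "SENSITIVITY": int(counts.get("SENSITIVITY", 0)),
            "NONE": int(counts.get("NONE", 0)),
        }


def score_screen(
    counts: CountTable,
    library: GuideLibrary,
    sheet: SampleSheet,
    compound: str,
    config: ScoreConfig = ScoreConfig(),
) -> ScoreResult:
    """Score one compound-vs-mock contrast of a pooled knockout screen.

    ``compound`` must match a condition label in the sample sheet.  The
    returned table covers every gene that survived the guides-per-gene
    filter; genes with fewer than two residual observations carry NaN
    statistics and call NONE.  FDR is computed across the scored genes of
    this contrast only.
    """
    if compound not in sheet.conditions:
        raise ValidationError(
            f"condition not found in sample sheet: {compound!r} "
            f"(available: {sheet.conditions})"
        )
    filt = filter_guides(
        counts,
        library,
        sheet,
        min_t0_count=config.min_t0_count,
        min_guides_per_gene=config.min_guides_per_gene,
        mode=config.filter_mode,
    )
    norm = normalize_depth(counts)
    lfcs = compute_guide_lfc(
        norm, sheet, pseudocount=config.pseudocount, retained=filt
    )
    effects = compute_residual_effects(
        lfcs,
        compound,
        library,
        span=config.span,
        robust_iters=config.robust_iters,
        stratify=config.loess_stratify,
        min_stratum=config.min_stratum,
        guard_mads=config.guard_mads,
    )
    effects = effects[effects["gene"].isin(filt.retained_genes)]
    if effects.empty:
        raise ValidationError("no residual observations left after filtering")
    results, prior = score_genes(
        effects,
        effect_threshold=config.effect_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    return ScoreResult(
        results=results,
        prior=prior,
        filter_report=filt.report,
        effects=effects,
        config=config,
    )
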