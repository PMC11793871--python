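"""Depth normalization, per-guide log2 fold changes, and abundance filters.

Counts are scaled to reads-per-million within each sample, then each
non-baseline sample's guide abundances are expressed as log2 fold change
against its matched T0 sample.  Guides that were too shallowly sequenced
at T0 (raw count below ``min_t0_count``) carry no usable fold-change
signal and are removed; genes left with too few guides are removed from
scoring entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountTable, GuideLibrary, SampleSheet

LFC_COLUMNS = ["guide_id", "condition", "bio_rep", "tech_rep", "lfc"]


@dataclass(frozen=True)
class NormalizedCounts:
    """Reads-per-million scaled abundances; same shape as the count table."""

    values: pd.DataFrame
    scale: float = 1e6

    @property
    def guides(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


@dataclass(frozen=True)
class FilterResult:
    """Outcome of the T0-depth and guides-per-gene filters.

    ``passes`` records, per guide and per T0 sample actually referenced by
    the sheet, whether the guide's raw T0 count met the threshold.  In
    ``replicate`` mode a guide contributes observations only from
    replicates whose T0 it passed, and is dropped globally only when it
    passes nowhere; in ``global`` mode it must pass every T0.
    """

    passes: pd.DataFrame  # bool, guides × T0 samples
    retained_guides: pd.Index
    retained_genes: pd.Index
    mode: str
    report: dict = field(default_factory=dict)

    def guide_passes(self, guide_id: str, t0_sample: str) -> bool:
        return bool(self.passes.at[guide_id, t0_sample])


def normalize_depth(counts: CountTable, scale: float = 1e6) -> NormalizedCounts:
    """Scale each sample column to sum to ``scale`` (reads per million)."""
    if scale <= 0:
        raise ValidationError(f"scale must be positive, got {scale}")
    totals = counts.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"sample(s) with zero total count: {list(zero.index)}"
        )
    values = counts.counts / totals * scale
    return NormalizedCounts(values=values, scale=scale)


def compute_guide_lfc(
    norm: NormalizedCounts,
    sheet: SampleSheet,
    pseudocount: float = 0.5,
    retained: FilterResult | None = None,
) -> pd.DataFrame:
    """Per-guide log2 fold change of each non-T0 sample vs its matched T0.

    lfc(g, s) = log2((norm(g, s) + pseudocount) / (norm(g, t0_ref(s)) + pseudocount))

    The pseudocount (on the normalized scale) keeps the ratio finite when
    a guide drops to zero reads.  When a :class:`FilterResult` is given,
    a guide yields a record for a sample only if it passed the T0-depth
    filter in that sample's matched T0.

    Returns a long DataFrame with columns guide_id, condition, bio_rep,
    tech_rep, lfc.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be non-negative")
    records = []
    for sid, row in sheet.frame.iterrows():
        if row["condition"] == "T0":
            continue
        if sid not in norm.samples:
            continue
        t0 = row["t0_ref"]
        if t0 not in norm.samples:
            raise ValidationError(f"matched T0 sample {t0!r} missing from counts")
        num = norm.values[sid] + pseudocount
        den = norm.values[t0] + pseudocount
        if pseudocount == 0 and ((num == 0).any() or (den == 0).any()):
            raise ValidationError(
                "zero abundance with pseudocount 0: log fold change undefined"
            )
        lfc = np.log2(num / den)
        frame = pd.DataFrame(
            {
                "guide_id": norm.guides,
                "condition": row["condition"],
                "bio_rep": row["bio_rep"],
                "tech_rep": row["tech_rep"],
                "lfc": lfc.to_numpy(),
            }
        )
        if retained is not None:
            keep = retained.passes[t0].reindex(norm.guides).fillna(False)
            frame = frame[keep.to_numpy()]
        records.append(frame)
    if not records:
        raise ValidationError("no non-T0 samples found in count table")
    return pd.concat(records, ignore_index=True)


def filter_guides(
    counts: CountTable,
    library: GuideLibrary,
    sheet: SampleSheet,
    min_t0_count: int = 30,
    min_guides_per_gene: int = 3,
    mode: str = "replicate",
) -> FilterResult:
    """Remove shallowly sequenced guides and under-covered genes.

    A guide is removed from a replicate when its RAW read count in that
    replicate's matched T0 sample is strictly below ``min_t0_count``
    (count == threshold is retained).  A gene is removed from scoring
    when fewer than ``min_guides_per_gene`` of its guides survive.
    """
    if mode not in ("replicate", "global"):
        raise ValidationError(f"unknown filter mode {mode!r}")
    t0_samples = [s for s in sheet.t0_samples if s in counts.samples]
    if not t0_samples:
        raise ValidationError("count table contains no T0 sample")

    # only T0 samples actually referenced by a non-T0 sample matter
    referenced = set(
        sheet.frame.loc[sheet.frame["condition"] != "T0", "t0_ref"]
    ) & set(t0_samples)
    if not referenced:
        referenced = set(t0_samples)
    t0_used = [s for s in t0_samples if s in referenced]

    passes = counts.counts[t0_used] >= min_t0_count
    if mode == "replicate":
        guide_ok = passes.any(axis=1)
    else:
        guide_ok = passes.all(axis=1)

    retained_guides = counts.guides[guide_ok]
    gene_of = library.gene_of.reindex(counts.guides)
    guides_per_gene = gene_of[guide_ok.to_numpy()].value_counts()
    retained_genes = pd.Index(
        sorted(guides_per_gene.index[guides_per_gene >= min_guides_per_gene])
    )
    all_genes = gene_of.dropna().unique()
    report = {
        "n_guides_in": len(counts.guides),
        "n_guides_removed": int((~guide_ok).sum()),
        "n_guides_retained": int(guide_ok.sum()),
        "n_genes_in": len(all_genes),
        "n_genes_removed": len(all_genes) - len(retained_genes),
        "n_genes_retained": len(retained_genes),
        "min_t0_count": min_t0_count,
        "min_guides_per_gene": min_guides_per_gene,
        "mode": mode,
    }
    return FilterResult(
        passes=passes,
        retained_guides=retained_guides,
        retained_genes=retained_genes,
        mode=mode,
        report=report,
    )
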