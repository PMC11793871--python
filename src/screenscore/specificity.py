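"""Cross-compound comparison: pan-compound ("non-specific") gene exclusion.

Genes that score in the same direction in every compound screened most
often reflect generic drug/stress response or residual fitness artifacts
rather than interaction with a particular mechanism; they are flagged and
removed from each compound's specific hit list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

MATRIX_COLUMNS = ["gene", "compound", "effect", "p_value", "fdr", "call"]


def classify_specificity(
    per_compound_results: dict[str, pd.DataFrame],
    direction_aware: bool = True,
) -> tuple[set[str], dict[str, pd.DataFrame]]:
    """Split hits into pan-compound (non-specific) and compound-specific.

    A gene is non-specific when it carries the SAME call (SENSITIVITY in
    every compound, or RESISTANCE in every compound).  With
    ``direction_aware=False`` any non-NONE call in every compound
    suffices.  Genes missing from any compound's table (filtered there)
    cannot be non-specific but stay eligible as specific hits where
    scored.

    Returns the non-specific gene set and, per compound, the table of its
    remaining called hits.
    """
    if len(per_compound_results) < 2:
        raise ValidationError("specificity comparison needs >= 2 compounds")
    universes = {c: set(r["gene"]) for c, r in per_compound_results.items()}
    shared = set.intersection(*universes.values())
    if not shared:
        raise ValidationError("compounds have disjoint gene universes")

    calls = {
        c: r.set_index("gene")["call"] for c, r in per_compound_results.items()
    }
    non_specific: set[str] = set()
    for gene in shared:
        gene_calls = [calls[c].get(gene, "NONE") for c in per_compound_results]
        if "NONE" in gene_calls:
            continue
        if direction_aware:
            if len(set(gene_calls)) == 1:
                non_specific.add(gene)
        else:
            non_specific.add(gene)

    specific = {}
    for compound, res in per_compound_results.items():
        hits = res[(res["call"] != "NONE") & ~res["gene"].isin(non_specific)]
        specific[compound] = hits.reset_index(drop=True)
    return non_specific, specific


def rank_genes(results: pd.DataFrame, direction: str) -> pd.DataFrame:
    """1-based ranking of genes by effect in the requested direction.

    RESISTANCE ranks the largest (most positive) effects first,
    SENSITIVITY the most negative.  Ties break by smaller p-value, then
    gene symbol.
    """
    if direction not in ("SENSITIVITY", "RESISTANCE"):
        raise ValidationError(f"unknown direction {direction!r}")
    out = results.copy()
    key = out["effect"] if direction == "SENSITIVITY" else -out["effect"]
    out["_key"] = key
    out = out.sort_values(["_key", "p_value", "gene"], kind="mergesort")
    out = out.drop(columns="_key").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def comparison_matrix(
    per_compound_results: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Long-format gene × compound table for cross-compound plotting.

    One row per gene per compound over the union of genes; genes unscored
    in a compound appear with NA statistics.  Row order is (gene,
    compound) lexicographic for run-to-run stability.
    """
    if len(per_compound_results) < 2:
        raise ValidationError("comparison needs >= 2 compounds")
    universes = [set(r["gene"]) for r in per_compound_results.values()]
    if not set.intersection(*universes):
        raise ValidationError("compounds have disjoint gene universes")
    all_genes = sorted(set.union(*universes))
    indexed = {
        c: r.set_index("gene") for c, r in per_compound_results.items()
    }
    rows = []
    for gene in all_genes:
        for compound in sorted(indexed):
            res = indexed[compound]
            if gene in res.index:
                r = res.loc[gene]
                rows.append(
                    (gene, compound, r["effect"], r["p_value"], r["fdr"], r["call"])
                )
            else:
                rows.append((gene, compound, np.nan, np.nan, np.nan, "NONE"))
    return pd.DataFrame(rows, columns=MATRIX_COLUMNS)
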