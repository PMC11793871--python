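"""Domain types and tab-separated readers/writers for pooled-screen tables.

All on-disk formats are plain TSV with a mandatory header row:

* ``library.tsv``  — columns ``guide_id``, ``gene``
* ``counts.tsv``   — column ``guide_id`` plus one integer column per sample
* ``samples.tsv``  — columns ``sample_id``, ``condition``, ``bio_rep``,
  ``tech_rep`` (optional, defaults to 1), ``t0_ref``
* ``results.tsv``  — columns ``gene``, ``effect``, ``n_obs``, ``t_mod``,
  ``df_total``, ``p_value``, ``fdr``, ``call``

Condition labels are free strings naming the compound, except the reserved
labels ``T0`` (the baseline sample taken before treatment) and ``MOCK``
(the vehicle-only arm), which are matched case-insensitively and stored
upper-case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

RESERVED_CONDITIONS = ("T0", "MOCK")

#: Allowed values of the per-gene hit call.
CALLS = ("SENSITIVITY", "RESISTANCE", "NONE")

RESULT_COLUMNS = [
    "gene",
    "effect",
    "n_obs",
    "t_mod",
    "df_total",
    "p_value",
    "fdr",
    "call",
]


@dataclass(frozen=True)
class GuideLibrary:
    """Guide → gene map of the sgRNA library.

    Each guide targets exactly one gene; a gene is typically covered by
    several guides (four per gene in genome-wide knockout libraries such
    as TKOv3).
    """

    frame: pd.DataFrame  # columns: guide_id, gene

    def __post_init__(self) -> None:
        missing = {"guide_id", "gene"} - set(self.frame.columns)
        if missing:
            raise ParseError(f"guide library missing columns: {sorted(missing)}")
        dup = self.frame["guide_id"][self.frame["guide_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"duplicate guide_id in library: {sorted(dup.unique())[:5]}"
            )

    @property
    def guides(self) -> pd.Index:
        return pd.Index(self.frame["guide_id"])

    @property
    def gene_of(self) -> pd.Series:
        """guide_id-indexed Series of gene symbols."""
        return self.frame.set_index("guide_id")["gene"]

    @property
    def n_genes(self) -> int:
        return self.frame["gene"].nunique()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class CountTable:
    """Raw integer read counts, guides × samples."""

    counts: pd.DataFrame  # index: guide_id, columns: sample_id, int values

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()]
            raise ValidationError(f"duplicated guide rows: {sorted(set(dups))[:5]}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at guide {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def guides(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample condition, replicate labels, and matched-T0 link.

    Every non-T0 sample must name an existing T0 sample in ``t0_ref``; T0
    samples leave it empty.  The same biological replicate may carry
    several technical replicates (independent sequencing of the same cell
    pellet).
    """

    frame: pd.DataFrame  # index: sample_id

    def __post_init__(self) -> None:
        required = {"condition", "bio_rep", "tech_rep", "t0_ref"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ParseError(f"sample sheet missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()]
            raise ValidationError(f"duplicate sample_id: {sorted(set(dups))}")
        triples = self.frame[["condition", "bio_rep", "tech_rep"]]
        dup = triples[triples.duplicated()]
        if len(dup):
            raise ValidationError(
                "duplicate (condition, bio_rep, tech_rep) triples: "
                f"{[tuple(r) for r in dup.itertuples(index=False)][:5]}"
            )
        t0_ids = set(self.t0_samples)
        if not t0_ids:
            raise ValidationError("sample sheet contains no T0 sample")
        for sid, ref in self.frame["t0_ref"].items():
            if self.frame.loc[sid, "condition"] == "T0":
                continue
            if ref not in t0_ids:
                raise ValidationError(
                    f"sample {sid!r} references unknown T0 sample {ref!r}"
                )

    @property
    def samples(self) -> pd.Index:
        return self.frame.index

    @property
    def t0_samples(self) -> list[str]:
        return list(self.frame.index[self.frame["condition"] == "T0"])

    @property
    def conditions(self) -> list[str]:
        """Non-reserved condition labels (the compounds), in sheet order."""
        seen: list[str] = []
        for c in self.frame["condition"]:
            if c not in RESERVED_CONDITIONS and c not in seen:
                seen.append(c)
        return seen

    def samples_for(self, condition: str) -> pd.DataFrame:
        return self.frame[self.frame["condition"] == condition]


@dataclass
class GeneResult:
    """Scored per-gene differential effect between treated and mock arms.

    ``effect`` is the mean Loess-normalized residual (log2 units):
    positive = guide enrichment under drug = resistance, negative =
    depletion = sensitivity.
    """

    gene: str
    effect: float
    n_obs: int
    t_mod: float = float("nan")
    df_total: float = float("nan")
    p_value: float = float("nan")
    fdr: float = float("nan")
    call: str = "NONE"

    def __post_init__(self) -> None:
        if self.call not in CALLS:
            raise ValidationError(f"invalid call {self.call!r}")


def read_guide_library(path) -> GuideLibrary:
    """Read a guide → gene annotation table (TSV: guide_id, gene)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return GuideLibrary(frame=frame)


def read_count_table(path, library: GuideLibrary) -> CountTable:
    """Read a raw count matrix and validate it against the guide library.

    The first column is ``guide_id``; every remaining column is one sample
    of integer read counts.  Unknown guides, duplicated guide rows, and
    negative or non-integer cells are errors.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    guide_col = raw.columns[0]
    guides = raw[guide_col]

    dup = guides[guides.duplicated()]
    if len(dup):
        raise ParseError(f"duplicated guide rows: {sorted(dup.unique())[:5]}")

    unknown = set(guides) - set(library.guides)
    if unknown:
        raise ParseError(
            f"guides absent from library: {sorted(unknown)[:10]}"
            + (" ..." if len(unknown) > 10 else "")
        )

    mat = raw.drop(columns=guide_col)
    for col in mat.columns:
        vals = pd.to_numeric(mat[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals))
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"non-integer count at guide {guides.iloc[row]!r}, sample {col!r}: "
                f"{mat[col].iloc[row]!r}"
            )
        neg = vals < 0
        if neg.any():
            row = int(np.argmax(neg.to_numpy()))
            raise ParseError(
                f"negative count at guide {guides.iloc[row]!r}, sample {col!r}"
            )
    counts = mat.astype(np.int64)
    counts.index = pd.Index(guides, name="guide_id")
    return CountTable(counts=counts)


def write_count_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="guide_id")


def read_sample_sheet(path) -> SampleSheet:
    """Read and validate a sample sheet.

    Columns: sample_id, condition, bio_rep, tech_rep (optional; defaults
    to 1), t0_ref (empty for T0 samples).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "condition", "bio_rep", "t0_ref"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"sample sheet missing columns: {sorted(missing)}")
    if "tech_rep" not in frame.columns:
        frame["tech_rep"] = "1"
    frame.loc[frame["tech_rep"] == "", "tech_rep"] = "1"

    cond = frame["condition"].str.strip()
    upper = cond.str.upper()
    frame["condition"] = cond.where(~upper.isin(RESERVED_CONDITIONS), upper)

    for col in ("bio_rep", "tech_rep"):
        try:
            frame[col] = frame[col].astype(int)
        except ValueError as exc:
            raise ParseError(f"non-integer {col} in sample sheet: {exc}") from None

    return SampleSheet(frame=frame.set_index("sample_id"))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index_label="sample_id")


def write_gene_results(results: list[GeneResult] | pd.DataFrame, path) -> None:
    """Write scored gene results as TSV, 6 significant digits on floats."""
    if isinstance(results, pd.DataFrame):
        frame = results.copy()
    else:
        if not results:
            raise ValidationError("no gene results to write")
        frame = pd.DataFrame([vars(r) for r in results])
    if frame.empty:
        raise ValidationError("no gene results to write")
    frame = frame[RESULT_COLUMNS]
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_gene_results(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"results table missing columns: {sorted(missing)}")
    return frame
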