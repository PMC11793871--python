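"""Generative model of a drug-vs-mock pooled CRISPR knockout screen.

The simulator emulates the design of a genome-wide chemogenetic screen:
a guide library (several guides per gene) is introduced into a cell pool,
the pool is split into biological replicates at day 0, and each replicate
grows for ~12 population doublings (an 18-day course with passaging every
3 days) either mock-treated or under drug, at deep per-guide coverage.

Growth is multiplicative in log2 space.  A guide targeting gene g in
replicate r changes abundance by

    MOCK:  G·s_g·a_i + ε          (G generations, per-generation fitness s_g)
    DRUG:  G·s_g·a_i + δ_g·a_i + ε

where δ_g is the TOTAL log2 drug-interaction effect over the screen
(directly comparable to the pipeline's effect estimate and the ±0.5 hit
threshold), a_i ∈ {0, 1} flags whether guide i actually cuts (a Bernoulli
mixture — the dominant real-data deviation the moderated test must
tolerate), and ε is small per-(guide, replicate) biological jitter shared
by the two arms of a replicate (it cancels in the treated-mock contrast).
Sequencing is negative binomial around the scaled population proportions
with variance μ + φμ².  All randomness flows from one master seed via
per-replicate child streams, so adding replicates never perturbs the
counts of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CountTable, GuideLibrary, SampleSheet


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated screen.

    Defaults mirror a genome-scale chemogenetic screen: 4 guides per
    gene, ~80% of guides active, 12 population doublings over the
    course, ≥200-fold sequencing coverage (300 mean reads per guide),
    three biological replicates, and tight amplicon-sequencing noise
    (NB dispersion 0.01).
    """

    n_genes: int = 1000
    guides_per_gene: int = 4
    frac_fitness: float = 0.15
    fitness_scale: float = 0.1  # mean log2 cost per generation among hit genes
    frac_interact: float = 0.0
    interaction_effect: float = 2.0  # total log2 effect; sign = direction
    frac_interact_shared: float = 0.0  # genes interacting in ALL compounds
    guide_active_prob: float = 0.8
    generations: float = 12.0
    depth_per_guide: float = 300.0
    nb_dispersion: float = 0.01
    bio_reps: int = 3
    tech_reps: int = 1
    compounds: tuple[str, ...] = ("DRUG",)
    bio_jitter_sd: float = 0.05  # log2 per (guide, replicate)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_fitness", "frac_interact", "frac_interact_shared",
                     "guide_active_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "guides_per_gene", "bio_reps", "tech_reps"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("generations", "depth_per_guide"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be >= 0")
        if not self.compounds:
            raise ValidationError("at least one compound required")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth coefficients behind a simulated screen.

    ``genes`` carries per-gene fitness (log2/generation) and one
    ``delta_<compound>`` column per compound (total log2 interaction
    effect; 0 for non-interacting genes).  ``guides`` carries the
    per-guide active flag.
    """

    genes: pd.DataFrame  # gene, fitness, delta_<compound>...
    guides: pd.DataFrame  # guide_id, gene, active

    def delta(self, compound: str) -> pd.Series:
        return self.genes.set_index("gene")[f"delta_{compound}"]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """Negative binomial with variance mean + dispersion·mean²; Poisson at 0."""
    mean = np.maximum(mean, 1e-12)
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return rng.poisson(lam)


def _draw_truth(cfg: SimConfig, rng: np.random.Generator
                ) -> tuple[SimTruth, np.ndarray]:
    genes = [f"GENE{i:05d}" for i in range(cfg.n_genes)]
    guide_ids = [
        f"sg{g}_{j + 1}" for g in genes for j in range(cfg.guides_per_gene)
    ]
    gene_of_guide = np.repeat(genes, cfg.guides_per_gene)

    # per-gene fitness: a frac_fitness subset pays an exponential log2
    # cost per generation with the configured mean
    fitness = np.zeros(cfg.n_genes)
    is_fit = rng.random(cfg.n_genes) < cfg.frac_fitness
    fitness[is_fit] = -rng.exponential(cfg.fitness_scale, is_fit.sum())

    gene_frame = pd.DataFrame({"gene": genes, "fitness": fitness})
    shared = rng.random(cfg.n_genes) < cfg.frac_interact_shared
    shared_sign = np.where(rng.random(cfg.n_genes) < 0.5, 1.0, -1.0)
    for compound in cfg.compounds:
        delta = np.zeros(cfg.n_genes)
        own = rng.random(cfg.n_genes) < cfg.frac_interact
        delta[own] = cfg.interaction_effect
        delta[shared] = np.abs(cfg.interaction_effect) * shared_sign[shared]
        gene_frame[f"delta_{compound}"] = delta

    active = rng.random(len(guide_ids)) < cfg.guide_active_prob
    guide_frame = pd.DataFrame(
        {"guide_id": guide_ids, "gene": gene_of_guide, "active": active}
    )
    truth = SimTruth(genes=gene_frame, guides=guide_frame)

    # initial pool composition: log-normally skewed guide abundances
    p0 = rng.lognormal(mean=0.0, sigma=1.0, size=len(guide_ids))
    return truth, p0 / p0.sum()


def simulate_screen(
    config: SimConfig,
) -> tuple[CountTable, GuideLibrary, SampleSheet, SimTruth]:
    """Simulate a full screen: counts, library, sample sheet, ground truth.

    Samples are named ``T0_r<b>``, ``MOCK_r<b>``, ``<COMPOUND>_r<b>``
    (with a ``_t<t>`` suffix when there are technical replicates); every
    arm of replicate b is anchored to ``T0_r<b>``.  Deterministic for a
    fixed config (including seed).
    """
    cfg = config
    root, *rep_seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.bio_reps + 1)
    rng = np.random.default_rng(root)
    truth, p0 = _draw_truth(cfg, rng)

    n_guides = len(truth.guides)
    total_depth = cfg.depth_per_guide * n_guides
    active = truth.guides["active"].to_numpy(dtype=float)
    fitness = np.repeat(truth.genes["fitness"].to_numpy(), cfg.guides_per_gene)
    deltas = {
        c: np.repeat(
            truth.genes[f"delta_{c}"].to_numpy(), cfg.guides_per_gene
        )
        for c in cfg.compounds
    }

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []

    def tech_names(cond: str, b: int) -> list[tuple[str, int]]:
        if cfg.tech_reps == 1:
            return [(f"{cond}_r{b}", 1)]
        return [(f"{cond}_r{b}_t{t}", t) for t in range(1, cfg.tech_reps + 1)]

    for b in range(1, cfg.bio_reps + 1):
        rep_rng = np.random.default_rng(rep_seeds[b - 1])
        t0_name = f"T0_r{b}"
        columns[t0_name] = _nb_draw(rep_rng, p0 * total_depth, cfg.nb_dispersion)
        sheet_rows.append((t0_name, "T0", b, 1, ""))

        # replicate-level realization of each guide's activity: shared by
        # the mock and drug arms (both descend from the same day-0 split),
        # so it cancels in the treated-minus-mock contrast
        jitter = rep_rng.normal(0.0, cfg.bio_jitter_sd, n_guides)
        base = cfg.generations * fitness * active + jitter
        for cond in ("MOCK", *cfg.compounds):
            log2_growth = base
            if cond != "MOCK":
                log2_growth = log2_growth + deltas[cond] * active
            prop = p0 * np.exp2(log2_growth)
            prop = prop / prop.sum()
            for name, t in tech_names(cond, b):
                columns[name] = _nb_draw(
                    rep_rng, prop * total_depth, cfg.nb_dispersion
                )
                sheet_rows.append((name, cond, b, t, t0_name))

    counts = pd.DataFrame(
        columns, index=pd.Index(truth.guides["guide_id"], name="guide_id")
    )
    library = GuideLibrary(frame=truth.guides[["guide_id", "gene"]].copy())
    sheet = SampleSheet(
        frame=pd.DataFrame(
            sheet_rows,
            columns=["sample_id", "condition", "bio_rep", "tech_rep", "t0_ref"],
        ).set_index("sample_id")
    )
    return CountTable(counts=counts), library, sheet, truth


def null_screen(config: SimConfig) -> tuple[CountTable, GuideLibrary,
                                            SampleSheet, SimTruth]:
    """Simulate a screen with every drug-interaction coefficient forced to 0."""
    cfg = replace(config, frac_interact=0.0, frac_interact_shared=0.0)
    return simulate_screen(cfg)


def write_truth(truth: SimTruth, genes_path, guides_path) -> None:
    truth.genes.to_csv(genes_path, sep="\t", index=False, float_format="%.6g")
    truth.guides.to_csv(guides_path, sep="\t", index=False)
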