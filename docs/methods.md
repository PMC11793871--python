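# Methods

## The scoring model

`screenscore` scores drug-vs-mock pooled CRISPR knockout screens: a
guide library (typically 4 sgRNAs per gene) is introduced into a cell
pool, a baseline (T0) sample is sequenced, and the pool is grown under
either vehicle (MOCK) or a compound for the length of the screen.  Genes
whose knockout changes drug response show up as guides that enrich
(resistance) or deplete (sensitivity) under drug relative to mock.

The chain, per compound contrast:

1. **Guide filter.**  A guide's fold change is meaningless if it was
   barely sequenced at baseline, so guides with a raw T0 read count
   below `min_t0_count` (default 30; the bound is strict, a count of
   exactly 30 passes) are removed.  Filtering is replicate-wise by
   default: each biological replicate has its own T0, and a guide keeps
   contributing observations from replicates whose T0 it passed
   (`filter_mode="global"` enforces the stricter all-replicates rule).
   Genes with fewer than `min_guides_per_gene` (default 3) surviving
   guides are removed from scoring.
2. **Depth normalization.**  Counts are scaled to reads per million
   within each sample.
3. **Log2 fold change.**  For every non-T0 sample,
   `lfc = log2((rpm + c) / (rpm_T0 + c))` against its matched T0, with
   pseudocount `c = 0.5` on the RPM scale keeping zero-count guides
   finite.  Technical replicates are averaged at this stage.
4. **M-A residuals.**  Per (guide, biological replicate), the treated
   and mock LFCs are reparameterized as `M = treated − mock` and
   `A = (treated + mock)/2`.  Positive M = enrichment under drug =
   resistance.  A robust local-linear Loess of M on A (span 0.3,
   tricube weights, 3 bisquare iterations), fitted separately within
   each replicate, removes any smooth abundance-dependent skew; the
   residuals are the normalized per-guide effects.
5. **Moderated t.**  Each gene's residuals (one observation per retained
   guide per replicate) give a mean `beta`, sample variance `s²`, and
   `df = n − 1`.  Variances are shrunk toward an empirical-Bayes prior
   (below), and `t = beta / sqrt(s̃²/n)` is referred to Student's t with
   `d0 + df` degrees of freedom, two-sided.
6. **FDR and calls.**  Benjamini–Hochberg step-up within the contrast.
   Hits require `fdr < 0.4` and `|effect| > 0.5` (both strict), with
   the sign of the effect deciding RESISTANCE vs SENSITIVITY.

## Empirical-Bayes variance moderation

Sample variances are modeled as `s² | σ² ~ σ² χ²_d / d` with
`σ² ~ s0² d0 / χ²_{d0}` (scaled inverse chi-square).  The prior
`(d0, s0²)` is fitted by the method of moments on log variances: with
`z = log s²` and `e = z − ψ(d/2) + log(d/2)`, the excess of the spread
of `e` over its chi-square sampling contribution,

    mean[(e − ē)² · n/(n−1) − ψ'(d/2)] = ψ'(d0/2),

identifies `d0` through the trigamma inverse (Newton iteration), and
`s0² = exp(ē + ψ(d0/2) − log(d0/2))`.  A non-positive excess means the
variances are no more dispersed than sampling alone: `d0 = ∞` and every
gene uses the pooled `s0² = exp(ē)`.  The finite-sample `n/(n−1)` factor
is included; the fit is checked in the test suite against an independent
bisection solve of the same moment equations.  Infinite `d0` is carried
explicitly, with total degrees of freedom capped at 1e6 for the t
distribution.  `d0 = 0` is admitted as the no-moderation limit and
reduces to the ordinary one-sample t.  Genes with `s² = 0` still receive
finite statistics through the prior — a primary benefit of moderation —
and no variance floor is applied beyond it.  Fewer than 100 genes with
positive variance triggers a warning and the pooled fallback.

## The signal guard on the Loess trend

A local smoother follows whatever dominates a neighborhood.  When many
genes respond to the compound in the same direction, their guides pile
up at one extreme of A (an enriched guide's A rises by half its M), and
in that region they can be the *majority* of points — a plain Loess of
any span then absorbs most of their signal into the "trend" and erases
it.  In simulations with 5% of genes at +2 log2, a plain span-0.3 fit
recovered only ~30% of the true effect, and neither larger spans (≤0.7)
nor more bisquare iterations helped, because the contamination is local,
one-sided, and locally dominant.

The fit is therefore guarded: a global robust linear pre-fit (Tukey
bisquare), which a concentrated minority cannot hijack, flags points
farther than `guard_mads` (default 3) MADs from it; flagged points are
excluded from the Loess fit and receive the trend interpolated from
their neighbors (constant beyond the fitted range).  With the guard, the
same simulation recovers the truth with unit slope while null
calibration and curved-trend removal are unchanged (quadratic-trend MAE
0.012 with noise SD 0.1).  The guard deliberately does nothing when the
data are near-perfectly linear, and it is skipped for strata under 50
points.  `guard_mads=None` restores the plain Loess.  Known limitation:
if strong trend curvature and concentrated signal coincide, the linear
pre-fit's MAD inflates, few points are flagged, and absorption can
return.

## The simulator

`simulate_screen` emulates the screen design the scorer targets: initial
guide abundances are log-normal(0, 1) (a skewed library), a fraction of
genes (`frac_fitness`, default 0.15) pays an exponential intrinsic
fitness cost (mean `fitness_scale` = 0.1 log2 per generation), a
fraction (`frac_interact`) carries a drug interaction `δ` expressed as a
TOTAL log2 effect over the screen so that simulated truth sits on the
same scale as the pipeline's effect estimate and the ±0.5 hit threshold.
Each guide is active with probability `guide_active_prob` (default 0.8,
a Bernoulli mixture — the dominant real-data deviation the moderated
test must tolerate); inactive guides carry no effect.  Growth runs
`generations` = 12 population doublings (an 18-day course, passaging
every 3 days); sequencing draws are negative binomial with variance
`μ + φμ²` (φ = 0.01, tight amplicon noise) at `depth_per_guide` = 300
mean reads (>200-fold coverage).  Three biological replicates split at
day 0; each redraws a small per-guide activity jitter (Normal(0, 0.05)
log2) that both arms of the replicate share — it therefore cancels in
the treated-minus-mock contrast, and in the no-noise limit a null
screen collapses to pure counting noise.  Technical replicates are
independent NB draws from the same proportions.  One master seed spawns
per-replicate child streams, so adding replicates never changes the
counts of existing ones.

What the simulator does *not* model: multiple lentiviral integrations
(MOI effects), clonal drift through passaging bottlenecks, guide
efficiency as a continuous quantity, copy-number artifacts, or
drug-concentration drift across passages.  Passing tests show the
scoring chain is calibrated and consistent under the generative model
above; they do not certify behavior under real-data pathologies outside
it (e.g. copy-number-driven false positives).

## Problem sizes and numerical choices

The test suite and the acceptance script run screens of 300–2000 genes
at 4 guides per gene — large enough for the Loess (≥50 points per
stratum enforced) and the prior fit (≥100 genes enforced) to be in their
asymptotic regime, and small enough that a full null-calibration study
(10 screens of 2000 genes) completes in seconds.  Loess uses
interpolation between fit points (delta = 1% of the A range) above 500
points, the standard speedup.  BH adjustment delegates to
`statsmodels.stats.multitest`; the local regression delegates to
`statsmodels`' lowess.  Ranking ties break by smaller p-value, then gene
symbol, making all outputs byte-reproducible; nothing in the scoring
chain is stochastic.

## Cross-compound specificity

With several compounds screened, a gene called in the SAME direction in
every compound is flagged non-specific (a generic stress/fitness
response) and excluded from each compound's specific hit list.  The rule
is direction-aware by default (`direction_aware=False` relaxes it to any
non-NONE call everywhere); genes unscored in any compound cannot be
flagged but remain eligible as specific hits where scored.
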