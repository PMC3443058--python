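# Methods

All expression values are log2 intensities.  Matrices are genes x samples
(`pandas.DataFrame`, gene IDs as index, sample IDs as columns).

## Annotation bridging

Probes are mapped to genes by majority consensus across identifier
sources: a probe keeps a gene if a strict majority of its sources agree;
probes with no majority are dropped.  The consensus is order-independent.
Multi-probe genes are collapsed by the mean of their probes' rows, which
preserves column sums per gene group.  `align_gene_space` intersects two
matrices' gene indices and returns both restricted to the shared, sorted
gene list.

## Preprocessing

**Quantile normalization** forces every sample to the same empirical
distribution: values are ranked per sample, each rank is replaced by the
mean across samples of the values at that rank, and ties within a sample
receive the mean of the reference values spanning the tied block, keeping
the transform rank-preserving and idempotent.

**Detection filtering** keeps a gene only if its detection p-value is
below `alpha` in at least `margin + 1` samples on the platform — genes
near the noise floor on either platform contribute only noise to
cross-platform comparisons.

### Per-platform versus pooled quantile normalization

Two uses are distinct and both are provided:

- As *input to correction methods*, each platform is quantile-normalized
  separately.  This removes within-platform technical spread without
  letting either platform's distribution contaminate the other before
  the correction step.
- As a *comparison state* in the variance decomposition, the pooled
  matrix is quantile-normalized across platforms.  Per-platform
  normalization cannot reduce the inter-platform variance fraction — it
  removes lab and replicate noise, which mechanically *inflates* the
  platform share — so the meaningful "does distribution matching alone
  help?" state is the pooled one.

## Cross-platform correction

### Mean-centering

Subtract each gene's within-platform mean.  Per-gene per-platform means
become exactly zero; gene-wise additive offsets are removed completely,
multiplicative (slope) bias is not.

### ComBat

Parametric empirical-Bayes batch adjustment.  Genes are standardized
against a pooled model, per-batch location (`gamma`) and scale (`delta`)
parameters are estimated per gene and shrunk toward batch-level priors
(normal for location, inverse-gamma for scale) by iterating the EB
updates to convergence, and the data are adjusted and rescaled.  The
implementation is validated against `sva::ComBat` to ~1e-4.

### DWD translation

The distance-weighted discrimination direction `w` separates the two
batches by minimizing `sum_i 1/r_i + C sum_i xi_i` over unit-norm `w`,
with residuals `r_i = y_i (w.x_i + beta) + xi_i`.  Slack variables are
eliminated analytically, leaving a smooth convex objective optimized by
SLSQP inside the span of the samples (after an SVD reduction).  Each
batch is then translated along `w` so both batch means project onto the
grand-mean projection.

**Why DWD cannot help in a balanced design:** the adjustment is a single
per-batch constant vector.  Adding a constant to every sample of a batch
changes neither the between-sample-type, between-lab, nor residual
sums of squares within that batch; it only moves the batch (platform)
mean.  So the inter-sample variance fraction after DWD is essentially
the bias-free fraction, and any check demanding a large *drop* in that
fraction from a per-batch translation is structurally unsatisfiable.
The corresponding test asserts the documented >20% drop and
fails with the measured value (a few percent), which is the honest
outcome.

### XPN (cross-platform normalization)

Both platforms share a block structure: gene clusters `alpha(g)` (K-means
on the pooled gene profiles, K = 25) and per-platform sample clusters
`beta(i)` (K-means on the gene-standardized per-platform view, L = 5).
Within platform `p` the model is

```
x_gi = A_{alpha(g), beta(i)}^p * b_g^p + c_g^p + sigma_g^p * eps_gi
```

fitted by alternating least squares: given `(b, c)`, each block entry of
`A` is the weighted block average; given `A`, each gene's `(b, c)` is a
regression of its row on its block profile.  The per-gene regression is
ridge-penalized toward `b = 1` with unit-information strength
`lambda = sigma_g^2 / n` (with `sigma_g^2` re-estimated each iteration).
This serves two purposes: it pins the scale gauge of the `(A, b)`
factorization — otherwise `(A/t, t*b)` is an equivalent fit and
cross-platform averaging of `A` becomes meaningless — and it bounds `b`
for flat-profile (noise) gene clusters where the unpenalized regression
is ill-conditioned.  Consensus parameters are sample-size-weighted
averages of the two platforms' `A`, `b`, `c`, `sigma`; each sample is
reconstructed from the consensus using its own standardized residuals,
so sample-specific signal survives.  The procedure is repeated over
`reps = 30` random clustering restarts and averaged, making the output
deterministic given the seed.

## Nested variance decomposition

Per gene, the random-effects model

```
y = mu + a_sampletype + b_platform(sampletype) + c_lab(platform) + e
```

is fitted on the balanced design by REML or by ANOVA (method-of-moments
on expected mean squares, truncated at zero).  For balanced data the
REML solution equals an isotonic regression: the df-weighted pool
adjacent violators algorithm (PAVA) applied to the stratum mean squares,
which matches `nlme::lme` to optimizer tolerance (~1e-4 relative) and
equals the ANOVA estimate whenever the latter is interior (all
components positive).  Unbalanced designs fall back to a generic
V-matrix REML (profiled likelihood, trust-region optimizer), also
validated against `nlme`.  Per-gene components are pooled across genes
by summing each level's estimates before forming fractions of total
variance.

## SAM differential expression

The statistic is `d_g = r_g / (s_g + s0)`: class-mean difference (or
mean paired difference) over the pooled standard error plus a fudge
factor.  `s0 = "auto"` picks the percentile of `s` that minimizes the
coefficient of variation of bin-wise median absolute `d` across the
`s`-spectrum (Tusher-style), decoupling `|d|` from the scatter level.
FDR is estimated by permutation: class labels are permuted (balanced
assignments; sign flips of pair differences in the paired case), and for
each threshold `delta` — applied asymmetrically to the sorted observed
`d` against its permutation-expected order statistics — the median
number of permutation scores exceeding the cuts estimates the false
calls (`pi0 = 1`, conservative).  When the permutation space is no
larger than the requested number of permutations (e.g. C(6,3) = 20
balanced relabelings, `2^n_pairs` sign patterns), it is enumerated
exhaustively and the result is seed-independent.

Calibration was checked empirically (see `tests/test_acceptance.py` and
`scripts/acceptance.py`): over replicated simulations with planted
effects, the mean estimated FDR at the selected threshold matches the
mean realized false-discovery proportion within Monte-Carlo error.

## Synthetic generators

**Reference-sample design** (`simulate_maqc`): four sample types x two
platforms x three labs x five replicates, Gaussian random effects with
variances (4, 1, 0.25, 0.04) on the log2 scale.  With `titration=True`
(default) sample types C and D are not independent draws: their per-gene
effects are *linear-scale* mixtures of A and B (75/25 and 25/75),
`c = log2(0.75 * 2^a + 0.25 * 2^b)` — mixing RNA mixes intensities, not
log intensities.  Titration induces correlation among sample-type
effects, so for variance-recovery checks `titration=False` gives i.i.d.
effects whose realized variances are reported in the truth dict.
Optional platform bias adds gene-wise offsets `~ N(0, offset_sd^2)` and
sensitivity slopes `~ LogNormal(0, slope_sigma^2)` to the second
platform, mimicking probe-chemistry differences.

**Clinical design** (`simulate_clinical`): each platform profiles its own
patients (optionally a shared subset) at baseline and three months; a
fraction of genes carries a treatment effect with log-normal magnitude
and random sign applied at follow-up only; patient-level random effects
create the pairing structure; platform 2 measures
`slope_g * signal + offset_g` plus noise; a fraction of genes is silent
(high detection p-values) to exercise the detection filter.  Truth
records affected genes, effects, bias fields and silent genes.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` seeded
  explicitly; derived seeds come from `numpy.random.SeedSequence` and
  stay below 2^31.
- Balanced REML uses the closed-form PAVA path rather than iterative
  likelihood maximization: exact, fast, and immune to convergence
  failures at zero boundaries.
- The DWD inner problem is solved in the sample span (rank <= n), so
  cost does not scale with the number of genes.
- XPN averages over clustering restarts instead of picking a "best"
  clustering, removing the discontinuous dependence on K-means
  initialization.
- Zero-variance genes are rejected or warned about explicitly rather
  than silently producing NaNs.

## Limitations

- ComBat and mean-centering assume the biological composition of the
  batches is comparable; with confounded designs they remove biology
  along with bias (demonstrated in the test suite for DWD).
- The nested model assumes Gaussian effects and a strictly nested
  design; crossed lab/platform structures are not supported.
- SAM's `pi0 = 1` makes the FDR estimate conservative when many genes
  are truly affected.
- XPN's block model with fixed K and L can under-fit expression
  structure that is not block-like; K and L are exposed as parameters
  but no automatic selection is attempted.
- The generators are stylized: real platform bias includes
  intensity-dependent (non-linear) distortion that the gene-wise
  offset + slope model only approximates.
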