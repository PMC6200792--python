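# Methods

## The estimation problem

A literature compilation of modern (~200-year) organic-carbon
accumulation rates contains one row per measured ecosystem: a mean rate
*yᵢ* in g C m⁻² y⁻¹, sometimes a standard deviation *sᵢ*, and labels
(ecosystem category, salinity class, inundation class). The goal is the
mean accumulation rate of each group of ecosystems, with uncertainty
that honestly reflects both between-study spread and each study's own
imprecision. Rates within a group span one to three orders of
magnitude, so a pooled sample mean is fragile: one imprecise high value
can move it substantially.

## Hierarchical measurement-error model

Per group *g*, fit independently:

- *yᵢ* | *θᵢ* ~ Normal(*θᵢ*, *sᵢ*²) — the observed rate scatters around
  the study's true rate with known measurement SD;
- *θᵢ* | μ_g, τ_g ~ Normal(μ_g, τ_g²) — true study rates scatter around
  the group mean with between-study SD τ_g;
- μ_g ~ Uniform(0.1, 10000) g C m⁻² y⁻¹ — the lower bound is the
  practical detection floor of sediment-dating rate methods, the upper
  bound an order of magnitude above anything reported;
- τ_g ~ Gamma(shape = 0.001, rate = 0.001), placed on the SD itself.

Integrating out the latent layer gives the equivalent marginal
likelihood *yᵢ* ~ Normal(μ_g, τ_g² + *sᵢ*²): each observation is
weighted by *wᵢ* = 1/(τ_g² + *sᵢ*²), which is what down-weights
imprecise values. The `excluding_uncertainty` variant drops the
measurement-error layer (*yᵢ* ~ Normal(μ_g, τ_g²), *sᵢ* ignored) and
serves as a sensitivity check: on data where uncertainty grows with the
rate, it produces systematically higher group means.

θ is not truncated at zero by default; a `truncate_theta` flag exists
for the interpretation in which latent rates are constrained positive,
at the cost of a slower, less well-mixing sampler (below).

### A note on the τ prior

Gamma(0.001, 0.001) on a standard deviation is extremely spiked at
zero (most of its mass lies below numerically tiny values). When a
group's data cannot rule out τ ≈ 0 — few observations with large
measurement SDs — the posterior for τ keeps a long plateau of
essentially-zero values, and posterior intervals for μ_g can be
slightly narrower than nominal. This is a property of the prior choice,
kept deliberately; both shape and rate are exposed in `ModelConfig`.

## Sampler

Metropolis-within-Gibbs on (μ_g, τ_g), with the latent layer collapsed:

- τ_g: random-walk Metropolis on log τ against the marginal target
  p(τ | μ, y) ∝ Gamma-prior × ∏ Normal(yᵢ; μ, τ² + sᵢ²), with the
  Jacobian of the log transform. The step size adapts toward a
  0.3–0.5 acceptance rate during burn-in only and is frozen afterwards.
- μ_g: exact conjugate draw from its marginal conditional — a normal
  with mean Σ*wᵢyᵢ*/Σ*wᵢ* and variance 1/Σ*wᵢ*, truncated to the
  uniform prior's support via inverse-CDF sampling.

Collapsing matters. The textbook alternative — Gibbs on the full
latent state (θ | rest, μ | θ, τ | θ) — is the natural transcription of
the model, but in small groups it falls into the well-known funnel:
τ shrinking pulls the θᵢ onto μ, which shrinks the residuals, which
pulls τ down further; chains stick for thousands of iterations
(observed: R̂ ≈ 12 on an 8-observation group at test-sized chains).
The collapsed kernel targets the identical posterior — the latent-θ and
marginal formulations are the same model — and mixes essentially like
an independence sampler (effective sample sizes near nominal). The
un-collapsed latent kernel is retained for `truncate_theta=True`, whose
marginal has no closed form. An entirely separate random-walk MH
sampler on (μ, log τ) under the marginal likelihood
(`sample_marginal_posterior`) acts as an internal cross-check in the
test suite.

Numerical details:

- log τ is the state variable. Because the prior concentrates mass at
  τ ≈ 0, chains legitimately visit log τ values whose exponential
  underflows to 0.0; carrying the log avoids feeding log(0) back into
  the kernel. Proposals with log τ > 700 get −∞ target (exp would
  overflow; the prior's −rate·τ term vanishes them anyway).
- Truncated-normal draws use Φ/Φ⁻¹ inversion with a boundary fallback
  when the conditional mass lies numerically outside the support.
- Chains start overdispersed: chain *c* starts μ at the 25/50/75th
  percentile of the group's rates and τ at 0.5/1/2 × their sample SD
  (floored at 10⁻³), cycling for more than three chains. Per-chain RNG
  streams derive from (seed, CRC32(group label), chain index), so
  results are independent of group iteration order and bit-reproducible
  from the seed.
- Defaults are 3 chains × 300 000 iterations with 100 000 burn-in and
  no thinning; the test suite and acceptance script run the same model
  at 2–3 chains × 3 000–20 000 iterations, which the collapsed
  sampler's mixing makes sufficient (R̂ < 1.01 throughout).
- Convergence: R̂ = sqrt(((n−1)/n·W + B/n)/W) on both μ and τ chains,
  threshold 1.1 (pipeline warning, escalatable to an error). Effective
  sample size uses Geyer's initial-monotone-positive-sequence
  truncation of the combined autocorrelation.
- Quantiles (2.5/50/97.5%) use linear interpolation of order statistics
  (numpy's default rule) on the pooled post-burn-in draws.
- Degenerate runs (every post-burn-in τ proposal rejected) raise a
  diagnostic error rather than returning silent output.

## SD imputation

Within each ecosystem category, the per-measurement coefficient of
variation CVᵢ = sᵢ/yᵢ is averaged over the rows that report an SD (a
mean of per-study CVs, not the SD-of-group over mean-of-group); rows
without an SD receive sᵢ = CV̄_g × yᵢ and are flagged `imputed`. A group
with no reported SDs falls back to the dataset-wide mean CV and is
flagged. Imputation is idempotent, never touches reported rows, and a
configurable floor (10⁻⁶ × yᵢ) guards against a pathological CV̄ = 0 so
downstream likelihoods stay proper. Whether the CV should be computed
within the 7 grouped categories or within finer raw ecosystem types is
ambiguous in principle; the grouped categories are used.

## Grouping and I/O

Raw literature ecosystem names map onto seven categories (lake,
reservoir, inland wetland, coastal wetland, lagoon, mangrove,
continental shelf) through a user-supplied YAML mapping, because the
folding of sparse types (fjords, inland seas) into larger categories is
a judgment call that should travel with the dataset, not the code;
`examples/grouping.yaml` ships a documented guess. Rows failing
validation (non-positive rate, unmapped name, out-of-range coordinates)
are rejected individually with row-level diagnostics, never silently
dropped — the load report carries total/accepted/rejected/SD-reported
counts. Rates ≤ 0 are rejected rather than clamped, consistent with the
0.1 prior floor. Rows missing a salinity or inundation label are
excluded only from that grouping, not from the dataset. CSV conventions:
UTF-8, header row, `""`/`"NA"` for missing; summary CSVs write explicit
`NA` markers for diagnostics that do not exist (e.g. R̂ of a fixed τ).

## Post-analysis

**Range overlap.** Pairwise overlap of the per-group [min, max] rate
intervals, under one of three metrics the caller must name (Jaccard
|∩|/|∪|; fraction of the smaller range |∩|/min(|A|,|B|); mean directed
(|∩|/|A| + |∩|/|B|)/2). No default is assumed in reports because a
single "average overlap" number is meaningless without its formula;
the metric travels in the output. Degenerate point-intervals score 1 if
the point lies inside the other interval, else 0, and are flagged.

**Fold-changes.** `median_ratio` (default) divides posterior medians,
matching how headline "×-fold" statements are usually computed;
`sample_ratio` forms the full distribution of paired posterior-draw
ratios and reports its median and 95% interval (unequal draw counts
are down-sampled with a recorded seed).

**Upscaling.** F = rate quantile × A_g × 10⁻¹² gives Tg C y⁻¹; the
2.5/50/97.5% flux quantiles are also expressed as percent of the median
flux. Global extents A_g are user-supplied config values with citation
fields (`examples/areas.yaml`); the package never bundles them as
facts. Rounding (half-even, integer percent) happens only at display;
machine outputs keep full precision.

## Synthetic data generator

Emulates the structure of a literature compilation: per group, latent
true rates θᵢ ~ Normal(μ_g, τ_g²) truncated by redraw; per-row CVs
drawn log-normally so that ±2 SD of log CV spans the configured range
(default 0.1–0.6); sᵢ = CVᵢ·θᵢ; observed yᵢ ~ Normal(θᵢ, sᵢ²) truncated
above the 0.1 detection floor; SDs masked to missing with probability
0.58. The default 7-category configuration has group sizes
(202, 13, 17, 53, 8, 45, 126) — 464 rows across 103 study ids, lakes
dominant — with true means and spreads echoing the magnitudes typical
of published syntheses (synthetic defaults, not measured facts).

Design notes and intentional mismatches with the fitting model:

- **Truncation by redraw, not clamping**, so positive support carries
  no point mass. θ is truncated at the detection floor rather than at
  zero: a true rate below the floor would never be reported, and latent
  rates between 0 and the floor with rate-proportional SDs make the
  observation-level truncation reject essentially every draw.
  A `truncate=False` flag gives the exact untruncated model (which can
  emit schema-invalid negative rates; intended for raw-array use).
- **Informative measurement SDs.** With sᵢ ∝ θᵢ (the default,
  `sd_model="cv_of_latent"`), the SDs carry information about the
  latent rates that the fitting model — which conditions on sᵢ as known
  exogenous constants — deliberately ignores. The consequence is real
  and worth understanding: the precision-weighted posterior for μ_g
  sits systematically below the generator's μ_g (≈ 12% at μ = 50,
  τ = 15, CVs 0.1–0.6, confirmed against a direct marginal-MLE
  computation at n = 20 000). This is the same mechanism by which the
  model down-weights "high estimates that are highly uncertain", and it
  is exactly why the excluding-uncertainty variant produces higher
  means. Parameter-recovery experiments on this generator therefore
  measure the estimand gap, not sampler error; recovery of the
  generating mean itself holds only under `sd_model="exogenous"`
  (sᵢ = CVᵢ·μ_g, independent of θᵢ), which the calibration tests use.
  Passing tests on synthetic data accordingly show internal
  consistency of the machinery, not that real-literature group means
  are unbiased for any "true" global mean.
- The generator produces plausible random coordinates and fixed
  per-group salinity/inundation labels; it does not emulate geographic
  clustering, dating-method differences, or within-study correlation
  of multiple cores.

## Pipeline and reproducibility

`run_pipeline` executes ingest/simulate → impute → fit (per requested
grouping: ecosystem category, salinity, inundation) → overlap/ratio/
upscale from one YAML config and writes a JSON run manifest: config
snapshot, SHA-256 of the dataset, seeds, per-stage wall time, per-group
R̂, and every output path. Re-running the same config reproduces every
output byte-identically. Groups are statistically independent and their
per-group RNG streams are label-derived, so results are invariant to
execution order. Convergence failures become manifest warnings;
`--strict` escalates them to exit code 3.

## Known limitations

- The Gamma(0.001, 0.001)-on-SD prior's spike at zero mildly shrinks
  τ and can under-cover in small groups; users wanting calibrated
  small-group intervals should widen the prior (e.g. shape = rate = 1).
- Independent per-group fits ignore any shared structure across groups
  (no partial pooling of τ_g, no covariates, no spatial model).
- The average range overlap depends strongly on the chosen metric and
  on whether ranges are taken on raw or log scale; it is reported as a
  descriptive statistic only.
- Imputed SDs inherit the mean CV of the reporting subset of a group,
  which assumes reporting is non-informative within group.
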