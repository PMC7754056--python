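# Methods

## Model and assumptions

The pipeline rests on one biological premise and two statistical choices.

The premise: in a healthy cohort, samples in the lowest decile of GCD
expression approximate the expression state of mildly affected patients,
so genes that are *specifically* low in those samples are candidate
co-tolerated (compensatory) modifiers.

The first statistical choice is to work with within-dataset ranks and
thresholds only. Expression units (RPKM, FPKM, TPM, array intensity) never
mix across datasets: Step 1 thresholds within the healthy matrix, Step 2
compares a pair-count statistic computed within the case–control study to
the same statistic computed within the healthy cohort, and Step 3 ranks
within the healthy matrix. Every downstream result is therefore invariant
under any strictly increasing transform applied to either dataset
separately (a tested property), which is the method's answer to
cross-platform confounding.

The second is to prefer exact or resampling-based null distributions over
parametric approximations: a hypergeometric tail for set overlap, a
without-replacement resampled null for the case–control contrast, and an
enumerated rank-sum null at small sizes.

## Step 1

With `N` samples, bottom fraction `f` (default 0.10), the low set has
exactly `k_low = floor(f·N)` members; ties at the boundary are broken by
matrix column order (stable sort), so results are reproducible and
independent of storage quirks. The overlap p-value is the hypergeometric
upper tail computed in log space (log-gamma binomial coefficients combined
by a running `logaddexp`), accurate at cohort scale where naive factorials
overflow. Bonferroni uses the number of genes actually tested: eligible
genes only, excluding the GCD itself (self-overlap is tautological).

Eligibility excludes constant genes and genes whose minimum-value tie
spans `>= N − k_low` samples (typically zero-inflated genes), because the
bottom set would then be an arbitrary selection from a majority tie.
Jittering was rejected as it fabricates ranks. The GCD and candidate
fractions are exposed as separate parameters (`fraction`,
`gene_fraction`), defaulting to equal values.

## Step 2

The null hypothesis is that the PM is as far below controls in disease as
it is below the GCD-not-low samples in health. The statistic is the count
of strictly lower (case, control) pairs; ties count zero, exactly mirrored
in the resampled null. The empirical p is `T / reps` with
`T = #{i : observed >= P_i}` and no add-one smoothing, so p = 0 is
attainable; rejection (p < 0.05) means the disease drop is consistently
*weaker* than the healthy-conditional drop — the signature of a
compensatory modifier rather than a passively co-regulated gene.

Null draws are without replacement within each pseudo-arm. Per-gene random
substreams are derived by hashing the master seed with the gene id
(SHA-256, folded to a 63-bit integer feeding `numpy`'s PCG64), so gene
order, subsetting and parallelism cannot change any result, and output is
bit-identical across platforms. Multiple testing across PMs is not
corrected by default (a flat 0.05, with an optional Benjamini–Hochberg
column in the CLI), matching the method's intended use as a screen.

## Step 3

Samples are split by whether the full-length isoform strictly exceeds the
truncated one — equivalent to ratio > 1 but defined when the denominator
is zero; exact ties (including 0/0) are excluded rather than assigned to a
side. The one-sided rank-sum test (alternative: DPM expression
stochastically smaller in the high-ratio group) is computed by exhaustive
enumeration over labelings with midrank ties for combined sizes up to 12,
including the observed table (no mid-p), and by the tie- and
continuity-corrected normal approximation above that. Enumeration shows
the approximation is within 0.01 of exact when the smaller group has at
least 5 members, degrading to ~0.02 for two-member groups — one reason the
exact branch covers the small-sample range.

## Power and type-I estimation

Both estimators use the healthy matrix alone. Detection confidence draws
both pseudo-arms of size N from the GCD-low stratum (jointly, without
replacement, hence disjoint whenever `2N` fits; otherwise independent
draws with a logged warning) and runs the full Step-2 test, resampling the
null afresh each of the R = 10 replicates. Confidence is the accepted
fraction; the minimal-N search walks an explicit grid because confidence
is Monte-Carlo noisy and not strictly monotone.

Type-I estimation draws pseudo-cases from the GCD-low stratum and
pseudo-controls from its complement — the null configuration — so every
rejection is a false positive. The test is exactly conservative: because
the observed statistic and the null replicates are exchangeable, each
gene's true rejection probability is below α. With continuous (log-normal)
synthetic marginals that probability typically sits only a little below
0.05, so a 100-replicate binomial estimate of it lands above 0.05 for an
appreciable share of genes; the binarized share-controlled summary is
therefore noisy even when control genuinely holds, and the pooled
rejection rate is the more stable summary. Real zero-inflated expression
data fattens the null's discrete atoms and pushes the per-gene probability
further below α, which is when the share-controlled summary is close
to 1.

## Synthetic cohorts

The generator produces the structure the method assumes, not a full
RNA-seq emulation. Healthy expression is log-normal per gene
(`marginal_log_mean = 1.0`, `marginal_log_sd = 0.5` — moderate
within-tissue biological variability on the natural-log scale); planted
PMs and decoys share a bivariate Gaussian copula with the GCD's latent
variable at `coupling_rho = 0.9`, the minimal model giving the required
lower-tail co-occurrence without dictating global linear correlation. The
case–control study (default 7+7) draws case GCD values below the healthy
2nd percentile; true DPMs follow their unconditional marginal in both arms
(not downregulated in disease); decoys are multiplied by
`decoy_case_effect = 0.3` in cases. With `sd = 0.5` and multiplicative
platform noise `noise_sd = 0.15`, a decoy's case drop measured against the
combined spread (1.204 / √(2·0.5² + 2·0.15²) ≈ 1.66 standard units) is
comparable to the healthy GCD-low-vs-rest drop at ρ = 0.9 (≈ 1.68 latent
units), i.e. decoys genuinely instantiate the null hypothesis Step 2 is
meant to reject PMs under. The whole case–control matrix is scaled by
`platform_scale = 100` to emulate a different measurement platform —
inert by rank invariance, present so nothing accidentally depends on
shared units.

The isoform pair is generated by a logistic link: per sample, P(FL >
truncated) = σ(w · mean of the negated modifier z-scores), with
`isoform_link_weight = 6.0` — a strong link, reflecting the direct
mechanistic control a splicing factor exerts over exon inclusion, and
calibrated by pilot runs so the planted modifiers separate from merely
GCD-coupled DPMs (all of which correlate with the ratio through the shared
latent factor).

What the generator does **not** emulate: zero inflation, library-size and
GC bias, gene–gene network structure among background genes, batch
effects beyond one global scale, and isoform quantification noise. Tests
passing on these cohorts show the statistics behave as designed under the
assumed structure; they do not certify performance on real tissue data,
where zero-heavy genes (handled by the eligibility screen) and unmodeled
covariates are the main differences.

## Numerical and design notes

- Hypergeometric tails validated against exhaustive subset enumeration
  (≤ 1e-12 for all N ≤ 12) and cross-checked against an independent
  library implementation at cohort scale.
- Low-set size uses `floor`, and sample-order tie-breaking, as the
  reproducible reading of "bottom 10%".
- Pair counting uses strict inequality both for the observed statistic and
  the null, and `T` counts null replicates with `P_i <=` observed — ties
  get no half-credit in either place.
- Degenerate inputs fail loudly: cohorts too small for the fraction,
  strata smaller than the requested arms, empty ratio partitions and
  constant genes raise typed errors that the CLI maps to exit code 4
  (data/format problems map to 3).
- Default problem sizes (400 samples × 1,000 genes; 200 seeds for
  error-rate estimates; 10,000 null replicates) are desk-scale choices
  that keep the full test suite and the acceptance script in the
  minutes range on one CPU while leaving Monte-Carlo slack far smaller
  than the margins being tested.

## Known limitations

- Step 1's screen is marginal per gene; co-regulated gene modules enter or
  leave together, and the method cannot distinguish a driver from its
  passengers without the later steps.
- Step 2's power collapses when the case–control arms are tiny (< 4 per
  arm) because the pair statistic takes few values.
- The enrichment universe is a mandatory explicit argument: enrichment
  p-values are only meaningful relative to a stated universe, and the
  defensible default (eligible genes of the healthy matrix) is a choice,
  not a fact.
- Multi-tissue intersection treats tissues symmetrically; no weighting by
  cohort size or tissue relevance.
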