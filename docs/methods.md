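# Methods

This note documents the models, conventions and numerical choices behind
`tmescore`, in the order data flows through the package.

## Housekeeping normalization (NanoString-style counts)

Input: non-negative linear counts, gene × sample, with a designated
housekeeping gene list (default: the 10-gene panel ACTB, ABCF1, B2M, G6PD,
GAPDH, GUSB, PGK1, RPLPO, TFRC, TUBB). With a +1 pseudo-count applied to
every count, sample *s* gets the scale factor

    f_s = mean_t( geomean_g(c_gt + 1) ) / geomean_g(c_gs + 1),

geometric means taken over the housekeeping genes present (≥ 50% of the
list must be found, else an error lists the missing genes; a sample whose
housekeeping counts are all zero is an error naming the sample). The
normalized value is `log2(f_s · (c + 1))`.

Applying the pseudo-count *before* scaling makes the post-normalization
housekeeping geometric means exactly equal across samples (machine
precision; the suite asserts ≤ 1e-9 relative) and makes the procedure
idempotent on its own output. The cost is that scale invariance — a sample
with all counts doubled normalizing to exactly the same profile — holds
only up to the pseudo-count's relative weight, ~1/count; it is tested at
1e-5 on large counts. No pseudo-count would give exact scale invariance but
undefined logs at zero counts; we prefer robustness at zero.

## Per-gene standardization

Each gene row is centered and scaled to sample SD 1 (denominator n−1,
matching the reference ecosystem's convention), requiring ≥ 3 samples.
Zero-variance genes are dropped with a warning by default (`error`
available): flat genes are common on targeted panels and carry no
directional information.

## PC1 signature scores

Samples are observations, z-scored signature genes are variables. The score
is the projection onto the unit-norm leading eigenvector of the gene-gene
covariance (computed via full SVD). Consequences: scores have mean 0 across
samples and variance equal to the leading eigenvalue; no per-signature
rescaling is applied by default, so larger/tighter signatures contribute
more variance to the TMEscore sum (a `rescale_signatures` flag z-scores
each signature column first, for users who want panel-size-balanced
contributions — the A/B panels have 25 vs 19 genes).

PCA leaves the eigenvector sign free. We orient it so its component sum is
positive, with an exact-zero tie broken by making the alphabetically first
gene's component non-negative. This makes "high score = high
signature-gene expression", makes results independent of gene ordering and
linear-algebra backend, and is asserted against an independent
eigendecomposition oracle at 1e-10. Coverage policy: scoring errors if
fewer than `min_coverage` (default 0.5) of a signature's genes are usable;
a single usable gene degenerates to that gene's z-scores with a warning.

## TMEscore assembly

TMEscoreA = sum of scores of direction-+1 signatures, TMEscoreB = sum for
direction-−1 signatures, both in collection order; TMEscore = A − B
computed once from those two sums, so the identity
`TMEscore − (TMEscoreA − TMEscoreB) = 0` holds bitwise. Directions live on
the signature objects (GMT description field `+1`/`-1`); a scored signature
without a direction is an error. Dichotomization: score > cutoff → "high",
score ≤ cutoff → "low" (boundary to "low", matching the survival cutpoint's
split rule).

## ssGSEA scores

Per sample, genes are ordered by decreasing expression, ties broken by gene
id ascending so results are exactly reproducible. Walking down the list,
the score accumulates `P_in(k) − P_out(k)`, where `P_in` is the in-set ECDF
weighted by `rank^α` (the top-expressed gene carries the largest rank
weight, the usual single-sample GSEA convention) and `P_out` is the
unweighted out-of-set ECDF. Defaults: α = 0.25, no cross-sample
normalization (optional division by the score range across samples). Only
ranks enter, so the score is invariant under strictly monotone per-sample
transforms — unlike the PC1 and z-mean scorers, it does not care whether
input is linear or log scale. A set covering every gene in the matrix has
an empty complement and is rejected.

## Biomarker statistics

Convention: higher score = more likely responder (RECIST CR/PR = 1,
SD/PD = 0).

- **ROC/AUC**: curve over unique score thresholds with sentinels;
  trapezoidal area, which with midrank tie handling equals the normalized
  Mann-Whitney U statistic (asserted to 1e-12).
- **DeLong**: per-sample placement values give AUC variance/covariance;
  z = (AUC1 − AUC2)/√(v1 + v2 − 2c12). If the variance term is ≤ 0 with
  equal AUCs, p = 1. "Unpaired" mode sets the covariance to 0 for curves
  from different sample sets (the evaluable subsets of different biomarkers
  overlap but need not coincide). Null calibration at n = 100 is within
  [0.035, 0.065] at α = 0.05 over 1000 replicates; the implementation is
  also checked against the R pROC reference in the suite.
- **Mann-Whitney**: exact enumeration when n_x + n_y ≤ 20 with no ties
  (small enough for desk-scale enumeration), else normal approximation with
  tie and continuity corrections.
- **Kruskal-Wallis**: tie-corrected H, chi-square reference; all-identical
  data returns H = 0, p = 1 rather than an error.
- **Fisher exact (2×2)**: two-sided by minimum-likelihood summation (the
  ecosystem default). The odds-ratio estimate is the unconditional sample
  OR with a 0.5 continuity correction when a cell is zero; the conditional
  MLE is out of scope.
- **BH adjustment**: step-up with cumulative minima, returned in input
  order. Note BH q-values are not a fixed point of the procedure in
  general; the suite asserts the step-up formula itself, q ≥ p, and that
  re-adjustment never decreases a value.
- **Spearman**: Pearson on midranks, t approximation with n − 2 df.

## Survival analysis

- **Kaplan-Meier**: product-limit estimator (censoring at an event time
  processed after the events), reported at event times.
- **Log-rank**: observed-minus-expected group-1 events over shared risk
  sets with hypergeometric variance; the standardized form (O−E)/√V is
  exposed because the cutpoint selector maximizes it.
- **Univariate Cox**: Newton-Raphson on the partial likelihood, Efron tie
  handling by default (Breslow behind a flag), covariate centered for
  stability, steps clamped to |Δβ| ≤ 2 to prevent overshoot, convergence at
  |Δβ| < 1e-9 within 50 iterations; |β| > 30 is reported as monotone
  likelihood (perfect separation). SE from the inverse information; Wald p
  and CI `exp(β ± 1.96·se)`. Checked against brute-force likelihood
  maximization and against lifelines.
- **Maximally-selected cutpoint**: candidates are observed score values
  whose split (low = score ≤ c) leaves ≥ `minprop` (default 0.1) of samples
  on each side; the candidate maximizing |standardized log-rank| wins, ties
  to the smallest cutpoint. No p-value is attached by default — the maximum
  is selection-biased — but a seeded permutation p over the maximal
  statistic is available. Like all changepoint estimators this one
  converges at a cube-root rate: under a planted two-cluster design
  (hazard ratio 4, n = 100) the selected split matches cluster membership
  to within 10% of samples in ≥ 95% of seeds, and exact-boundary recovery
  should not be expected.

## Association screens

Mutation screen: per gene with ≥ `min_mutated` (default 5) mutated *and*
wild-type samples, Mann-Whitney of score by status; BH across exactly the
tested genes; direction = sign of the median score difference; rows sorted
by (q, p, gene). Subtype enrichment builds the 2×2 table from a binary
class and a caller-grouped two-level subtype and dispatches to Fisher or
Yates-corrected chi-square. Signature correlation screen: Spearman per
column with BH, constant columns dropped with a warning. All screens align
samples by id, never by position.

## Synthetic cohorts

Latents (a_s, b_s) are bivariate standard normal with correlation
`latent_corr` (default −0.3: stromal activation accompanies immune
exclusion). Signature-A genes are `baseline + loading_a·a_s + N(0,
noise_sd²)` on the log2 scale (B genes analogous with b_s; background genes
pure noise; per-gene baselines ~N(7,1) give realistic log2 levels but drop
out under standardization). Response is Bernoulli with logit
`beta0 + beta1·(a_s − b_s)`; survival is exponential with hazard
`baseline_hazard·exp(−hazard_gamma·(a_s − b_s))` under independent uniform
censoring whose horizon is solved numerically so the expected censored
fraction equals `censor_rate`; mutations are Bernoulli with logit
`logit(0.2) + mut_assoc_slope·a_s`.

Defaults are the package's reference study conditions: n = 60, panel sizes
25/19 with 56 background genes, unit loadings and noise, beta1 = 2,
beta0 = −1 (≈ 25-30% responders, typical of ICB in advanced gastric
cancer), hazard_gamma = 1, baseline_hazard = 0.1, censor_rate = 0.3,
20 mutation genes with slope 1. The seed is mandatory; each component draws
from its own spawned substream, so enabling or resizing one component never
perturbs another's draws.

What the generator does *not* emulate: count-level noise models (negative
binomial, library-size effects — a Poisson count mode exists only in the
fixture, to exercise housekeeping normalization), batch effects, gene-gene
correlation beyond the single factor per signature, non-proportional
hazards, or informative censoring. Passing the end-to-end recovery suite
therefore shows the pipeline is correct and well-calibrated under its own
assumptions, not that any fixed AUC will be achieved on real tumors.

The packaged gene panel is a synthetic stand-in: it reproduces the
structure of a TME NanoString panel (25 immune "A" genes, 19 stromal "B"
genes including FAP, MIR100HG, SYNPO, TGFB1I1; 10 housekeeping genes;
checkpoint genes as metadata) with field-typical marker symbols, and is not
a published, validated signature.

## Problem sizes in the validation suite

Oracle-equality checks use 200 random matrices (PC1) and 500 instances
(AUC); calibration and recovery use 1000 null replicates at n = 100
(DeLong), 100 seeds at n = 500 (Cox), 100 seeds at n = 100 (cutpoint), and
50 seeds at n = 60 (end-to-end) — sizes at which the Monte-Carlo error of
each rate or mean is comfortably below the asserted margin.

## Known limitations

- Gene identifiers are opaque case-sensitive strings; no HGNC aliasing or
  probe collapsing (tables must be gene-level).
- No multivariable Cox, competing risks, partial AUC, or combined-biomarker
  models.
- The DeLong "unpaired" mode assumes independent curves; partially
  overlapping sample sets are treated as independent.
- Mutation input is a binary gene × sample matrix; MAF parsing is the
  caller's one-line preprocessing step.
- Meta-cohort pooling (combining datasets before cutpoint selection) is the
  caller's responsibility; cutpoints are per-dataset.
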