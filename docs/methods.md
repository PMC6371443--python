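# Methods

## PLS path modeling

### Estimator

`fit_plssem` implements the classical Lohmöller alternating least-squares
estimator for recursive (acyclic) structural models with reflective
measurement. All standardization in the package uses the sample convention
(mean 0, sd 1 with the n−1 denominator); outer weights are reported on the
unit-variance score scale, i.e. scaled so that var(X_j w_j) = 1, which is
also the scale on which convergence is monitored.

- **Inner scheme**: path weighting only. A predecessor of block j is
  weighted by its coefficient in the multiple OLS regression of Y_j on all
  of j's predecessors; a successor by its correlation with Y_j. Centroid
  and factorial schemes are not implemented.
- **Outer mode**: Mode A only (weights ∝ indicator–proxy correlations).
  Reflective measurement is the standard choice for co-expressed gene
  blocks; Mode B / formative blocks are out of scope, as are consistent-PLS
  corrections and higher-order constructs.
- **Convergence**: max absolute change of any outer weight < `tolerance`
  (default 1e-7) within `max_iterations` (default 300). Non-convergence
  returns the fit with `converged=False` plus a `ConvergenceWarning`; with
  noise-free single indicators the iteration converges in one step because
  the scores equal the standardized columns from the start.
- **Sign indeterminacy**: latent scores are defined up to sign. After
  convergence each block is flipped, if necessary, so its sum of loadings
  is non-negative; an exact zero sum is resolved by the sign of the first
  indicator's loading. This determinism is what makes bootstrap draws
  comparable.
- **Degenerate inputs**: zero-variance indicator columns are rejected at
  data construction; collinear predecessor scores (correlation-matrix
  condition number > 1e12) raise an error naming the latent variables; a
  single-indicator block has loading 1 and AVE = CR = 1 identically.

Path coefficients are per-target OLS on the final standardized scores, so
with all blocks single-indicator the engine reduces exactly to OLS path
analysis among the standardized observed columns — the tests exploit this
reduction as an independent oracle, along with the two-block special case
where the single path equals the Pearson correlation.

Total effects are computed as T = Σ_{p=1..L} B^p, which on a DAG equals the
sum over all directed paths of the products of edge coefficients (B is
nilpotent, so the series is exact, not truncated).

### Bootstrap

`bootstrap_plssem` resamples the n cases with replacement, re-standardizes
within each resample and refits. Every parameter (outer weights, loadings,
path coefficients, total effects over all ancestor–descendant pairs) is
sign-aligned to the original-sample estimate — the "individual sign
changes" convention — before the bootstrap SE (n−1 sd over draws) is
computed. Significance compares t = |original| / SE with the fixed critical
value 1.96 (the two-sided 5% normal point; configurable), rather than a
Student quantile. The default number of draws is 5000; the tests use
scaled-down draw counts (≤ 2000) chosen so the SEs are stable to within a
few percent of the large-B value.

Resamples that produce a zero-variance indicator column or a non-converged
fit are discarded and redrawn so the requested number of valid draws is
reached; more than 10% discards raises an error, on the view that such data
should be inspected rather than silently summarized. A parameter with zero
bootstrap SE (e.g. a noise-free path of exactly 1) gets t = ∞ and is
flagged significant. Percentile/BCa intervals, blindfolding and permutation
tests are out of scope.

### Built-in hormone models

The registry holds the six hormone-specific structures (ABA, BR, IAA, CTK,
JA, SA): five latent variables (hormone block, NACs, MYBs, WRKYs, flowering
block), three first-order hormone→TF edges, three second-order
TF→flowering edges, and a direct hormone→flowering edge for every hormone
except IAA. ABA keeps the direct edge by default because the six structures
are otherwise parallel; `builtin_model(..., direct_edge=False)` drops it.
The recorded case counts (88, 41, 38, 52, 56, 59) are advisory metadata:
how a cases × indicators matrix is constructed from expression data (what a
"case" is, which genes indicate each block) is deliberately left to the
user, and a mismatching case count only warns. For the CTK model the
registry also carries the reported standardized coefficients
(0.945, 0.993, 0.917 first order; 0.130, −0.359, −0.208 second order),
which the generator can use as ground truth for recovery studies. The IAA
model keeps all three second-order edges; only its direct edge is absent.

## Synthetic data

`simulate_sem_dataset` draws exogenous latent variables as independent
standard normals and builds each endogenous one as the coefficient-weighted
sum of its predecessors plus an independent residual scaled so every latent
variance is exactly 1; feasibility (bᵀΣb ≤ 1 with Σ the implied predecessor
covariance) is checked analytically before sampling. Indicators are
x = λ·η + √(1−λ²)·noise, so λ = 1 gives noise-free indicators and the
indicator correlation between two single-indicator blocks is λ₁λ₂β. What
this emulates is the *covariance structure* the estimator consumes — it
does not emulate counts-derived expression summaries, block assignment
noise, or non-normal latent distributions, so recovery results certify the
estimator, not any claim about real panicle data.

`simulate_counts` emulates a triplicated two-condition RNA-seq design
(3 DP vs 3 SP by default): counts are negative binomial with mean
s_j·μ·2^(lfc·[SP]) and dispersion α (α = 0 is the Poisson limit), planted
DE genes drawn uniformly at random. Defaults (base mean 100, α = 0.1,
fourfold planted changes) are typical of moderately expressed transcripts
at desk-scale depth. Constant per-gene base means are used; real libraries
have heavy-tailed mean distributions, so power estimates here are
optimistic for low-expressed genes.

`simulate_annotation` plants enriched terms by biasing query sampling
toward their member genes by a configurable factor; genes hit by no term
stay outside the annotated universe, as with real sparse GO annotation.
`simulate_ct` writes Ct tables with ct_target = ct_ref + ΔCt_baseline −
log2(fold change) + noise, so noise-free tables invert exactly through
2^-ΔΔCt; amplification efficiency is ideal (exactly 2 per cycle).

Every generator owns a single `numpy.random.Generator` seeded explicitly;
reruns are bit-identical.

## Differential expression

The DE stage is a self-contained negative-binomial Wald pipeline, not a
re-implementation of any external tool: median-of-ratios size factors
(medians over the all-positive genes of per-gene ratios to geometric means;
reported without renormalization, so only ratios of size factors are
scale-meaningful); per-gene normalized counts k = K/s; log2FC from group
means with a 0.5 pseudocount per group mean; per-gene method-of-moments
dispersion α̂ = max(0, (v−m)/m²) with v the pooled within-group variance
and m the overall mean; delta-method SE² = (1/ln2)²[(1/μ̂₁+α̂)/n₁ +
(1/μ̂₂+α̂)/n₂]; two-sided normal p; BH step-up FDR; up/down calls at
FDR ≤ 0.01 inclusive. Counts are used as given (non-negative reals are
accepted, since upstream quantifiers emit non-integer expected counts).
Fold-change orientation is second condition minus first, with condition
order taken from sample order (DP before SP by convention), so positive
log2FC means "up in SP".

**Known limitation — calibration at 3-vs-3.** With two groups of three, the
per-gene dispersion estimate has only 4 degrees of freedom, and the Wald z
referred to the normal has roughly t₄ tails: in the package's own null
simulations the p < 0.05 fraction sits near 0.12 rather than 0.05, and at
BH FDR 0.01 a planted-DE simulation shows high recall (~0.97 for fourfold
changes at mean 200) but an empirical false-discovery proportion well above
the nominal level, because a few null genes draw near-zero dispersion
estimates. This is the known cost of per-gene estimation without sharing
information across genes (no shrinkage, no Cook's filtering, no independent
filtering — all deliberately out of scope); the tests assert this actual
behavior, and the separate calibration check that demands nominal error
control documents the gap rather than hiding it. For production inference
at n = 3 per group, an empirical-Bayes dispersion method is the right tool;
this stage's contract is the stated formulas.

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) for a query of n annotated genes overlapping k of a term's M genes
in an N-gene universe (delegated to scipy's stable implementation; an
exhaustive-enumeration oracle pins it in the tests). Query genes outside
the annotated universe are dropped with a warning and excluded from n;
`frequency` is defined as 100·k/n over the annotated query. Raw p-values
are reported by default — matching the common reporting style for GO
tables — with BH adjustment available as an opt-in column. Terms
overlapping the query by fewer than `min_overlap` genes (default 2) are
suppressed. The GO graph is not modeled: no term-term decorrelation, no
OBO parsing.

## Expression utilities and qPCR

FPKM = 1e9·C/(N·L) with N the column sum of the supplied count matrix
(no effective-length correction). Z-scoring is per gene row with the n−1
sd; constant rows cannot be standardized and become all zeros, with the
affected gene ids returned and warned about — erroring would make routine
heat-map preparation fragile, and zero is the natural "no signal" value.
Whether population or sample sd is used is a package convention (sample,
stated once, visible in the (1,2,3) → (−1,0,1) example), not a claim about
any external convention. qPCR quantification averages technical-replicate
Cts per (sample, gene, role), computes ΔCt against the per-sample reference
gene, ΔΔCt against a designated calibrator sample, and RQ = 2^−ΔΔCt; the
calibrator's RQ is exactly 1.

## Problem sizes in the test suite

The suite runs at desk scale by design: recovery checks use n = 2000 and
n = 20,000 cases (10 seeds) for the CTK structure, the bootstrap coverage
study uses 200 replications of n = 200 cases with 500 draws each, DE
calibration uses 2000-gene matrices, and oracle equivalences run on
fixtures small enough to enumerate. The second-order recovery check uses
the six-edge CTK structure (no direct edge): with the direct edge included,
the hormone score is nearly collinear with the MYB score (correlation
0.993 by construction), which makes the MYB→flowering OLS coefficient too
ill-conditioned for a ±0.02 recovery claim to be meaningful at these sizes;
dropping the edge whose generating coefficient is zero conditions the
regression while leaving the estimand unchanged.
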