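# Methods

## Pair features

For lncRNAs A < B (lexicographic), the feature is `S = 1[expr(A) > expr(B)]`
per sample; ties encode 0 (the count of tied comparisons is logged). Only
the canonical orientation is kept: on tie-free data the reversed indicator
is the complement `1 − S`, so the dropped orientation carries no extra
information — a Cox coefficient simply changes sign with the orientation.
Because S depends only on the within-sample ordering, the feature matrix is
invariant to strictly increasing per-sample transforms; this is the
method's core robustness property and is asserted bit-for-bit in the tests.

Pairs whose prevalence of ones across samples falls outside [0.2, 0.8]
(closed interval) are removed: a near-constant indicator cannot stratify
patients.

## Screens

*Immune relation*: Pearson correlation on log2(x+1) between every lncRNA
and every immune gene, over all samples (tumor + normal) by default; both
the method (Spearman available) and the sample set (tumor-only available)
are configurable because coexpression screens are run both ways in
practice. A lncRNA qualifies with any correlation r > 0.4 at p < 0.001
(strict inequalities). Zero-variance genes are skipped with a warning
rather than erroring.

*Differential expression*: Welch's t-test per gene on log2(x+1), with
log2FC the difference of group means on that scale, BH-adjusted across the
tested lncRNAs; a gene passes at |log2FC| ≥ 1 and adjusted p < 0.05. The
test is deliberately a plain two-sample test behind a pluggable interface
(any callable `test(tumor, normal) -> p` can be substituted); moderated
variance estimators are out of scope. The threshold is applied to the
*adjusted* p-value.

## Selection funnel and risk score

1. Univariate Cox per pair (Efron ties, Wald p); survivors at p < 0.05.
   Per-pair fit failures are logged and skipped, never fatal.
2. Bootstrap stability selection: B patient resamples with replacement
   (default B = 1000; scaled runs use B = 100 with the threshold scaled to
   B/10). Each resample runs a full L1-penalized Cox path
   (coordinate-descent Coxnet, 100 path points down to `1e-3·λ_max`) with λ
   chosen by k-fold (default 10) cross-validated partial-likelihood
   deviance in the Verweij–van Houwelingen form, minimum rule. A pair's
   frequency is the number of resamples whose chosen support contains it;
   selection requires frequency strictly greater than the threshold.
   Resamples with degenerate folds are redrawn; individual resample
   failures are counted and tolerated up to 10%.
3. Unpenalized multivariate Cox (Efron ties) on the selected pairs supplies
   the coefficients: `RiskScore = Σ βᵢ Sᵢ`. Exactly collinear features are
   dropped greedily in canonical order before fitting.

The coefficients come from the unpenalized refit, not the LASSO, so the
reported hazard ratios and confidence intervals have their usual Cox
interpretation. A cohort in which nothing passes a stage yields an *empty*
results object (and the pipeline records an empty signature) rather than an
error.

Caveat: because the univariate screen and the bootstrap selection reuse the
same cohort, pure-noise features that survive the marginal screen are
re-selected more often than a naive null rate would suggest; on null data
the funnel can emit a small spurious signature. The synthetic generator's
ground truth is the intended way to judge such artifacts.

## Evaluation

*Time-dependent ROC*: cumulative-case / dynamic-control with IPCW weights.
At horizon t, cases are subjects with an observed event by t (weight
1/G(T⁻), with G the Kaplan–Meier estimate of the censoring survival
function), controls are subjects beyond t (their common weight cancels).
The AUC is the weighted probability that a case outscores a control (ties
half-weight), identical to the trapezoid under the weighted sweep; it is
checked against explicit pairwise enumeration to 1e-12.

*Cutoff*: candidates are midpoints of consecutive sorted unique risk
scores, constrained so each side keeps ≥10% of samples (an unstated but
necessary stabilizer). For each candidate a single-covariate Cox model on
the high/low indicator is maximized — via an O(n) Efron profile likelihood
exact for a binary covariate — and the cutoff minimizing AIC = 2 − 2·logPL
is returned. Ties at the cutoff go to the low-risk group ("higher than" is
strict). A Youden-point rule on the 1-year ROC is available behind a flag.
Note that with a continuous score the AIC-minimizing cutpoint behaves like
any maximally selected statistic and can overfit single boundary samples;
pair-signature scores are sums of a few βᵢ and hence take few distinct
values, which keeps the candidate set small and the choice stable. The
cutoff-recovery simulations therefore use discrete score levels.

*Group comparisons*: KM + log-rank (lifelines); risk score vs clinical
covariates via Wilcoxon rank-sum (2 levels) or Kruskal–Wallis (>2), risk
group vs covariate via Pearson chi-square without continuity correction;
age is dichotomized at 65 for the rank tests only. Independence analysis
fits univariate and joint Cox models on risk score, age, gender and stage
(ordinal-linear by default, factor coding available).

## ssGSEA

Per sample, genes are ranked by expression (average ranks for ties). The
ranked list is walked from the highest expression down; the enrichment
score is the sum over positions of the difference between the in-set
cumulative distribution weighted by rank^α (α = 0.25) and the uniform
out-of-set cumulative distribution. Scores are then min–max normalized per
signature across samples so group contrasts are scale-free; both α and the
normalization are configurable. Group comparisons use the unpaired
Wilcoxon rank-sum test (risk groups are independent samples), Spearman
correlation against the risk score, and median-split survival stratification
(ties to the low stratum); raw p < 0.05 is the default significance flag
with BH correction available but off.

## Synthetic cohorts

Log2 expression is normal per gene (lncRNA means U(1,6), immune mRNA means
U(3,8), sds U(0.8,1.5)) and exponentiated to an FPKM-like scale, matching
positivity and the pipeline's log2(x+1) transform. True immune lncRNAs mix
the standardized log2 value of an assigned immune mRNA with independent
noise at weight r (default 0.9) so the achieved log-scale correlation
concentrates near r. True DE lncRNAs add a tumor-only shift of
`de_log2fc` (default 2) on the log2 scale. Both members of a planted
prognostic pair share a location so the pair indicator stays near
prevalence 0.5 and remains informative.

Tumor survival is exponential with hazard `h₀·exp(Σ βₖ Sₖ)`
(h₀ = 5·10⁻⁴/day, median ≈ 3.8 years at baseline — colon-cohort scale),
with the indicators computed exactly as the pair encoder computes them.
Censoring is independent exponential with its rate solved numerically
(Brent) so the expected censored fraction hits the target; this keeps the
IPCW independence assumption valid. Times are rounded up to whole days to
produce registry-style ties. Stage (4 ordinal levels) is tilted by the
standardized true linear predictor through an ordered-logit construction,
giving the independence analysis realistic confounding; T/N/M derive from
stage with noise, age ~ N(66, 11) clipped to [30, 90], gender balanced.

One integer seed feeds a `SeedSequence` hierarchy with a separate stream
per component (mRNA, lncRNA, survival, censoring, clinical), so enlarging
the gene panel does not perturb the survival draws. Identical config +
seed reproduces the cohort bit-for-bit.

What the generator does *not* emulate: read-count noise, batch effects,
tumor purity, correlated gene modules beyond the planted immune pairings,
non-proportional hazards, informative censoring. Passing recovery tests
therefore demonstrates correctness of the machinery under the stated model,
not robustness to those real-data complications.

## Problem sizes and defaults

Simulation-based checks run at desk scale chosen for adequate power: the
headline recovery study uses 300 tumors, 20 lncRNAs (≥53 pairs after the
prevalence filter), B = 100 bootstraps with threshold B/10, 20 seeds;
cutoff recovery uses two 60-patient clusters at hazard ratio e^1.5 over 50
seeds; generator defaults mirror these conditions. The full-size settings
(B = 1000, threshold 100) remain the package defaults.

## Known limitations

- The stability-selection frequency counts CV-chosen supports; counting
  per-λ path membership is a plausible alternative reading and would give
  larger frequencies.
- With strongly correlated pairs (shared genes), the funnel often selects
  correlated companions alongside true pairs; coefficients of true pairs
  remain consistent but their variance inflates.
- The AIC cutoff does not correct for cutpoint selection multiplicity (see
  above).
- Efron tie handling makes the subject-duplication invariance of the Cox
  estimate approximate rather than exact (Breslow would be exact).
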