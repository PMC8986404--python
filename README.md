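# lncpair

Prognostic signatures for censored survival cohorts built from **immune-related
lncRNA pairs** rather than absolute expression levels.

## The problem and the approach

Bulk expression values from different cohorts or platforms are hard to compare
without batch correction, which makes expression-based prognostic signatures
fragile. The pair trick (in the spirit of top-scoring-pair classifiers)
side-steps normalization entirely: for an unordered pair of lncRNAs (A, B) a
patient is scored

```
S_i = 1  if expr(A) > expr(B) in that patient, else 0
```

which depends only on the within-sample ordering and is invariant to any
strictly increasing per-sample transform of expression.

The full pipeline, aimed at tumor cohorts with matched clinical follow-up:

1. **Immune screen** — lncRNAs co-expressed with an immune gene list
   (Pearson on log2(x+1), r > 0.4, p < 0.001);
2. **DE screen** — tumor-vs-normal differential expression of those lncRNAs
   (|log2FC| ≥ 1, Benjamini–Hochberg adjusted p < 0.05);
3. **Pair features** — all 0/1 pair indicators, keeping pairs whose
   prevalence of ones lies in [0.2, 0.8];
4. **Selection funnel** — univariate Cox screen (p < 0.05), then
   bootstrap-stabilized LASSO-Cox: on each of B patient resamples a full
   L1-penalized Cox path is fitted with λ chosen by 10-fold cross-validated
   partial-likelihood deviance, and pairs entering the chosen support in more
   than `freq_threshold` resamples (default >100 of 1000) survive;
5. **Risk score** — an unpenalized multivariate Cox fit on the selected
   pairs gives `RiskScore = Σᵢ βᵢ·Sᵢ`;
6. **Evaluation** — 1/2/3-year IPCW time-dependent ROC/AUC, an AIC-optimal
   high/low cutoff, Kaplan–Meier + log-rank, clinical association and
   independent-prognostic-factor Cox tables, and an ssGSEA immune landscape
   (risk-group comparisons, Spearman correlation with the risk score,
   score-stratified survival, checkpoint-gene contrasts).

A synthetic-cohort generator (`lncpair.simulate`) produces TCGA-like
tumor/normal matrices with known immune-correlated lncRNAs, known DE
lncRNAs, and survival whose hazard is exp(Σ βₖ·Sₖ) over known true pairs —
so every stage has a recoverable ground truth.

## Worked example

```python
from lncpair import CohortConfig, simulate_cohort, PairSignatureCox
from lncpair.simulate import lnc_id

config = CohortConfig(
    n_tumor=200, n_normal=30, n_lncrna=16, n_immune_mrna=16,
    n_true_immune_lnc=6, n_true_de_lnc=6,
    true_pairs=[(lnc_id(0), lnc_id(1), 0.8), (lnc_id(2), lnc_id(3), -0.8)],
    seed=42,
)
cohort = simulate_cohort(config)
model = PairSignatureCox.from_cohort(
    cohort.expression, cohort.clinical, list(cohort.expression.mrna_ids),
    n_bootstrap=100, freq_threshold=10,
)
results = model.fit(seed=42)
print(results.summary())
strat = results.stratify()
print(f"AIC-optimal cutoff: {strat.cutoff:.3f}   log-rank p: {strat.logrank.p:.2e}")
```

prints

```
Pair-signature Cox model
================================================================
samples: 200    events: 129
pairs screened: 10    univariate survivors: 3
bootstraps: 100    frequency threshold: >10    selected: 3

                   beta     se     HR  ci_low  ci_high      p  freq
covariate
LNC0001|LNC0002  1.2253 0.2211 3.4052  2.2077   5.2523 0.0000   100
LNC0002|LNC0004  0.2667 0.2144 1.3057  0.8578   1.9875 0.2134    68
LNC0003|LNC0004 -1.0299 0.2028 0.3571  0.2400   0.5313 0.0000   100

log partial likelihood: -543.1258
AIC-optimal cutoff: 0.098   log-rank p: 3.79e-08
```

Both planted pairs are selected in every bootstrap (`freq = 100`), their
hazard ratios sit on the correct sides of 1 (true log-hazards +0.8 / −0.8;
the estimates are noisier because a correlated companion pair was also
selected), and the AIC cutoff splits the cohort into groups whose survival
separates at p ≈ 4·10⁻⁸.

The same analysis runs from the shell: `lncpair simulate` writes a fixture,
`lncpair run-all --config cfg.yaml` chains every stage and writes all
intermediate tables plus a manifest.

## Layout

- `lncpair.simulate` — synthetic cohorts with ground truth
- `lncpair.screen` — immune correlation + DE screens, BH adjustment
- `lncpair.pairs` — pair encoding and prevalence filter
- `lncpair.signature` — Cox engine, CV-LASSO, stability selection, risk model
- `lncpair.model` — `PairSignatureCox` / `PairSignatureCoxResults`
- `lncpair.evaluate` — IPCW ROC, AIC cutoff, KM/log-rank, clinical tests
- `lncpair.immune` — ssGSEA and immune-landscape comparisons
- `lncpair.io`, `lncpair.pipeline`, `lncpair.cli` — formats, runner, CLI

See `docs/methods.md` for the statistical details and design choices.
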