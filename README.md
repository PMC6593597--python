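# twiner

Twin-network recovery (twiner) penalties for sparse logistic regression:
identify gene signatures **shared by two diseases** by letting each
gene's gene-gene correlation structure in the two diseases set its own
regularization strength.

## The problem

Breast and prostate carcinomas — and hormone-dependent cancers in
general — share signaling layers, and genes driving features common to
both diseases are candidate shared biomarkers. Classifying tumor vs
normal tissue separately per disease finds per-disease signatures; what
is wanted is a single classifier over both cohorts whose selected genes
behave *similarly* in the two diseases' co-expression networks.

## The method

Let Σ_A and Σ_B be the p × p Pearson correlation matrices of the two
cohorts and σ_j^A, σ_j^B the j-th columns (gene *j*'s correlation with
the rest of the transcriptome). The dissimilarity of gene *j* across
diseases is the angle between those vectors,

    d_j(A,B) = arccos( ⟨σ_j^A, σ_j^B⟩ / (‖σ_j^A‖·‖σ_j^B‖) ),

normalized by the maximum into penalty factors w_j = d_j / max_k d_k ∈
[0, 1]. These enter a weighted elastic-net logistic regression for
tumor (either disease) vs normal:

    min_{β₀,β}  −(1/n) ℓ(β₀, β) + λ[ α‖w∘β‖₁ + (1−α)‖w∘β‖₂² ],

so genes with "twin" correlation patterns (small d_j) are penalized
less and are preferentially selected. Around the estimator sits the
full experimental protocol: an angular pre-filter (default: discard
genes with d_j ≥ 75°), 100 random 75/25 train/test splits with 10-fold
cross-validation for λ at α = 0.9, Brier score / PR-AUC /
misclassification metrics, consensus signatures (genes selected in
> 75% of runs), correlation-network export for the selected genes, and
survival validation (Cox fit on the signature, median-risk split,
Kaplan–Meier curves, log-rank test).

The weighted solver is written here (numba-accelerated coordinate
descent, glmnet-style); correlation, cross-validation folding, PR-AUC,
Cox/KM/log-rank go through numpy/scikit-learn/scikit-survival/lifelines.

## A worked example

```python
import numpy as np
import twiner as tw

# two cohorts sharing a 30-gene "twin" correlation block; 5 of those
# genes drive the tumor/normal outcome in both cohorts
scenario = tw.TwinScenario(seed=1)          # n=150/cohort, p=300
ds_a, ds_b, truth = tw.generate(scenario)

merged  = tw.merge_cohorts(ds_a, ds_b)
weights = tw.compute_twiner_weights(ds_a, ds_b, merged.gene_ids)
kept, kept_w, dropped = tw.prefilter_by_angle(merged, weights, 75.0)
print(f"kept {kept.n_genes}/{merged.n_genes} genes")

result = tw.run_stability(kept, kept_w, n_runs=30, base_seed=1001)
print(result.medians[["test_mse", "test_auc_pr"]].round(3))
print({m: len(g) for m, g in result.consensus.items()})
```

prints (exact numbers for these seeds):

```
kept 31/300 genes
        test_mse  test_auc_pr
en         0.099        0.960
twiner     0.099        0.961
{'en': 9, 'twiner': 9}
```

The pre-filter keeps essentially the twin block (its median angular
distance is ≈ 40° against ≈ 90° for disease-specific and noise genes);
both methods then classify with Brier score ≈ 0.10 and PR-AUC ≈ 0.96 on
held-out samples, and the consensus signatures contain all 5 planted
signal genes.

The `examples/` scripts walk one capability each: angular weights
(`01`), the weighted fit (`02`), the stability protocol (`03`) and
survival validation (`04`). A thin CLI mirrors the pipeline:
`twiner simulate --seed 7 --out data/` and
`twiner run --expr-a A.tsv --expr-b B.tsv ... --out results/`.

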