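# logsumlr

Sparse, group-aware biomarker selection and binary classification with
**LogSum + L2 penalized logistic regression**, solved by coordinate
descent inside an IRLS loop.

High-dimensional expression data (p genes ≫ n samples) breaks plain
logistic regression twice over: the fit is dense (every gene gets a
coefficient, none interpretable as a biomarker) and it overfits badly.
Penalized logistic regression addresses both by minimizing

```
min over (β0, β):   (1/n) Σᵢ [ log(1 + exp(ηᵢ)) − yᵢ ηᵢ ]  +  P(β),
η = β0 + Xβ
```

This package implements the **LogSum + L2** penalty

```
P(β) = λ Σⱼ [ λ1 · log(|βⱼ| + ε) + λ2 · βⱼ² ],    λ1 + λ2 = 1
```

whose log-sum term is a tight, nearly unbiased surrogate for the L0 norm
(aggressive sparsity with little shrinkage of large coefficients) and
whose ridge term spreads weight over groups of correlated features, so
co-regulated genes are selected together.  The workhorse is the
closed-form univariate thresholding operator: with zero band
λ* = 2√(λ1(1+2λ2)) − (1+2λ2)ε,

```
f(w) = 0                                            if |w| ≤ λ*
f(w) = sign(w) · [ (|w| − (1+2λ2)ε)
        + √((|w| + (1+2λ2)ε)² − 4λ1(1+2λ2)) ] / (2(1+2λ2))   otherwise
```

applied coordinate-wise to the IRLS working response.  Seven comparator
penalties run through the same solver: lasso (L1), elastic net, SCAD,
MCP, L1/2 ("half"), L1/2+ridge, and plain LogSum.  Tuning is by
stratified k-fold cross-validation over a decreasing λ path with warm
starts; ties break toward the sparser model.

Also included: the two synthetic grouped-feature scenarios used to
benchmark the method (correlated standard-normal designs with sparse
true coefficients and logit-scale noise), classification metrics with a
rank-based AUC, support-recovery β-sensitivity/β-specificity, a study
runner that emits the benchmark tables, and a loader for GEO-style
series-matrix expression files.

## Worked example

```python
from logsumlr import (PenaltyConfig, scenario1, generate, split, fit,
                      classify, select_support, classification_metrics,
                      support_metrics, predict_proba)

data = generate(scenario1(rho=0.2), seed=7)      # 200 x 1000, 5 true features
train, test = split(data, train_frac=0.7, seed=7)
cfg = PenaltyConfig("LOGSUM_L2", lam=0.02, lam1=0.5, lam2=0.5, eps=0.01)
model = fit(train, cfg)

print("selected features:", select_support(model).tolist())
rep = classification_metrics(test.y, classify(model, test.X),
                             scores=predict_proba(model, test.X))
print(f"test accuracy = {rep.accuracy:.3f}, AUC = {rep.auc:.3f}")
sup = support_metrics(data.true_beta, model.beta)
print(f"beta-sensitivity = {sup.beta_sensitivity:.2f}, "
      f"beta-specificity = {sup.beta_specificity:.4f}")
```

prints

```
selected features: [0, 1, 2, 3, 4]
test accuracy = 1.000, AUC = 1.000
beta-sensitivity = 1.00, beta-specificity = 1.0000
```

i.e. at this penalty level the fit keeps exactly the five true features
(indices 0–4), rejects all 995 noise features, and classifies the
held-out 30% perfectly.  In practice λ, λ1 and ε are tuned by
`cross_validate` / `default_grid` rather than fixed by hand.

A CLI mirrors the library:

```sh
logsumlr simulate --scenario 1 --rho 0.2 --seed 7 --out sim.tsv
logsumlr fit --data sim.tsv --penalty logsum_l2 --lam 0.02 --out coef.tsv
logsumlr cv  --data sim.tsv --penalty l1 --k 10 --seed 7 --out coef_l1.tsv
logsumlr study --config study.cfg --out-dir results/
```

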