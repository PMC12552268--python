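# dplasso

Weighted L1 (lasso) multinomial logistic regression for high-dimensional
variable selection, with per-feature penalty weights derived from how well
each feature separates the outcome classes on its own — *discriminative
power* (DP) weights.

## Who this is for

Analysts selecting a small set of class-associated features from a wide
numeric matrix with a categorical outcome — the motivating case is
classifying cell types (or cell states) from single-cell RNA-seq expression
with `p` genes ≫ `N` cells, where sparse, stable gene panels matter because
selected genes feed follow-up experiments. The same machinery applies to any
multinomial outcome with many numeric predictors.

## The model

For outcome `Y ∈ {1..K}` and predictors `x ∈ R^p`, class probabilities follow
the softmax model

```
π_k(x) = exp(b_k + x'β_k) / Σ_r exp(b_r + x'β_r),   k = 1..K,
```

and the full `K×p` coefficient matrix is estimated by minimizing

```
(1/N) Σ_i −log π_{y_i}(x_i)  +  λ Σ_j Σ_k w_j [ α|β_kj| + (1−α) β_kj²/2 ],
```

a weighted elastic-net multinomial loss (α = 1 gives the weighted lasso).
The weights `w_j` come from univariate class-separation indices computed on
standardized predictors:

| scheme | index | weight |
|---|---|---|
| `DPan` | one-way ANOVA F statistic `F_j` | `w_j = log(1 + 1/F_j)` |
| `DPdb` | Davies–Bouldin-style index `DB_j` | `w_j = DB_j` |
| `DPsi` | silhouette index `S_j ∈ [−1,1]` | `w_j = 1/|S_j|` |

A feature with strong univariate signal gets a small weight and is penalized
less; a feature with no signal gets a large (possibly infinite) weight, and
`w_j = +∞` excludes it outright. Weights are rescaled to sum to the number
of finite-weight features, mirroring the penalty-factor convention of
standard lasso software. Baseline adaptive-lasso weights (`AdaLS` from
per-feature marginal multinomial fits, `AdaRI` from a cross-validated ridge
fit) and the unweighted `Lasso`/`Enet` are provided for comparison.

The solver is block coordinate descent with IRLS working responses, a
guaranteed-descent majorization fallback, warm-started regularization paths,
active-set updates and full KKT verification — coefficients are exactly zero
for unselected features, so "selected" needs no thresholding.

## Worked example

```python
import dplasso as dp

design = dp.SimulationDesign(K=7, p=100, N=1000, rho=0.0, kappa=0.5, seed=7)
data, truth = dp.simulate_dataset(design)          # 10 true features

weights = dp.rescale_weights(dp.compute_dp_weights(data, "AN"))
cv = dp.cross_validate(data, weights, alpha=1.0, nfolds=10, seed=7)
m = dp.selection_metrics(cv.selected_fit.coef, truth)
print(cv.selected_fit.n_selected, m.tpr, round(m.fpr, 3))
```

prints

```
34 1.0 0.267
```

— the ANOVA-weighted lasso recovers all 10 simulated signal features (TPR
1.0) while selecting 34 features in total; the plain lasso on the same data
selects 72. The `examples/` directory has one short script per capability
(weights, fitting, the replicated selection benchmark, and the single-cell
classification protocol), each printing and explaining its output. A thin
CLI mirrors the same steps:

```
dplasso simulate --K 7 --p 100 --N 1000 --rho 0.6 --kappa 0.5 --seed 1 --out-prefix sim
dplasso weights  --input sim.X.tsv --labels sim.y.tsv --method anova --out w.tsv
dplasso fit      --input sim.X.tsv --labels sim.y.tsv --weights w.tsv --seed 1 --out model.json
```

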