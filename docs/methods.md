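# Methods

## Model and estimator

`dplasso` fits the multinomial logistic (softmax) model with the full
K-class parameterization: one intercept and one coefficient vector per
class, no reference category. The estimator minimizes the mean negative
log-likelihood plus a weighted elastic-net penalty,

```
(1/N) Σ_i −log π_{y_i}(x_i) + λ Σ_j Σ_k w_j [ α|β_kj| + (1−α) β_kj²/2 ],
```

with per-feature penalty factors `w_j ≥ 0` shared across classes and
unpenalized intercepts. `w_j = 0` leaves a feature unpenalized (it is part
of every model on the path); `w_j = +∞` excludes it (coefficients pinned at
zero). This is the penalty-factor semantics of mainstream lasso software.

**Identifiability.** The softmax is invariant to adding a constant to all
intercepts, or to a feature's coefficients across classes. Intercepts are
reported mean-centered. For a *penalized* column the L1 term itself pins the
shift: the optimum balances coefficient signs within the column
(a weighted-median condition), and forcing a mean-zero column instead would
increase the objective and break agreement with any exact minimizer of the
loss — so penalized columns are reported at the optimum, not re-centered.
Fully unpenalized columns (`w_j = 0`, or the whole fit at `λ = 0`) are
mean-centered; pure-ridge columns are mean-zero at the optimum
automatically. One residual degeneracy is inherent to the model: for *even*
K the L1 penalty is exactly flat along part of the shift direction (the sum
of absolute deviations of an even-sized set is constant between its two
middle order statistics), so coefficients are then unique only up to that
interval; class contrasts, fitted probabilities, objective values and the
selected support are unaffected.

## Discriminative-power weights

All indices are computed per feature on standardized predictors
(subtract the mean, divide by the sample standard deviation, ddof = 1 — the
indices themselves are affine-invariant, so this affects only the stored
transform):

* **ANOVA (`AN`)** — the one-way F statistic,
  `F_j = [(N−K)/(K−1)] · between-class SS / within-class SS`;
  weight `w_j = log(1 + 1/F_j)`. The log transform tames the very large F
  values that standardized high-signal features produce. `F = ∞` (zero
  within-class variance) gives `w = 0` (unpenalized); `F = 0` (identical
  class means) excludes the feature.
* **Davies–Bouldin-style (`DB`)** — per-class dispersion
  `δ_k = sqrt(Σ_{i∈k}(x_ij − x̄_k)²)` (root of the raw sum of squares, *not*
  the classic per-size-normalized root mean square — a deliberate choice,
  kept as the primary definition; `normalized=True` switches to the classic
  form, which differs only by a constant factor when classes are balanced),
  class distance `|x̄_r − x̄_l|`, and
  `DB_j = (1/K) Σ_k max_{l≠k} (δ_k+δ_l)/|x̄_k−x̄_l|`. Used directly as the
  weight; coinciding class means give `+∞` (excluded).
* **Silhouette (`SI`)** — mean over observations of
  `(Δ_i − δ_i)/max(δ_i, Δ_i)` where `δ_i` is the mean absolute distance to
  the other members of the observation's class (divisor `n_k − 1`) and
  `Δ_i` the minimum over other classes of the mean absolute distance; the
  0/0 case is set to 0, the standard convention. Weight `w_j = 1/|S_j|`;
  `S_j = 0` excludes the feature. The per-feature computation uses
  class-sorted prefix sums, O(N log N + NK) per feature, so p = 10,000 is
  routine.

After exclusion, finite weights are rescaled once, explicitly, to sum to the
number of finite-weight features (the same normalization mainstream software
applies internally to penalty factors; applying it once keeps fits
identical while making reported weights comparable across schemes).

**Baselines.** `AdaLS` fits an unpenalized intercept+slope multinomial model
per feature (L-BFGS on the exact likelihood, symmetric mean-centered
parameterization) and uses `w_j = 1 / mean_k |slope_kj|`. `AdaRI` fits a
ridge multinomial model on all predictors jointly, with the ridge strength
chosen by 10-fold CV over a 10-point grid anchored the way mainstream
software anchors its ridge grids (entry point computed as if the mixing
parameter were 0.001, so even the weakest grid point shrinks substantially),
and uses `w_j = 1 / mean_k |β̂_kj|` on the original predictor scale. Both are
deliberately simple readings of "adaptive weights from marginal / ridge
fits"; no exponent hyperparameter is applied (γ = 1).

## Optimizer

Block coordinate descent over class blocks. For each class the likelihood is
replaced by a weighted least-squares surrogate from the current
probabilities (IRLS working response, curvature `π(1−π)` floored at 1e-5);
cyclic coordinate descent with elastic-net soft-thresholding solves the
surrogate over the active set, with sweeps restricted to the currently
nonzero working set between full admission sweeps. The IRLS surrogate is not
a global majorizer, so each full cycle is objective-checked: if the
penalized objective rose, the cycle is rolled back and redone with the
uniform curvature bound 1/4, which *is* a majorizer — the reported objective
is therefore non-increasing across outer iterations. Convergence is declared
when the largest curvature-weighted squared coefficient change in a full
cycle falls below the tolerance (default 1e-7; the oracle-comparison tests
use 1e-13). After convergence at each λ the full gradient is computed and
the KKT conditions are verified over all features; violators join the active
set and the fit resumes. The iteration budget is 100,000 coordinate sweeps.

Predictors are standardized internally by default and coefficients returned
on the original scale; selection is scale-invariant either way. The λ grid
is log-spaced over 100 values from `λ_max` (the smallest λ whose
intercept-plus-unpenalized-features fit satisfies the zero-coefficient
subgradient condition) down to `λ_max · r`, with `r = 0.01` when `p > N` and
`1e-4` otherwise. Internally generated paths stop early once the deviance
explained exceeds 0.999 of the null deviance or improves by less than 1e-5
of it per step — conventional path-stopping rules.

## Cross-validation

Stratified K-fold (default 10), fold assignment from a single explicit seed
and recorded in the result. The full-data fit and all fold fits advance in
lockstep down the shared grid; each fold is scored by mean multinomial
deviance on its held-out cells. Because held-out deviance along the path
rises steeply once fits overfit, the descent stops after the mean CV
deviance has failed to improve for 10 consecutive grid points past its
running minimum; grid points beyond that cannot be selected (verified to
reproduce full-grid selections exactly on p=100 and p=1000 instances).
`lambda_min` (the default rule) minimizes mean CV deviance; `lambda_1se` is
the largest λ within one standard error (fold SD/√folds) of the minimum.
For the elastic net, α is selected on the grid {0.1, …, 1.0} by the same CV.

## Synthetic data

The simulator emulates the study conditions of the variable-selection
benchmark: predictors are i.i.d. `MVN(0, Σ)` with Σ block-diagonal in
identical 20×20 equicorrelation blocks (`σ² = 0.5` on the diagonal, `ρσ²`
within a block, 0 across blocks; ρ ∈ [0,1), smallest eigenvalue
`σ²(1−ρ) > 0`), sampled block-wise from one 20×20 Cholesky factor so
p = 10,000 needs no dense factorization. Outcomes are multinomial draws from
the softmax with zero intercepts and a sparse true coefficient matrix:
under structure 1, classes 2..K carry the sign pattern
`(κ, −κ, κ, κ, −κ, κ)` on features 1–10; under structure 2, class 3 (and
class 6 for K = 7) instead carries `−κ` on features 11–20 with all its other
entries zero. Built-in patterns exist for K ∈ {2, 4, 7}; defaults are
κ = 0.5, σ² = 0.5 — the benchmark's stated values. Class imbalance arises
only stochastically (intercepts are zero).

The single-cell fixture generates a TPM-scale cells-by-genes matrix:
log-normal baseline expression, class-specific multiplicative fold changes
(`effect**s` with a random sign pattern s, each informative gene forced to
distinguish at least two classes), log-normal cell-level noise, and per-cell
closure to 1e6. It deliberately omits counting noise, dropout and library
-size variation, so passing tests demonstrate the selection and protocol
machinery, not robustness to those artifacts of real scRNA-seq data. The
gene filter keeps genes exceeding 1 TPM (strictly) in at least
`ceil(0.25 · cells)` cells; expression is modeled as `log(TPM+1)` by default
(switchable off). Input matrices are declared TPM by the caller; conversion
from raw counts is out of scope.

## Evaluation protocol

Selection metrics use exact zeros of the fitted coefficient matrix: a
feature is selected iff any class coefficient is nonzero; TPR and FPR are
the selected fractions of true and null features. The repeated
classification protocol runs outer stratified K-fold CV (default 10×10 = 100
train/test pairs; the examples and tests use smaller geometries), computing
penalty weights, standardization and the inner CV for λ (and α) on each
outer training set only. Replicate r of the study runner uses dataset seed
`master_seed + r`, so partial reruns are reproducible.

## Problem sizes used in the shipped checks

The test suite reruns the study at reduced replicate counts (2–5 replicates
per design point; p = 10,000 with 4 CV folds and a 40-point grid), and
`scripts/acceptance.py` uses 20 replicates at p = 100 and 10 at p = 1000.
These sizes are the package's own choice of a desk-scale replication of
the full benchmark, whose reference configuration averages 100 replicates
per design point.

## Known limitations

* SCAD/MCP penalties, the relaxed lasso, pairwise class-difference penalties
  and multivariate (correlation-adjusted) versions of the DP indices are out
  of scope.
* The DP indices are univariate by design: a feature informative only in
  combination with others receives a large weight. This is intended (it is
  what makes the method robust when p ≫ N) but means purely interactive
  signals are penalized heavily.
* For even K, individual coefficient values are identified only up to the
  flat interval of the penalty along the class-shift direction (contrasts
  and probabilities are unique).
* At high within-block correlation the marginal effects of true features and
  their null block-mates are nearly identical, so *all* marginal weighting
  schemes (DP and adaptive baselines alike) assign them similar weights; the
  multivariate fit then resolves the support. Selection behavior in that
  regime is driven by the fit, not the weights.
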