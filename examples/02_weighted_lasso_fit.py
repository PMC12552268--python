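"""Fit the weighted multinomial lasso with cross-validated penalty strength.

Simulates one structure-1 dataset (K=7 classes, p=100 features of which the
first 10 carry signal), computes ANOVA penalty weights, selects lambda by
10-fold cross-validation and reports what was selected.
"""

import numpy as np

import dplasso as dp

design = dp.SimulationDesign(K=7, p=100, N=1000, rho=0.0, kappa=0.5, seed=7)
data, truth = dp.simulate_dataset(design)

weights = dp.rescale_weights(dp.compute_dp_weights(data, "AN"))
cv = dp.cross_validate(data, weights, alpha=1.0, nfolds=10, seed=7)
fit = cv.selected_fit
m = dp.selection_metrics(fit.coef, truth)

print(f"lambda grid: {cv.path.lambda_max:.4f} ... {cv.lambdas[-1]:.5f}")
print(f"selected lambda (CV-min rule): {cv.lambda_min:.4f}")
print(f"features selected: {fit.n_selected} of {data.p}")
print(f"true-positive rate: {m.tpr:.2f}   false-positive rate: {m.fpr:.3f}")
pred = dp.predict_classes(fit, data.X)
print(f"training misclassification: {dp.misclassification_rate(pred, data.y):.3f}")
print(
    "\nAll 10 simulated signal features should be recovered (TPR 1.0) with a"
    "\nmodest number of false positives; the plain lasso on the same data"
    "\nselects roughly twice as many features."
)
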