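"""Compute discriminative-power penalty weights for a labeled matrix.

Builds a small three-class dataset with two informative features, scores
every feature with the ANOVA F statistic, the Davies-Bouldin-style index and
the silhouette index, and prints the derived penalty weights. Low weight =
strong univariate class signal = penalized less in the weighted lasso.
"""

import numpy as np

import dplasso as dp

rng = np.random.default_rng(0)
N, K = 120, 3
y = np.repeat(np.arange(K), N // K)
X = rng.standard_normal((N, 6))
X[:, 0] += 2.0 * (y == 0)          # strong shift for class 1
X[:, 1] -= 2.5 * (y == 2)          # strong negative shift for class 3
data = dp.LabeledDataset(X=X, y=y)

print(f"{'feature':>8} {'F':>8} {'w_AN':>8} {'DB':>8} {'w_DB':>8} {'S':>8} {'w_Si':>8}")
wan = dp.rescale_weights(dp.compute_dp_weights(data, "AN"))
wdb = dp.rescale_weights(dp.compute_dp_weights(data, "DB"))
wsi = dp.rescale_weights(dp.compute_dp_weights(data, "SI"))
for j in range(data.p):
    print(
        f"{data.feature_ids[j]:>8} {wan.raw_index[j]:8.2f} {wan.weight[j]:8.3f}"
        f" {wdb.raw_index[j]:8.2f} {wdb.weight[j]:8.3f}"
        f" {wsi.raw_index[j]:8.3f} {wsi.weight[j]:8.3f}"
    )
print(
    "\nFeatures f1 and f2 carry the class signal, so their F statistics are"
    "\nlarge (and silhouettes positive) and their penalty weights are the"
    "\nsmallest of the six; the weighted lasso will keep them preferentially."
)
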