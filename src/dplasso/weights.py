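"""Discriminative-power (DP) indices and penalty weights.

Each predictor is scored by how well it separates the K outcome classes on
its own: large between-class distances relative to within-class spread mean
high discriminative power and therefore a *small* L1 penalty weight. Three
indices are provided:

* ``anova_f`` — the one-way ANOVA F statistic of the predictor across
  classes; transformed to a weight via ``w = log(1 + 1/F)``.
* ``db_index`` — a Davies–Bouldin-style index whose per-class dispersion is
  the root of the *sum* of squared deviations from the class mean (not the
  root mean square of the classic index); used directly as the weight.
  ``normalized=True`` switches to the classic per-class-size normalization.
* ``silhouette_index`` — the mean silhouette width of the predictor with
  absolute-value distances; the weight is ``1/|S|``.

Weights of ``+inf`` mark features that carry no univariate class signal at
all; such features are excluded from the penalized fit (coefficients forced
to zero), the penalty-factor-infinity convention of standard lasso software.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dataset import LabeledDataset

__all__ = [
    "DPWeightSet",
    "standardize",
    "anova_f",
    "db_index",
    "silhouette_index",
    "compute_dp_weights",
    "rescale_weights",
]

logger = logging.getLogger(__name__)

#: recognised weighting schemes (DP indices plus the baselines computed in
#: :mod:`dplasso.benchmark` and the unit-weight plain lasso)
METHODS = ("AN", "DB", "SI", "ADA_LS", "ADA_RI", "UNIT")


@dataclass
class DPWeightSet:
    """Per-feature raw index values and derived L1 penalty weights.

    ``excluded[j]`` is True exactly when ``weight[j] == +inf``; excluded
    features never enter the penalized fit. ``rescaled`` records whether the
    finite weights have been rescaled to sum to their own count.
    """

    method: str
    raw_index: np.ndarray
    weight: np.ndarray
    excluded: np.ndarray = field(default=None)
    rescaled: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown weight method {self.method!r}")
        self.raw_index = np.asarray(self.raw_index, dtype=np.float64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if self.excluded is None:
            self.excluded = np.isinf(self.weight)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if np.any(self.weight < 0):
            raise ValueError("penalty weights must be non-negative")
        if not np.array_equal(self.excluded, np.isinf(self.weight)):
            raise ValueError("excluded mask must flag exactly the +inf weights")

    @property
    def p(self) -> int:
        return self.weight.shape[0]

    @property
    def n_finite(self) -> int:
        return int((~self.excluded).sum())

    @classmethod
    def unit(cls, p: int) -> "DPWeightSet":
        """Unit weights: the ordinary (unweighted) lasso."""
        return cls("UNIT", np.ones(p), np.ones(p))


def standardize(
    X: np.ndarray, feature_ids: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center each column to mean 0 and scale to sample sd 1 (ddof=1).

    Returns ``(X_standardized, mean, sd)`` so the same transform can be
    replayed on new data. Constant columns are an error: a predictor with
    zero variance has no scale and no discriminative content.
    """
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd <= 0)
    if bad.size:
        ids = feature_ids or [f"f{j + 1}" for j in range(X.shape[1])]
        raise ValueError(
            "constant column(s) cannot be standardized: "
            + ", ".join(ids[j] for j in bad[:10])
        )
    return (X - mean) / sd, mean, sd


def _group_stats(xj: np.ndarray, y: np.ndarray):
    """Class counts, class means and within-class sums of squares."""
    K = int(y.max()) + 1
    n_k = np.bincount(y, minlength=K).astype(np.float64)
    sums = np.bincount(y, weights=xj, minlength=K)
    means = sums / n_k
    ss_within = np.bincount(y, weights=(xj - means[y]) ** 2, minlength=K)
    return n_k, means, ss_within


def anova_f(xj: np.ndarray, y: np.ndarray) -> float:
    """One-way ANOVA F statistic of a single predictor across classes.

    ``F = [(N-K)/(K-1)] * between-SS / within-SS``. Returns ``+inf`` when
    the within-class sum of squares is zero but class means differ, and 0
    when all class means coincide.
    """
    xj = np.asarray(xj, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    N = xj.shape[0]
    n_k, means, ss_within = _group_stats(xj, y)
    K = n_k.shape[0]
    if N <= K:
        raise ValueError(f"need N > K for the F statistic (N={N}, K={K})")
    ss_between = float(np.sum(n_k * (means - xj.mean()) ** 2))
    sw = float(ss_within.sum())
    if ss_between <= 0.0:
        return 0.0
    if sw == 0.0:
        return np.inf
    return (N - K) / (K - 1) * ss_between / sw


def db_index(xj: np.ndarray, y: np.ndarray, normalized: bool = False) -> float:
    """Davies–Bouldin-style index of a single predictor.

    Per-class dispersion is ``sqrt(sum_i (x_ij - mean_k)^2)`` (root of the
    raw sum of squares); ``normalized=True`` divides the sum by ``n_k``
    first, recovering the classic root-mean-square dispersion. Distance
    between classes is the absolute difference of class means. The index is
    the average over classes of the worst-case (dispersion sum)/(mean
    distance) ratio, and is ``+inf`` when two class means coincide exactly.
    """
    xj = np.asarray(xj, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    n_k, means, ss_within = _group_stats(xj, y)
    K = n_k.shape[0]
    if normalized:
        delta = np.sqrt(ss_within / n_k)
    else:
        delta = np.sqrt(ss_within)
    total = 0.0
    for k in range(K):
        best = 0.0
        for l in range(K):
            if l == k:
                continue
            gap = abs(means[k] - means[l])
            num = delta[k] + delta[l]
            if gap == 0.0:
                return np.inf
            best = max(best, num / gap)
        total += best
    return total / K


@njit(cache=True)
def _silhouette_columns(X, y, n_k, K):  # pragma: no cover - numba
    """Mean silhouette width per column, absolute-value distance.

    For each column the per-class sorted values and prefix sums give every
    sum of |x_i - x_h| over a class in O(log n) instead of O(n), so the
    whole matrix costs O(p * (N log N + N K)).
    """
    N, p = X.shape
    out = np.empty(p)
    for j in range(p):
        col = X[:, j]
        # per-class sorted values + prefix sums
        sorted_vals = []
        prefixes = []
        for k in range(K):
            vals = np.empty(n_k[k])
            c = 0
            for i in range(N):
                if y[i] == k:
                    vals[c] = col[i]
                    c += 1
            vals = np.sort(vals)
            pref = np.empty(n_k[k] + 1)
            pref[0] = 0.0
            for t in range(n_k[k]):
                pref[t + 1] = pref[t] + vals[t]
            sorted_vals.append(vals)
            prefixes.append(pref)
        s_sum = 0.0
        for i in range(N):
            xi = col[i]
            yi = y[i]
            delta = 0.0
            big_delta = np.inf
            for k in range(K):
                vals = sorted_vals[k]
                pref = prefixes[k]
                nk = n_k[k]
                pos = np.searchsorted(vals, xi)
                tot = pos * xi - pref[pos] + (pref[nk] - pref[pos]) - (nk - pos) * xi
                if k == yi:
                    delta = tot / (nk - 1)  # excludes the zero self-distance
                else:
                    m = tot / nk
                    if m < big_delta:
                        big_delta = m
            denom = max(delta, big_delta)
            if denom > 0.0:
                s_sum += (big_delta - delta) / denom
        out[j] = s_sum / N
    return out


def silhouette_index(xj: np.ndarray, y: np.ndarray) -> float:
    """Mean silhouette width of a single predictor in [-1, 1].

    Within-class distance of observation i is the average absolute distance
    to the other members of its class (divisor ``n_k - 1``); between-class
    distance is the minimum over other classes of the mean absolute
    distance. Observations with both distances zero contribute width 0.
    """
    xj = np.ascontiguousarray(np.asarray(xj, dtype=np.float64).reshape(-1, 1))
    y = np.asarray(y, dtype=np.int64)
    K = int(y.max()) + 1
    n_k = np.bincount(y, minlength=K)
    if n_k.min() < 2:
        raise ValueError("silhouette needs every class to have n_k >= 2")
    return float(_silhouette_columns(xj, y, n_k, K)[0])


def _all_indices(data: LabeledDataset, method: str) -> np.ndarray:
    Xs, _, _ = standardize(data.X, data.feature_ids)
    if method == "AN":
        return np.array([anova_f(Xs[:, j], data.y) for j in range(data.p)])
    if method == "DB":
        return np.array([db_index(Xs[:, j], data.y) for j in range(data.p)])
    if method == "SI":
        return _silhouette_columns(
            np.asfortranarray(Xs), data.y, data.class_counts, data.K
        )
    raise ValueError(f"unknown DP method {method!r}")


def compute_dp_weights(
    data: LabeledDataset, method: str, max_weight: float | None = None
) -> DPWeightSet:
    """Compute raw DP indices on standardized predictors and map to weights.

    Transforms: ``AN``: ``w = log(1 + 1/F)`` (F=inf -> w=0 unpenalized,
    F=0 -> excluded); ``DB``: ``w = DB`` (DB=inf -> excluded); ``SI``:
    ``w = 1/|S|`` (S=0 -> excluded). ``max_weight`` caps all weights at a
    finite ceiling instead of excluding zero-signal features (off by
    default: exclusion keeps the objective well defined without an extra
    tuning constant).
    """
    method = method.upper()
    raw = _all_indices(data, method)
    with np.errstate(divide="ignore"):
        if method == "AN":
            w = np.log1p(1.0 / raw)  # log1p(1/0)=inf, log1p(1/inf)=0
        elif method == "DB":
            w = raw.copy()
        else:
            w = 1.0 / np.abs(raw)
    if max_weight is not None:
        if max_weight <= 0 or not np.isfinite(max_weight):
            raise ValueError("max_weight must be a positive finite number")
        w = np.minimum(w, max_weight)
    ws = DPWeightSet(method=method, raw_index=raw, weight=w)
    if ws.n_finite == 0:
        raise ValueError(f"all {data.p} features excluded under method {method}")
    return ws


def rescale_weights(w: DPWeightSet) -> DPWeightSet:
    """Rescale finite weights to sum to the number of finite-weight features.

    Mirrors the internal penalty-factor rescaling of standard lasso software
    (factors rescaled to sum to p), applied over non-excluded features only.
    An all-zero finite weight vector (everything unpenalized) is returned
    unchanged with a warning.
    """
    finite = ~w.excluded
    if not finite.any():
        raise ValueError("no finite weights to rescale")
    total = w.weight[finite].sum()
    if total == 0.0:
        logger.warning(
            "all finite penalty weights are zero (fully unpenalized); "
            "rescaling skipped"
        )
        return DPWeightSet(w.method, w.raw_index.copy(), w.weight.copy(), rescaled=False)
    new = w.weight.copy()
    new[finite] *= finite.sum() / total
    return DPWeightSet(w.method, w.raw_index.copy(), new, rescaled=True)
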