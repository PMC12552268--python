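"""Weighted elastic-net multinomial logistic regression.

Minimizes, over intercepts ``b_k`` and the full K x p coefficient matrix,

    (1/N) * sum_i -log pi_{y_i}(x_i)
        + lambda * sum_j sum_k w_j * [ alpha*|beta_kj| + (1-alpha)/2 * beta_kj^2 ]

where ``pi_k = softmax_k(b_k + x' beta_k)`` uses the full K-class
parameterization and ``w_j`` are per-feature penalty factors (the
discriminative-power weights or any adaptive-lasso weights). Intercepts are
never penalized. Features with ``w_j = +inf`` are excluded (coefficients
pinned at zero); features with ``w_j = 0`` are unpenalized and belong to
every model on the path.

The optimizer is block majorization-minimization over class blocks with
cyclic coordinate descent inside each block, warm starts along a decreasing
log-spaced lambda grid, active-set iteration, and full KKT verification at
each lambda. By default predictors are standardized internally and
coefficients are returned on the original scale (selection is unaffected).

Identifiability: the softmax is invariant to a common shift of the
intercepts or of any coefficient column across classes. Intercepts are
reported mean-centered. Penalized coefficient columns need no convention —
the penalty itself pins the shift at its optimum — while fully unpenalized
columns (``w_j = 0`` or ``lambda = 0``) are mean-centered after fitting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._cd import cd_active
from .dataset import LabeledDataset
from .weights import DPWeightSet

__all__ = [
    "MultinomialFit",
    "RegPath",
    "CVResult",
    "softmax_probabilities",
    "penalized_objective",
    "lambda_max",
    "fit_at_lambda",
    "fit_path",
    "cross_validate",
    "predict_classes",
    "misclassification_rate",
]

logger = logging.getLogger(__name__)

MAX_PASSES = 100_000
TOL = 1e-7


def _softmax(eta: np.ndarray) -> np.ndarray:
    z = eta - eta.max(axis=1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=1, keepdims=True)
    return z


@dataclass
class MultinomialFit:
    """One fitted model at a single penalty strength.

    ``intercepts`` and ``coef`` are on the original predictor scale, so
    ``eta = intercepts + X @ coef.T`` directly. ``coef[k, j] == 0`` exactly
    for excluded features and unselected features.
    """

    intercepts: np.ndarray  # (K,)
    coef: np.ndarray        # (K, p)
    lambda_: float
    alpha: float
    weightset: DPWeightSet | None = None
    n_iter: int = 0
    converged: bool = True
    class_labels: list = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.coef.shape[0]

    @property
    def p(self) -> int:
        return self.coef.shape[1]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.p:
            raise ValueError(f"X has {X.shape[1]} columns, model expects {self.p}")
        return self.intercepts + X @ self.coef.T

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.linear_predictor(X))

    @property
    def selected(self) -> np.ndarray:
        """Boolean mask: features with any exactly-nonzero coefficient."""
        return np.abs(self.coef).sum(axis=0) != 0

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


@dataclass
class RegPath:
    """Fits along a decreasing lambda grid (warm-started)."""

    lambdas: np.ndarray
    fits: list[MultinomialFit]
    lambda_max: float

    def fit_at(self, lam: float) -> MultinomialFit:
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return self.fits[i]

    @property
    def n_selected(self) -> np.ndarray:
        return np.array([f.n_selected for f in self.fits])


@dataclass
class CVResult:
    """Cross-validated penalty selection."""

    nfolds: int
    fold_assignment: np.ndarray
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    sd_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float
    selection_rule: str
    selected_fit: MultinomialFit
    path: RegPath

    @property
    def selected_lambda(self) -> float:
        return self.lambda_min if self.selection_rule == "min" else self.lambda_1se


def softmax_probabilities(fit: MultinomialFit, x: np.ndarray) -> np.ndarray:
    """Class probabilities for one sample (overflow-safe softmax)."""
    return fit.predict_proba(np.atleast_2d(x))[0]


def multinomial_deviance(fit: MultinomialFit, X: np.ndarray, y: np.ndarray) -> float:
    """Mean multinomial deviance ``(2/n) * sum_i -log pi_{y_i}``."""
    prob = fit.predict_proba(X)
    picked = np.clip(prob[np.arange(len(y)), y], 1e-300, None)
    return float(-2.0 * np.mean(np.log(picked)))


def penalized_objective(
    fit: MultinomialFit, data: LabeledDataset, weights: DPWeightSet
) -> float:
    """Value of the penalized loss at the fit, on the scale of ``data.X``."""
    dev = 0.5 * multinomial_deviance(fit, data.X, data.y)
    finite = ~weights.excluded
    wj = weights.weight[finite]
    bk = fit.coef[:, finite]
    pen = np.sum(wj * (fit.alpha * np.abs(bk) + 0.5 * (1 - fit.alpha) * bk**2))
    return dev + fit.lambda_ * float(pen)


class _Problem:
    """Internal fitting state on the (optionally standardized) scale."""

    def __init__(
        self,
        data: LabeledDataset,
        weights: DPWeightSet,
        alpha: float,
        standardize: bool = True,
    ):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if weights.p != data.p:
            raise ValueError("weight vector length does not match p")
        self.data = data
        self.weights = weights
        self.alpha = alpha
        self.standardize = standardize
        X = data.X
        if standardize:
            self.x_mean = X.mean(axis=0)
            sd = X.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                raise ValueError("constant columns cannot be standardized")
            self.x_sd = sd
            Xw = (X - self.x_mean) / sd
        else:
            self.x_mean = np.zeros(data.p)
            self.x_sd = np.ones(data.p)
            Xw = X
        self.X = np.asfortranarray(Xw)
        self.colsq = (self.X**2).mean(axis=0)
        self.y = data.y.astype(np.int64)
        self.N, self.p = self.X.shape
        self.K = data.K
        self.included = ~weights.excluded
        self.w = np.where(self.included, weights.weight, 0.0)  # kernel-safe
        self.free = self.included & (self.w == 0.0)  # always-active features
        self.Y = np.zeros((self.N, self.K))
        self.Y[np.arange(self.N), self.y] = 1.0
        # state
        counts = np.bincount(self.y, minlength=self.K).astype(float)
        freq = np.clip(counts / self.N, 1e-10, None)
        self.b = np.log(freq) - np.log(freq).mean()
        self.beta = np.zeros((self.K, self.p))
        self.eta = np.tile(self.b, (self.N, 1))
        self.active = self.free.copy()
        self.passes_used = 0

    def gradient(self) -> np.ndarray:
        """(p, K) gradient of the unpenalized loss at the current state."""
        P = _softmax(self.eta)
        return self.X.T @ (P - self.Y) / self.N

    def solve(self, lam: float, tol: float = TOL, max_passes: int = MAX_PASSES) -> bool:
        """Fit at one lambda from the current warm state; returns converged."""
        converged = True
        for _ in range(100):  # active-set / KKT rounds
            idx = np.flatnonzero(self.active)
            npass, conv = cd_active(
                self.X, self.y, idx, self.w, lam, self.alpha,
                self.beta, self.b, self.eta, self.colsq, tol,
                max_passes - self.passes_used,
            )
            self.passes_used += npass
            converged = bool(conv)
            if not converged:
                warnings.warn(
                    f"coordinate descent hit the pass budget at lambda={lam:.4g}",
                    RuntimeWarning,
                )
                break
            G = self.gradient()
            thr = lam * self.alpha * self.w * (1 + 1e-6) + 1e-12
            viol = (
                self.included
                & ~self.active
                & (np.abs(G).max(axis=1) > thr)
            )
            if not viol.any():
                break
            self.active |= viol
        self.active |= self.beta.any(axis=0)
        return converged

    def snapshot(self, lam: float, converged: bool) -> MultinomialFit:
        """Back-transform to the original scale and package."""
        coef = (self.beta / self.x_sd).copy()
        b = self.b - coef @ self.x_mean
        # center the unpenalized directions (softmax-invariant shifts)
        free_cols = self.included.copy() if lam == 0.0 else self.free
        coef[:, free_cols] -= coef[:, free_cols].mean(axis=0, keepdims=True)
        b = b - b.mean()
        return MultinomialFit(
            intercepts=b,
            coef=coef,
            lambda_=lam,
            alpha=self.alpha,
            weightset=self.weights,
            n_iter=self.passes_used,
            converged=converged,
            class_labels=list(self.data.class_labels),
        )


def lambda_max(
    data: LabeledDataset, weights: DPWeightSet, alpha: float = 1.0
) -> float:
    """Smallest lambda at which every penalized coefficient is zero.

    Computed from the subgradient condition at the null fit (intercepts plus
    any unpenalized ``w_j = 0`` features): ``max_{j,k} |g_kj| / (alpha*w_j)``
    over features with finite positive weight.
    """
    if alpha <= 0.0:
        raise ValueError("lambda_max requires alpha > 0")
    prob = _Problem(data, weights, alpha)
    return _lambda_max_from(prob)


def _lambda_max_from(prob: _Problem) -> float:
    pen = prob.included & (prob.w > 0)
    if not pen.any():
        raise ValueError("no penalized features: lambda_max is undefined")
    if prob.free.any():
        prob.solve(lam=max(1.0, 1e3))  # unpenalized features only
    g = np.abs(prob.gradient()).max(axis=1)
    return float((g[pen] / (prob.alpha * prob.w[pen])).max())


def fit_at_lambda(
    data: LabeledDataset,
    weights: DPWeightSet,
    lambda_: float,
    alpha: float = 1.0,
    standardize: bool = True,
    tol: float = TOL,
    max_passes: int = MAX_PASSES,
) -> MultinomialFit:
    """Cold-start fit of the penalized model at one lambda."""
    if lambda_ < 0:
        raise ValueError("lambda must be non-negative")
    prob = _Problem(data, weights, alpha, standardize=standardize)
    if lambda_ == 0.0 or alpha == 0.0:
        prob.active = prob.included.copy()
    converged = prob.solve(lambda_, tol=tol, max_passes=max_passes)
    return prob.snapshot(lambda_, converged)


def _default_min_ratio(N: int, p: int) -> float:
    return 0.01 if p > N else 1e-4


def fit_path(
    data: LabeledDataset,
    weights: DPWeightSet,
    alpha: float = 1.0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    lambdas: np.ndarray | None = None,
    standardize: bool = True,
    tol: float = TOL,
    max_passes: int = MAX_PASSES,
    dev_ratio_max: float = 0.999,
    fdev: float = 1e-5,
) -> RegPath:
    """Warm-started regularization path on a decreasing log-spaced grid.

    When the grid is generated internally the path stops early once the
    fraction of null deviance explained exceeds ``dev_ratio_max`` or
    improves by less than ``fdev`` between consecutive lambdas (the
    convention of standard lasso path software); an explicitly supplied
    ``lambdas`` grid is fitted in full.
    """
    prob = _Problem(data, weights, alpha, standardize=standardize)
    lam_max = _lambda_max_from(prob)
    explicit = lambdas is not None
    if explicit:
        grid = np.sort(np.asarray(lambdas, dtype=float))[::-1]
    else:
        if n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")
        ratio = lambda_min_ratio or _default_min_ratio(data.N, data.p)
        grid = np.geomspace(lam_max, lam_max * ratio, n_lambda)
    fits: list[MultinomialFit] = []
    used: list[float] = []
    nulldev = None
    prev_dev = None
    for lam in grid:
        prob.passes_used = 0
        converged = prob.solve(lam, tol=tol, max_passes=max_passes)
        fits.append(prob.snapshot(lam, converged))
        used.append(lam)
        # early stopping on the deviance trajectory (generated grids only)
        P = _softmax(prob.eta)
        picked = np.clip(P[np.arange(prob.N), prob.y], 1e-300, None)
        dev = float(-2.0 * np.mean(np.log(picked)))
        if nulldev is None:
            nulldev = max(dev, 1e-12)
        if not explicit and prev_dev is not None and nulldev > 0:
            if dev < (1.0 - dev_ratio_max) * nulldev:
                break
            if (prev_dev - dev) / nulldev < fdev and fits[-1].n_selected > 0:
                break
        prev_dev = dev
    return RegPath(lambdas=np.array(used), fits=fits, lambda_max=lam_max)


def _stratified_folds(y: np.ndarray, nfolds: int, seed: int) -> np.ndarray:
    from sklearn.model_selection import StratifiedKFold

    counts = np.bincount(y)
    nfolds_eff = min(nfolds, int(counts[counts > 0].min()))
    if nfolds_eff < nfolds:
        warnings.warn(
            f"reducing folds from {nfolds} to {nfolds_eff}: smallest class has "
            f"{nfolds_eff} members",
            RuntimeWarning,
        )
    skf = StratifiedKFold(n_splits=nfolds_eff, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=np.int64)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = f
    return assignment


def cross_validate(
    data: LabeledDataset,
    weights: DPWeightSet,
    alpha: float = 1.0,
    nfolds: int = 10,
    rule: str = "min",
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    standardize: bool = True,
    tol: float = TOL,
    patience: int = 10,
) -> CVResult:
    """Stratified K-fold cross-validation of the penalty strength.

    The full-data fit and every training-fold fit advance in lockstep down
    the shared lambda grid (warm starts everywhere); each fold is scored by
    mean multinomial deviance on its held-out samples. Because held-out
    deviance along a lasso path rises steeply once the fit overfits, the
    descent down the grid stops after the mean CV deviance has failed to
    improve for ``patience`` consecutive grid points past the running
    minimum — the remaining, smaller lambdas cannot be selected.

    ``lambda_min`` minimizes the mean CV deviance; ``lambda_1se`` is the
    largest lambda whose mean deviance is within one standard error (fold sd
    / sqrt(nfolds)) of the minimum. The returned selected fit is the
    full-data fit at the chosen lambda.
    """
    if nfolds < 2:
        raise ValueError("nfolds must be >= 2")
    if rule not in ("min", "1se"):
        raise ValueError("rule must be 'min' or '1se'")
    full = _Problem(data, weights, alpha, standardize=standardize)
    lam_max = _lambda_max_from(full)
    ratio = lambda_min_ratio or _default_min_ratio(data.N, data.p)
    grid_all = np.geomspace(lam_max, lam_max * ratio, n_lambda)
    assignment = _stratified_folds(data.y, nfolds, seed)
    nfolds_eff = assignment.max() + 1
    folds = []
    for f in range(nfolds_eff):
        train = np.flatnonzero(assignment != f)
        test = np.flatnonzero(assignment == f)
        dtrain = data.subset(train)
        if np.bincount(dtrain.y, minlength=data.K).min() == 0:
            warnings.warn(
                f"fold {f}: a class is absent from the training split",
                RuntimeWarning,
            )
        folds.append(
            (_Problem(dtrain, weights, alpha, standardize=standardize),
             data.X[test], data.y[test])
        )
    fits: list[MultinomialFit] = []
    dev_rows = []
    mean_so_far: list[float] = []
    for lam in grid_all:
        full.passes_used = 0
        conv = full.solve(lam, tol=tol)
        fits.append(full.snapshot(lam, conv))
        row = np.empty(nfolds_eff)
        for f, (prob, Xte, yte) in enumerate(folds):
            prob.passes_used = 0
            prob.solve(lam, tol=tol)
            row[f] = multinomial_deviance(prob.snapshot(lam, True), Xte, yte)
        dev_rows.append(row)
        mean_so_far.append(row.mean())
        i_min_sofar = int(np.argmin(mean_so_far))
        if len(mean_so_far) - 1 - i_min_sofar >= patience:
            break
    grid = grid_all[: len(fits)]
    full_path = RegPath(lambdas=grid, fits=fits, lambda_max=lam_max)
    dev = np.vstack(dev_rows)  # (n_lambda_used, nfolds)
    mean_dev = dev.mean(axis=1)
    sd_dev = dev.std(axis=1, ddof=1)
    i_min = int(np.argmin(mean_dev))
    se_min = sd_dev[i_min] / np.sqrt(nfolds_eff)
    within = np.flatnonzero(mean_dev <= mean_dev[i_min] + se_min)
    i_1se = int(within.min())  # grid is decreasing: smallest index = largest lambda
    lam_min, lam_1se = float(grid[i_min]), float(grid[i_1se])
    chosen = lam_min if rule == "min" else lam_1se
    selected = full_path.fit_at(chosen)
    return CVResult(
        nfolds=int(nfolds_eff),
        fold_assignment=assignment,
        lambdas=grid,
        mean_deviance=mean_dev,
        sd_deviance=sd_dev,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        selection_rule=rule,
        selected_fit=selected,
        path=full_path,
    )


def predict_classes(fit: MultinomialFit, Xnew: np.ndarray) -> np.ndarray:
    """Argmax class codes; ties resolve to the smallest class index."""
    return np.argmax(fit.predict_proba(Xnew), axis=1)


def misclassification_rate(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    return float(np.mean(pred != truth))
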