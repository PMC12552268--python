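"""Independent reference solvers used only as test oracles.

The proximal-gradient (FISTA) solver below minimizes exactly the same
penalized multinomial objective as the package's coordinate-descent solver,

    (1/N) sum_i -log softmax_{y_i}(b + x_i' B')
        + lam * sum_j sum_k w_j (alpha |B_kj| + (1-alpha)/2 B_kj^2),

but by a completely different algorithm (accelerated full-gradient descent
with a closed-form elastic-net prox), so agreement between the two is a
meaningful correctness check. Intended for tiny instances only.
"""

from __future__ import annotations

import numpy as np


def softmax(eta: np.ndarray) -> np.ndarray:
    z = eta - eta.max(axis=1, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=1, keepdims=True)
    return z


def objective(Theta, X, Y, lam, alpha, w):
    """Penalized objective; Theta is (K, p+1) with intercepts in column 0."""
    N = X.shape[0]
    b, B = Theta[:, 0], Theta[:, 1:]
    eta = b + X @ B.T
    m = eta.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(eta - m).sum(axis=1))
    nll = float((lse - (eta * Y).sum(axis=1)).mean())
    pen = float(np.sum(w * (alpha * np.abs(B) + 0.5 * (1 - alpha) * B**2)))
    return nll + lam * pen


def _grad(Theta, X, Y):
    N = X.shape[0]
    b, B = Theta[:, 0], Theta[:, 1:]
    P = softmax(b + X @ B.T)
    R = (P - Y) / N
    g = np.empty_like(Theta)
    g[:, 0] = R.sum(axis=0)
    g[:, 1:] = R.T @ X
    return g


def fista_multinomial(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    lam: float,
    alpha: float = 1.0,
    w: np.ndarray | None = None,
    max_iter: int = 100_000,
    tol: float = 1e-14,
):
    """Reference minimizer of the weighted elastic-net multinomial objective.

    Returns ``(intercepts, coef)`` with intercepts mean-centered (the zero
    initialization keeps the iterates in the mean-zero subspace for every
    unpenalized direction). Excluded (infinite-weight) features must be
    removed by the caller.
    """
    X = np.asarray(X, dtype=np.float64)
    N, p = X.shape
    if w is None:
        w = np.ones(p)
    Y = np.zeros((N, K))
    Y[np.arange(N), np.asarray(y, dtype=int)] = 1.0
    Xa = np.hstack([np.ones((N, 1)), X])
    # softmax Hessian over classes is bounded by (1/2) I, so the Lipschitz
    # constant of the gradient is at most smax(Xa'Xa) / (2N)
    L = np.linalg.eigvalsh(Xa.T @ Xa).max() / (2.0 * N)
    step = 1.0 / L
    Theta = np.zeros((K, p + 1))
    Z = Theta.copy()
    t_acc = 1.0
    f_prev = np.inf
    for it in range(max_iter):
        G = _grad(Z, X, Y)
        cand = Z - step * G
        new = cand.copy()
        # prox of the weighted elastic net on the feature columns
        thr = step * lam * alpha * w
        denom = 1.0 + step * lam * (1.0 - alpha) * w
        Bc = cand[:, 1:]
        new[:, 1:] = np.sign(Bc) * np.maximum(np.abs(Bc) - thr, 0.0) / denom
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        Z = new + ((t_acc - 1.0) / t_next) * (new - Theta)
        Theta, t_acc = new, t_next
        if it % 50 == 0:
            f = objective(Theta, X, Y, lam, alpha, w)
            if abs(f_prev - f) < tol * (1.0 + abs(f)):
                break
            f_prev = f
    b = Theta[:, 0] - Theta[:, 0].mean()
    return b, Theta[:, 1:]


def random_instance(rng, N=60, p=4, K=3, signal=1.0):
    """Small random multinomial dataset with standardized predictors."""
    X = rng.standard_normal((N, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    B = rng.standard_normal((K, p)) * signal
    eta = X @ B.T
    P = softmax(eta)
    y = np.array([rng.choice(K, p=row) for row in P])
    # ensure every class has >= 2 members
    for k in range(K):
        deficit = 2 - int((y == k).sum())
        if deficit > 0:
            free = np.flatnonzero(np.bincount(y, minlength=K)[y] > 2)
            y[rng.choice(free, size=deficit, replace=False)] = k
    return X, y
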