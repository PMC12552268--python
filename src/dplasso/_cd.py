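"""Numba coordinate-descent kernel for the weighted elastic-net multinomial fit.

Outer iterations cycle over class blocks. For each block the multinomial
log-likelihood is replaced by a penalized weighted least-squares surrogate
built from the current probabilities (IRLS working response with curvature
``pi*(1-pi)``, floored for stability), which cyclic coordinate descent with
soft-thresholding solves over the active set. Because the IRLS surrogate is
not a global majorizer, every full cycle is objective-checked: if the
penalized objective increased, the cycle is rolled back and redone with the
uniform curvature bound 1/4, which majorizes the softmax likelihood and
guarantees descent. The reported objective is therefore non-increasing
across outer iterations.

Convergence follows the usual path-solver convention: a cycle converges when
the largest curvature-weighted squared coefficient change falls below the
tolerance. One "pass" is one sweep of coordinate updates over the active set
for one class.
"""

import numpy as np
from numba import njit

VFLOOR = 1e-5  # curvature floor for the IRLS weights


@njit(cache=True, fastmath=True)
def _objective(eta, ycodes, beta, b, w, lam, alpha, active):  # pragma: no cover
    N, K = eta.shape
    nll = 0.0
    for i in range(N):
        mx = eta[i, 0]
        for r in range(1, K):
            if eta[i, r] > mx:
                mx = eta[i, r]
        s = 0.0
        for r in range(K):
            s += np.exp(eta[i, r] - mx)
        nll += mx + np.log(s) - eta[i, ycodes[i]]
    nll /= N
    pen = 0.0
    for t in range(active.shape[0]):
        j = active[t]
        for k in range(beta.shape[0]):
            bkj = beta[k, j]
            pen += w[j] * (alpha * abs(bkj) + 0.5 * (1.0 - alpha) * bkj * bkj)
    return nll + lam * pen


@njit(cache=True, fastmath=True)
def _sweep(
    X, active, which, w, lam, alpha, beta, b, res, v, u, sumv, dcol, k, N
):  # pragma: no cover
    """One coordinate sweep (intercept + the given active-set positions).

    ``u`` maintains the product ``v * res`` so the gradient inner product
    needs a single multiply per sample.
    """
    inner_crit = 0.0
    num = 0.0
    for i in range(N):
        num += u[i]
    d = num / sumv
    if d != 0.0:
        b[k] += d
        for i in range(N):
            res[i] -= d
            u[i] -= v[i] * d
        crit = d * d * sumv / N
        if crit > inner_crit:
            inner_crit = crit
    for s in range(which.shape[0]):
        t = which[s]
        j = active[t]
        dj = dcol[t]
        bj = beta[k, j]
        g = 0.0
        for i in range(N):
            g += X[i, j] * u[i]
        g = g / N + dj * bj
        thr = lam * alpha * w[j]
        denom = dj + lam * (1.0 - alpha) * w[j]
        if g > thr:
            bnew = (g - thr) / denom
        elif g < -thr:
            bnew = (g + thr) / denom
        else:
            bnew = 0.0
        d = bnew - bj
        if d != 0.0:
            beta[k, j] = bnew
            for i in range(N):
                res[i] -= X[i, j] * d
                u[i] -= v[i] * X[i, j] * d
            crit = d * d * dj
            if crit > inner_crit:
                inner_crit = crit
    return inner_crit


@njit(cache=True, fastmath=True)
def _class_cycle(
    X, ycodes, active, w, lam, alpha, beta, b, eta, colsq, tol, max_passes, exact
):  # pragma: no cover
    """One full cycle over class blocks; returns (passes, max_crit)."""
    N, p = X.shape
    K = b.shape[0]
    m = active.shape[0]
    res = np.empty(N)
    v = np.empty(N)
    u = np.empty(N)
    z = np.empty(N)
    dcol = np.empty(m)
    passes = 0
    cycle_crit = 0.0
    for k in range(K):
        # probabilities for class k and the working quadratic
        sumv = 0.0
        for i in range(N):
            mx = eta[i, 0]
            for r in range(1, K):
                if eta[i, r] > mx:
                    mx = eta[i, r]
            s = 0.0
            for r in range(K):
                s += np.exp(eta[i, r] - mx)
            pik = np.exp(eta[i, k] - mx) / s
            yik = 1.0 if ycodes[i] == k else 0.0
            if exact:
                vi = pik * (1.0 - pik)
                if vi < VFLOOR:
                    vi = VFLOOR
            else:
                vi = 0.25
            v[i] = vi
            sumv += vi
            res[i] = (yik - pik) / vi  # residual of the working response
            u[i] = yik - pik
            z[i] = eta[i, k] + res[i]
        # per-coordinate curvature (1/N) sum v x^2
        for t in range(m):
            j = active[t]
            if exact:
                d = 0.0
                for i in range(N):
                    d += v[i] * X[i, j] * X[i, j]
                dcol[t] = d / N
            else:
                dcol[t] = 0.25 * colsq[j]
        # one admission sweep over the full active set, then iterate on the
        # currently nonzero working set; admission of further coordinates
        # happens on the next surrogate cycle
        inner_crit = _sweep(
            X, active, np.arange(m), w, lam, alpha, beta, b, res, v, u,
            sumv, dcol, k, N,
        )
        passes += 1
        if inner_crit > cycle_crit:
            cycle_crit = inner_crit
        if inner_crit >= tol:
            work = np.flatnonzero(beta[k][active])
            inner = 0
            while work.shape[0] > 0:
                wcrit = _sweep(
                    X, active, work, w, lam, alpha, beta, b, res, v, u,
                    sumv, dcol, k, N,
                )
                inner += 1
                passes += 1
                if wcrit < tol or inner >= 1000 or passes >= max_passes:
                    break
        for i in range(N):
            eta[i, k] = z[i] - res[i]
    # keep intercepts identifiable (common shift leaves softmax unchanged)
    c = 0.0
    for k in range(K):
        c += b[k]
    c /= K
    if c != 0.0:
        for k in range(K):
            b[k] -= c
        for i in range(N):
            for k in range(K):
                eta[i, k] -= c
    return passes, cycle_crit


@njit(cache=True, fastmath=True)
def cd_active(
    X,          # (N, p) float64, Fortran order preferred
    ycodes,     # (N,) int64 class codes 0..K-1
    active,     # (m,) int64 feature indices allowed to move
    w,          # (p,) float64 penalty weights (finite on active features)
    lam,        # float
    alpha,      # float in [0, 1]
    beta,       # (K, p) float64, updated in place
    b,          # (K,) float64 intercepts, updated in place
    eta,        # (N, K) float64 linear predictors incl. intercept, in place
    colsq,      # (p,) float64 mean of squared column entries
    tol,        # convergence tolerance (curvature-weighted squared change)
    max_passes, # remaining pass budget
):  # pragma: no cover - numba
    """Run the block CD until the active-set fit converges.

    Returns ``(passes, converged)``.
    """
    passes = 0
    obj = _objective(eta, ycodes, beta, b, w, lam, alpha, active)
    converged = False
    while passes < max_passes:
        beta_snap = beta.copy()
        b_snap = b.copy()
        eta_snap = eta.copy()
        np_, crit = _class_cycle(
            X, ycodes, active, w, lam, alpha, beta, b, eta, colsq, tol,
            max_passes - passes, True,
        )
        passes += np_
        new_obj = _objective(eta, ycodes, beta, b, w, lam, alpha, active)
        if new_obj > obj + 1e-12 * (1.0 + abs(obj)):
            # IRLS overshoot: roll back and take a guaranteed-descent
            # majorization cycle instead
            beta[:, :] = beta_snap
            b[:] = b_snap
            eta[:, :] = eta_snap
            np_, crit = _class_cycle(
                X, ycodes, active, w, lam, alpha, beta, b, eta, colsq, tol,
                max_passes - passes, False,
            )
            passes += np_
            new_obj = _objective(eta, ycodes, beta, b, w, lam, alpha, active)
            if new_obj > obj:
                new_obj = obj  # numerically at the floor
        obj = new_obj
        if crit < tol:
            converged = True
            break
    return passes, converged
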