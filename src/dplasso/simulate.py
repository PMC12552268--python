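"""Synthetic data generator for the variable-selection study.

Predictors are drawn i.i.d. from ``MVN(0, Sigma)`` where ``Sigma`` is
block-diagonal with identical 20x20 equicorrelation blocks: diagonal
``sigma^2`` (default 0.5) and off-diagonal ``rho * sigma^2`` within a
block, zero across blocks. Outcomes are multinomial draws from the softmax
probabilities under a sparse true coefficient matrix with zero intercepts:

* structure 1 — classes 2..K carry the sign pattern
  ``(kappa, -kappa, kappa, kappa, -kappa, kappa)`` on features 1-10 and are
  zero elsewhere (K=2: class 2 is ``kappa`` on features 1-10);
* structure 2 — class 3 (and class 6 when K=7) instead carries ``-kappa``
  on features 11-20 only, all its other components zero.

The truth support is the set of features with a nonzero column in the true
coefficient matrix: features 1-10 under structure 1, 1-20 under structure 2
(for K >= 4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import LabeledDataset

__all__ = [
    "SimulationDesign",
    "make_block_covariance",
    "make_true_beta",
    "simulate_dataset",
]

BLOCK_SIZE = 20


@dataclass(frozen=True)
class SimulationDesign:
    """Configuration of one simulated dataset.

    ``sigma2`` is the marginal predictor variance, ``rho`` the within-block
    correlation, ``kappa`` the effect size of the true coefficients.
    """

    K: int = 7
    p: int = 100
    N: int = 1000
    rho: float = 0.0
    sigma2: float = 0.5
    kappa: float = 0.5
    structure: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K not in (2, 4, 7):
            raise ValueError("built-in coefficient patterns exist for K in {2, 4, 7}")
        if self.p % BLOCK_SIZE != 0 or self.p <= 0:
            raise ValueError(f"p must be a positive multiple of {BLOCK_SIZE}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if self.structure not in (1, 2):
            raise ValueError("structure must be 1 or 2")
        if self.structure == 2 and self.K == 2:
            raise ValueError("structure 2 is defined for K in {4, 7}")


def make_block_covariance(design: SimulationDesign) -> np.ndarray:
    """Dense p x p block-diagonal covariance with equicorrelation blocks."""
    B = np.full((BLOCK_SIZE, BLOCK_SIZE), design.rho * design.sigma2)
    np.fill_diagonal(B, design.sigma2)
    n_blocks = design.p // BLOCK_SIZE
    cov = np.zeros((design.p, design.p))
    for b in range(n_blocks):
        s = b * BLOCK_SIZE
        cov[s : s + BLOCK_SIZE, s : s + BLOCK_SIZE] = B
    return cov


def make_true_beta(K: int, p: int, kappa: float, structure: int) -> np.ndarray:
    """True K x p coefficient matrix of the generating softmax model."""
    if K not in (2, 4, 7):
        raise ValueError("K must be one of {2, 4, 7}")
    if structure not in (1, 2) or (structure == 2 and K == 2):
        raise ValueError(f"unsupported structure {structure} for K={K}")
    if p < BLOCK_SIZE:
        raise ValueError(f"p must be at least {BLOCK_SIZE}")
    beta = np.zeros((K, p))
    signs = {2: [1], 4: [1, -1, 1], 7: [1, -1, 1, 1, -1, 1]}[K]
    for row, s in enumerate(signs, start=1):
        beta[row, :10] = s * kappa
    if structure == 2:
        moved = [2] if K == 4 else [2, 5]  # classes 3 and 6 (0-based rows)
        for row in moved:
            beta[row, :] = 0.0
            beta[row, 10:20] = -kappa
    return beta


def _sample_predictors(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw X ~ MVN(0, Sigma) using one 20x20 Cholesky factor per block."""
    B = np.full((BLOCK_SIZE, BLOCK_SIZE), design.rho * design.sigma2)
    np.fill_diagonal(B, design.sigma2)
    L = np.linalg.cholesky(B)
    Z = rng.standard_normal((design.N, design.p))
    X = np.empty_like(Z)
    for b in range(design.p // BLOCK_SIZE):
        s = b * BLOCK_SIZE
        X[:, s : s + BLOCK_SIZE] = Z[:, s : s + BLOCK_SIZE] @ L.T
    return X


def simulate_dataset(design: SimulationDesign) -> tuple[LabeledDataset, np.ndarray]:
    """Generate one dataset; returns ``(data, truth_support)``.

    ``truth_support`` is a boolean mask over features marking columns of the
    true coefficient matrix with any nonzero entry. Bit-reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(design.seed)
    X = _sample_predictors(design, rng)
    beta = make_true_beta(design.K, design.p, design.kappa, design.structure)
    eta = X @ beta.T
    eta -= eta.max(axis=1, keepdims=True)
    prob = np.exp(eta)
    prob /= prob.sum(axis=1, keepdims=True)
    u = rng.random(design.N)
    y = (prob.cumsum(axis=1) < u[:, None]).sum(axis=1)
    # guard against a class absent by chance in a tiny draw
    if np.bincount(y, minlength=design.K).min() < 2:
        raise RuntimeError(
            "a class received fewer than 2 samples; increase N or change seed"
        )
    truth = np.abs(beta).sum(axis=0) != 0
    data = LabeledDataset(
        X=X, y=y, class_labels=list(range(1, design.K + 1))
    )
    return data, truth
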