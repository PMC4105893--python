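"""Fuzzy c-means in position space (FCM) and in feature space (FCM-WF).

Both variants minimise the same objective

    J_m = sum_i sum_j u_ij^m * ||X_i - C_j||^2

over a row-stochastic membership matrix U (N x K) and centroids C
(K x F) by the usual alternating updates.  ``spatial_only`` mode
restricts the space to the normalized (x, y) columns — the standard
FCM baseline; ``with_features`` uses all nine components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError, InputError

__all__ = [
    "FcmConfig",
    "FuzzyPartition",
    "initialize_membership",
    "update_centroids",
    "update_membership",
    "objective",
    "fcm_fit",
    "defuzzify",
    "select_columns",
]

_COINCIDENT = 1e-12  # squared distance below which a point sits on a centroid


@dataclass(frozen=True)
class FcmConfig:
    """Settings of one fuzzy c-means run.

    ``fuzzifier_m`` is the membership-softness exponent (conventional
    choice 2).  Convergence is declared when the relative change of the
    objective between successive iterations drops below ``tol``.
    """

    K: int
    fuzzifier_m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 300
    seed: int | None = None
    feature_mode: str = "with_features"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.fuzzifier_m <= 1:
            raise ConfigError("fuzzifier_m must be > 1")
        if self.tol <= 0 or self.max_iter < 1:
            raise ConfigError("tol must be > 0 and max_iter >= 1")
        if self.feature_mode not in ("spatial_only", "with_features"):
            raise ConfigError(f"unknown feature_mode {self.feature_mode!r}")


@dataclass
class FuzzyPartition:
    """Result of a fit: memberships, centroids and objective history."""

    U: np.ndarray
    C: np.ndarray
    J_history: list[float]
    converged: bool

    @property
    def K(self) -> int:
        return self.U.shape[1]


def select_columns(X: np.ndarray, feature_mode: str) -> np.ndarray:
    """Restrict a full feature matrix to the clustering space.

    ``spatial_only`` keeps the first two columns (x, y) of a 9-column
    matrix; matrices that are already 2-column pass through unchanged.
    """
    X = np.asarray(X, dtype=float)
    if feature_mode == "spatial_only" and X.shape[1] > 2:
        return X[:, :2]
    return X


def initialize_membership(N: int, K: int, seed=None) -> np.ndarray:
    """Random row-stochastic start: each row uniform on the K-simplex."""
    if N < K:
        raise InputError(f"need N >= K, got N={N}, K={K}")
    rng = np.random.default_rng(seed)
    U = rng.random((N, K))
    U /= U.sum(axis=1, keepdims=True)
    return U


def update_centroids(X: np.ndarray, U: np.ndarray, m: float,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """Weighted means C_j = sum_i u_ij^m X_i / sum_i u_ij^m.

    A membership column that is identically zero gives no information;
    its centroid is re-seeded at a random data point.
    """
    W = U ** m
    denom = W.sum(axis=0)
    dead = denom <= 0
    if np.any(dead):
        rng = rng or np.random.default_rng()
        denom = denom.copy()
        denom[dead] = 1.0
    C = (W.T @ X) / denom[:, None]
    if np.any(dead):
        idx = rng.integers(0, X.shape[0], size=int(dead.sum()))
        C[dead] = X[idx]
    return C


def update_membership(X: np.ndarray, C: np.ndarray, m: float) -> np.ndarray:
    """Closed-form optimal memberships for fixed centroids.

    u_ij = 1 / sum_k (||X_i - C_j|| / ||X_i - C_k||)^(2/(m-1)).  A point
    coinciding with one or more centroids splits its membership equally
    over the coinciding centroids and is 0 elsewhere.
    """
    d2 = cdist(X, C, metric="sqeuclidean")
    coincide = d2 < _COINCIDENT
    U = np.zeros_like(d2)
    hit = coincide.any(axis=1)
    if np.any(hit):
        rows = coincide[hit]
        U[hit] = rows / rows.sum(axis=1, keepdims=True)
    free = ~hit
    if np.any(free):
        p = d2[free] ** (-1.0 / (m - 1.0))
        U[free] = p / p.sum(axis=1, keepdims=True)
    return U


def objective(X: np.ndarray, U: np.ndarray, C: np.ndarray, m: float) -> float:
    """The fuzzy within-cluster scatter J_m (always >= 0)."""
    d2 = cdist(X, C, metric="sqeuclidean")
    return float(((U ** m) * d2).sum())


def fcm_fit(X: np.ndarray, config: FcmConfig) -> FuzzyPartition:
    """Alternate centroid/membership updates from a seeded random start.

    Iterates until the relative objective change falls below
    ``config.tol`` or ``config.max_iter`` is reached.  The recorded
    J_history is non-increasing because each half-update minimises the
    objective in its own block.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise InputError("feature matrix contains non-finite values")
    Xs = select_columns(X, config.feature_mode)
    N = Xs.shape[0]
    if N < config.K:
        raise InputError(f"need at least K={config.K} objects, got {N}")
    rng = np.random.default_rng(config.seed)
    U = initialize_membership(N, config.K, seed=rng)
    history: list[float] = []
    converged = False
    J_prev = None
    for _ in range(config.max_iter):
        C = update_centroids(Xs, U, config.fuzzifier_m, rng=rng)
        U = update_membership(Xs, C, config.fuzzifier_m)
        J = objective(Xs, U, C, config.fuzzifier_m)
        history.append(J)
        if J_prev is not None:
            scale = max(abs(J_prev), 1e-300)
            if abs(J_prev - J) <= config.tol * scale:
                converged = True
                break
        J_prev = J
    return FuzzyPartition(U=U, C=C, J_history=history, converged=converged)


def defuzzify(U: np.ndarray) -> np.ndarray:
    """Hard labels by maximal membership; ties go to the lowest index."""
    return np.argmax(U, axis=1)
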