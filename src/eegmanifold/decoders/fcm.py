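"""Classical fuzzy c-means clustering.

Alternates membership and center updates for the objective
J = sum_j sum_k x_jk^m ||u_j - c_k||^2 subject to unit membership row sums;
used to place the antecedent fuzzy sets of the TSK decoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class FCMResult:
    centers: np.ndarray          # (K, d)
    memberships: np.ndarray      # (n, K), rows sum to 1
    m: float
    objective_trace: np.ndarray
    converged: bool


def _kmeanspp_init(U: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Distance-weighted (k-means++-style) center seeding."""
    n = U.shape[0]
    centers = [U[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            np.sum((U[:, None, :] - np.asarray(centers)[None]) ** 2, axis=-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            centers.append(U[rng.integers(n)])
            continue
        centers.append(U[rng.choice(n, p=d2 / total)])
    return np.asarray(centers, dtype=float)


def fcm(
    U: np.ndarray,
    K: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int | None = None,
) -> FCMResult:
    """Fuzzy c-means on points ``U`` (n x d) into K clusters.

    ``m > 1`` is the fuzzifier.  K=1 is the degenerate case: the single
    center is the data mean and every membership is 1.  Deterministic under a
    fixed seed.  Non-convergence within ``max_iter`` returns with
    ``converged=False`` and a warning rather than failing.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    n, d = U.shape
    if K < 1:
        raise ValueError("K must be at least 1")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    if n <= K and K > 1:
        raise ValueError(f"need more than K={K} points, got {n}")
    if K == 1:
        return FCMResult(
            centers=U.mean(axis=0, keepdims=True),
            memberships=np.ones((n, 1)),
            m=m,
            objective_trace=np.zeros(1),
            converged=True,
        )

    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(U, K, rng)
    objective = []
    x = None
    for _ in range(max_iter):
        d2 = np.sum((U[:, None, :] - centers[None]) ** 2, axis=-1)  # (n, K)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        x = inv / inv.sum(axis=1, keepdims=True)
        xm = x**m
        centers = (xm.T @ U) / xm.sum(axis=0)[:, None]
        objective.append(float(np.sum(xm * d2)))
        # relative tolerance so the criterion is scale-free in the data units
        if (
            len(objective) > 1
            and abs(objective[-2] - objective[-1]) < tol * (1.0 + abs(objective[-1]))
        ):
            return FCMResult(
                centers=centers,
                memberships=x,
                m=m,
                objective_trace=np.asarray(objective),
                converged=True,
            )
    warnings.warn(f"fuzzy c-means did not converge in {max_iter} iterations")
    return FCMResult(
        centers=centers,
        memberships=x,
        m=m,
        objective_trace=np.asarray(objective),
        converged=False,
    )
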