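"""t-distributed stochastic neighbor embedding, implemented from scratch.

High-dimensional affinities use per-point Gaussian kernels whose bandwidth
sigma_i is found by binary search so that every conditional distribution
p_{.|i} has the requested perplexity; the joint distribution is the
symmetrization p_ij = (p_{j|i} + p_{i|j}) / (2N).  Low-dimensional
affinities use a Student-t kernel with one degree of freedom, and the
embedding minimizes KL(P || Q) by gradient descent with momentum, early
exaggeration, and a deterministic PCA initialization under a fixed seed.
"""

from __future__ import annotations

import warnings

import numpy as np

_EPS = 1e-12


def _pairwise_sq_dists(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X**2, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _conditional_row(d_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """Conditional p_{.|i} at precision beta = 1/(2 sigma^2); returns (p, entropy)."""
    p = np.exp(-d_row * beta)
    s = max(p.sum(), _EPS)
    p = p / s
    # Shannon entropy in nats
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return p, h


def conditional_probabilities(
    X: np.ndarray, perplexity: float, tol: float = 1e-7, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point conditional distributions with perplexity-matched sigmas.

    Returns (P_cond (n, n) with zero diagonal and unit row sums, sigmas (n,)).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 < perplexity < n:
        raise ValueError(f"perplexity must lie in (1, n={n})")
    D = _pairwise_sq_dists(X)
    off = ~np.eye(n, dtype=bool)
    target = np.log(perplexity)
    P = np.zeros((n, n))
    sigmas = np.empty(n)
    for i in range(n):
        d_row = D[i, off[i]]
        if np.all(d_row < _EPS):
            raise ValueError("all pairwise distances vanish; inputs are duplicates")
        beta, lo, hi = 1.0, 0.0, np.inf
        p = None
        for _ in range(max_iter):
            p, h = _conditional_row(np.maximum(d_row, _EPS), beta)
            diff = h - target
            if abs(diff) < tol:
                break
            if diff > 0:  # entropy too high -> sharpen
                lo = beta
                beta = beta * 2.0 if not np.isfinite(hi) else (lo + hi) / 2.0
            else:
                hi = beta
                beta = (lo + hi) / 2.0
        P[i, off[i]] = p
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
    return P, sigmas


def joint_probabilities(
    X: np.ndarray, perplexity: float, tol: float = 1e-7
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetrized joint P: p_ij = (p_{j|i} + p_{i|j}) / (2N); sums to 1."""
    P_cond, sigmas = conditional_probabilities(X, perplexity, tol=tol)
    n = X.shape[0]
    P = (P_cond + P_cond.T) / (2.0 * n)
    return P, sigmas


def _deduplicate(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Jitter exact duplicate rows so pairwise distances are well defined."""
    _, counts = np.unique(X.round(decimals=12), axis=0, return_counts=True)
    if np.any(counts > 1):
        scale = max(X.std(), 1.0) * 1e-8
        warnings.warn("duplicate points detected; adding tiny jitter", stacklevel=3)
        X = X + rng.standard_normal(X.shape) * scale
    return X


def _pca_init(X: np.ndarray, n_dims: int) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Y = Xc @ Vt[:n_dims].T
    std = Y[:, 0].std()
    return Y / (std if std > 0 else 1.0) * 1e-4


def tsne_embed(
    X: np.ndarray,
    perplexity: float = 30.0,
    n_dims: int = 2,
    n_iter: int = 1000,
    learning_rate: float = 200.0,
    early_exaggeration: float = 4.0,
    exaggeration_iter: int = 100,
    momentum: tuple[float, float] = (0.5, 0.8),
    momentum_switch: int = 250,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Run t-SNE; returns (embedding (n, n_dims), diagnostics).

    Diagnostics carry the per-point sigmas, the KL(P||Q) trace, and the final
    KL value.  Deterministic under a fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 5:
        raise ValueError("t-SNE needs at least 5 points")
    rng = np.random.default_rng(seed)
    X = _deduplicate(X, rng)
    P, sigmas = joint_probabilities(X, perplexity)
    P = np.maximum(P, _EPS)

    Y = _pca_init(X, n_dims)
    Y = Y + rng.standard_normal(Y.shape) * 1e-6
    update = np.zeros_like(Y)
    gains = np.ones_like(Y)  # per-coordinate adaptive gains (delta-bar-delta)
    kl_trace = np.empty(n_iter)

    for it in range(n_iter):
        exag = early_exaggeration if it < exaggeration_iter else 1.0
        num = 1.0 / (1.0 + _pairwise_sq_dists(Y))
        np.fill_diagonal(num, 0.0)
        Q = num / max(num.sum(), _EPS)
        Q = np.maximum(Q, _EPS)
        PQ = exag * P - Q
        # gradient of KL wrt Y (Student-t kernel, 1 d.f.)
        W = PQ * num
        grad = 4.0 * ((np.diag(W.sum(axis=1)) - W) @ Y)
        mom = momentum[0] if it < momentum_switch else momentum[1]
        gains = np.where(np.sign(grad) != np.sign(update),
                         gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        update = mom * update - learning_rate * gains * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
        kl_trace[it] = np.sum(P * (np.log(P) - np.log(Q)))

    diagnostics = {
        "sigmas": sigmas,
        "kl_trace": kl_trace,
        "kl_final": float(kl_trace[-1]),
        "perplexity": perplexity,
        "n_iter": n_iter,
        "seed": seed,
    }
    return Y, diagnostics
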