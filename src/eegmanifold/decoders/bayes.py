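"""Gaussian naive Bayes decoder.

Class-conditional densities factorize over features (naive independence),
each feature Gaussian with class-specific mean and variance; priors are the
class frequencies.  Posteriors are normalized to sum to 1 and the predicted
class is the argmax (lowest index on ties).  Zero-variance features get a
small variance floor instead of failing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VAR_FLOOR = 1e-9


@dataclass
class NBModel:
    classes: np.ndarray
    priors: np.ndarray     # (J,)
    means: np.ndarray      # (J, d)
    variances: np.ndarray  # (J, d)


def nb_fit(U: np.ndarray, labels: np.ndarray, var_floor: float = VAR_FLOOR) -> NBModel:
    U = np.atleast_2d(np.asarray(U, dtype=float))
    labels = np.asarray(labels)
    classes = np.unique(labels)
    J, d = len(classes), U.shape[1]
    priors = np.empty(J)
    means = np.empty((J, d))
    variances = np.empty((J, d))
    for j, c in enumerate(classes):
        Xc = U[labels == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        priors[j] = len(Xc) / len(U)
        means[j] = Xc.mean(axis=0)
        variances[j] = np.maximum(Xc.var(axis=0), var_floor)
    return NBModel(classes=classes, priors=priors, means=means, variances=variances)


def nb_predict(model: NBModel, u: np.ndarray):
    """(posteriors, label); accepts one vector or a batch of rows."""
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    U = np.atleast_2d(u)
    # log P(c) + sum_i log N(u_i; mu_ci, var_ci), stabilized before exponentiation
    log_lik = -0.5 * (
        np.log(2 * np.pi * model.variances[None, :, :])
        + (U[:, None, :] - model.means[None]) ** 2 / model.variances[None]
    ).sum(axis=2)
    log_post = np.log(model.priors)[None, :] + log_lik
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    labels = model.classes[post.argmax(axis=1)]
    if single:
        return post[0], labels[0]
    return post, labels
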