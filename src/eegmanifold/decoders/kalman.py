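"""Linear Kalman filter decoder.

Generative state-space view of decoding: the hidden state y_t (here a
one-hot class vector, dimension J) evolves linearly, y_t = A y_{t-1} + q,
and emits the observed latent factors l_t = H y_t + v, with Gaussian process
and observation noise Q, V.  A and H are fitted by least squares over
training (state, observation) pairs, Q and V as residual covariances
(eigenvalue-clipped to stay positive semidefinite).  The Kalman gain is
iterated to its steady state before decoding; each trial starts from y_0
mapped from the average of its first few observations through pinv(H), and
the trial's class is the argmax of the time-averaged filtered state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tsk import one_hot


@dataclass
class KFModel:
    A: np.ndarray          # (J, J) state transition
    H: np.ndarray          # (p, J) observation matrix
    Q: np.ndarray          # (J, J) process noise covariance
    V: np.ndarray          # (p, p) observation noise covariance
    gain: np.ndarray       # (J, p) steady-state Kalman gain
    classes: np.ndarray
    n_init: int = 3


def _psd_clip(M: np.ndarray, name: str) -> np.ndarray:
    M = (M + M.T) / 2.0
    vals, vecs = np.linalg.eigh(M)
    if vals.min() < 0:
        warnings.warn(f"{name} covariance had negative eigenvalues; clipped to 0")
        vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def steady_state_gain(
    A: np.ndarray,
    H: np.ndarray,
    Q: np.ndarray,
    V: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> np.ndarray:
    """Iterate the Riccati recursion until the Kalman gain is stationary."""
    J = A.shape[0]
    P = Q.copy() + 1e-9 * np.eye(J)
    gain = np.zeros((J, H.shape[0]))
    for _ in range(max_iter):
        P_pred = A @ P @ A.T + Q
        S = H @ P_pred @ H.T + V
        new_gain = P_pred @ H.T @ np.linalg.pinv(S)
        P = (np.eye(J) - new_gain @ H) @ P_pred
        if np.max(np.abs(new_gain - gain)) < tol:
            return new_gain
        gain = new_gain
    return gain


def kf_fit(
    features: np.ndarray,
    labels: np.ndarray,
    trial_ids: np.ndarray | None = None,
    classes=None,
    ridge: float = 1e-8,
    n_init: int = 3,
    q_floor: float = 0.01,
) -> KFModel:
    """Fit the state-space decoder from per-epoch latent factors.

    ``trial_ids`` groups consecutive epochs into trials; without them each
    sample is its own (length-1) sequence and A defaults to the identity.

    ``q_floor`` is added to the diagonal of the fitted process covariance:
    with class labels constant within a trial the within-trial state
    residuals are identically zero, which would drive the Kalman gain to
    zero and freeze the filter at its initial state; the floor keeps the
    filter responsive to observations.
    """
    L = np.atleast_2d(np.asarray(features, dtype=float))
    Y, classes = one_hot(labels, classes)
    n, J = Y.shape
    if trial_ids is None:
        trial_ids = np.arange(n)
    trial_ids = np.asarray(trial_ids)

    # A from consecutive within-trial state pairs: Y2 ~ Y1 A^T
    prev, nxt = [], []
    for t in np.unique(trial_ids):
        idx = np.flatnonzero(trial_ids == t)
        if len(idx) > 1:
            prev.append(Y[idx[:-1]])
            nxt.append(Y[idx[1:]])
    if prev:
        Y1 = np.concatenate(prev)
        Y2 = np.concatenate(nxt)
        A = np.linalg.solve(
            Y1.T @ Y1 + ridge * np.eye(J), Y1.T @ Y2
        ).T
        Q = _psd_clip(np.cov((Y2 - Y1 @ A.T).T, bias=True) + ridge * np.eye(J), "process")
    else:
        A = np.eye(J)
        Q = ridge * np.eye(J)
    Q = Q + q_floor * np.eye(J)

    # H from all (state, observation) pairs: L ~ Y H^T
    H = np.linalg.solve(Y.T @ Y + ridge * np.eye(J), Y.T @ L).T
    resid = L - Y @ H.T
    V = _psd_clip(np.atleast_2d(np.cov(resid.T, bias=True)) + ridge * np.eye(L.shape[1]),
                  "observation")

    gain = steady_state_gain(A, H, Q, V)
    return KFModel(A=A, H=H, Q=Q, V=V, gain=gain, classes=classes, n_init=n_init)


def kf_filter(model: KFModel, sequence: np.ndarray) -> np.ndarray:
    """Run the steady-gain filter over one trial's observation sequence."""
    L = np.atleast_2d(np.asarray(sequence, dtype=float))
    y = np.linalg.pinv(model.H) @ L[: model.n_init].mean(axis=0)
    out = np.empty((len(L), model.A.shape[0]))
    for t, l_t in enumerate(L):
        y_pred = model.A @ y
        y = y_pred + model.gain @ (l_t - model.H @ y_pred)
        out[t] = y
    return out


def kf_decode(model: KFModel, sequence: np.ndarray):
    """(filtered state trajectory, trial label): argmax of time-averaged y."""
    traj = kf_filter(model, sequence)
    label = model.classes[traj.mean(axis=0).argmax()]
    return traj, label
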