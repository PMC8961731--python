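"""Long short-term memory decoder, implemented in plain numpy.

One LSTM layer: forget, input and output gates squashed by the sigmoid, a
tanh candidate cell, the cell update c_t = f_t * c_{t-1} + i_t * c~_t and
hidden state h_t = o_t * tanh(c_t).  The cell equations alone do not make a
decoder, so a linear softmax readout on the final hidden state and full-batch
gradient descent (backpropagation through time, gradient clipping) are added;
training is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class LSTMParams:
    """Gate weights: W_*x on the input, W_*h recurrent, b_* biases."""

    Wfx: np.ndarray
    Wfh: np.ndarray
    bf: np.ndarray
    Wix: np.ndarray
    Wih: np.ndarray
    bi: np.ndarray
    Wox: np.ndarray
    Woh: np.ndarray
    bo: np.ndarray
    Wcx: np.ndarray
    Wch: np.ndarray
    bc: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.bf.size

    @property
    def input_size(self) -> int:
        return self.Wfx.shape[1]

    @classmethod
    def init(cls, input_size: int, hidden_size: int, rng: np.random.Generator):
        def w(rows, cols):
            return rng.standard_normal((rows, cols)) * (1.0 / np.sqrt(max(cols, 1)))

        z = np.zeros(hidden_size)
        return cls(
            Wfx=w(hidden_size, input_size), Wfh=w(hidden_size, hidden_size), bf=z.copy() + 1.0,
            Wix=w(hidden_size, input_size), Wih=w(hidden_size, hidden_size), bi=z.copy(),
            Wox=w(hidden_size, input_size), Woh=w(hidden_size, hidden_size), bo=z.copy(),
            Wcx=w(hidden_size, input_size), Wch=w(hidden_size, hidden_size), bc=z.copy(),
        )

    def fields(self):
        return [
            "Wfx", "Wfh", "bf", "Wix", "Wih", "bi",
            "Wox", "Woh", "bo", "Wcx", "Wch", "bc",
        ]


def lstm_step(params: LSTMParams, u_t, h_prev, c_prev):
    """One cell update; returns (h_t, c_t, gates dict).

    Inputs may be single vectors or batches (rows).  With all-zero weights
    and biases every gate is sigmoid(0) = 1/2, so c_t = c_{t-1}/2 and
    h_t = tanh(c_t)/2.
    """
    u_t = np.atleast_2d(np.asarray(u_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=float))
    if not np.all(np.isfinite(u_t)):
        raise ValueError("non-finite input to LSTM step")
    f = _sigmoid(u_t @ params.Wfx.T + h_prev @ params.Wfh.T + params.bf)
    i = _sigmoid(u_t @ params.Wix.T + h_prev @ params.Wih.T + params.bi)
    o = _sigmoid(u_t @ params.Wox.T + h_prev @ params.Woh.T + params.bo)
    g = np.tanh(u_t @ params.Wcx.T + h_prev @ params.Wch.T + params.bc)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    gates = {"f": f.squeeze(), "i": i.squeeze(), "o": o.squeeze(),
             "candidate": g.squeeze()}
    return h.squeeze() if h.shape[0] == 1 else h, \
        c.squeeze() if c.shape[0] == 1 else c, gates


@dataclass
class LSTMClassifier:
    params: LSTMParams
    Wy: np.ndarray          # (J, hidden)
    by: np.ndarray          # (J,)
    classes: np.ndarray
    history: dict = field(default_factory=dict, repr=False)


def _forward(params: LSTMParams, Wy, by, X):
    """X: (N, T, D).  Returns caches for BPTT and final softmax probs."""
    N, T, D = X.shape
    Hn = params.hidden_size
    h = np.zeros((N, Hn))
    c = np.zeros((N, Hn))
    cache = []
    for t in range(T):
        u = X[:, t, :]
        f = _sigmoid(u @ params.Wfx.T + h @ params.Wfh.T + params.bf)
        i = _sigmoid(u @ params.Wix.T + h @ params.Wih.T + params.bi)
        o = _sigmoid(u @ params.Wox.T + h @ params.Woh.T + params.bo)
        g = np.tanh(u @ params.Wcx.T + h @ params.Wch.T + params.bc)
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache.append((u, h, c, f, i, o, g, c_new, tanh_c))
        h, c = h_new, c_new
    logits = h @ Wy.T + by
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return h, probs, cache


def _backward(params: LSTMParams, Wy, by, probs, O, h_final, cache):
    """Gradients of mean cross-entropy; returns (param grads dict, dWy, dby)."""
    N = probs.shape[0]
    dlogits = (probs - O) / N
    dWy = dlogits.T @ h_final
    dby = dlogits.sum(axis=0)
    dh = dlogits @ Wy
    dc = np.zeros((N, params.hidden_size))
    grads = {name: np.zeros_like(getattr(params, name)) for name in params.fields()}
    for t in reversed(range(len(cache))):
        u, h_prev, c_prev, f, i, o, g, c_new, tanh_c = cache[t]
        do = dh * tanh_c
        dc = dc + dh * o * (1 - tanh_c**2)
        df = dc * c_prev
        di = dc * g
        dg = dc * i
        # through the nonlinearities
        do_pre = do * o * (1 - o)
        df_pre = df * f * (1 - f)
        di_pre = di * i * (1 - i)
        dg_pre = dg * (1 - g**2)
        grads["Wox"] += do_pre.T @ u
        grads["Woh"] += do_pre.T @ h_prev
        grads["bo"] += do_pre.sum(axis=0)
        grads["Wfx"] += df_pre.T @ u
        grads["Wfh"] += df_pre.T @ h_prev
        grads["bf"] += df_pre.sum(axis=0)
        grads["Wix"] += di_pre.T @ u
        grads["Wih"] += di_pre.T @ h_prev
        grads["bi"] += di_pre.sum(axis=0)
        grads["Wcx"] += dg_pre.T @ u
        grads["Wch"] += dg_pre.T @ h_prev
        grads["bc"] += dg_pre.sum(axis=0)
        dh = (
            do_pre @ params.Woh
            + df_pre @ params.Wfh
            + di_pre @ params.Wih
            + dg_pre @ params.Wch
        )
        dc = dc * f
    return grads, dWy, dby


def lstm_fit(
    sequences: np.ndarray,
    labels: np.ndarray,
    hidden_size: int = 16,
    epochs: int = 200,
    lr: float = 0.5,
    seed: int = 0,
    clip: float = 5.0,
    classes=None,
) -> LSTMClassifier:
    """Train the LSTM + softmax readout by full-batch gradient descent.

    ``sequences`` is (N, T, D), or (N, D) for single-step sequences.  Raises
    if the loss diverges to NaN (lower the learning rate).
    """
    from .tsk import one_hot

    X = np.asarray(sequences, dtype=float)
    if X.ndim == 2:
        X = X[:, None, :]
    if X.ndim != 3:
        raise ValueError("sequences must be (N, T, D) or (N, D)")
    O, classes = one_hot(labels, classes)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    N, T, D = X.shape
    rng = np.random.default_rng(seed)
    params = LSTMParams.init(D, hidden_size, rng)
    Wy = rng.standard_normal((len(classes), hidden_size)) / np.sqrt(hidden_size)
    by = np.zeros(len(classes))

    losses = np.empty(epochs)
    for ep in range(epochs):
        h, probs, cache = _forward(params, Wy, by, X)
        loss = -np.mean(np.log(np.maximum((probs * O).sum(axis=1), 1e-300)))
        if not np.isfinite(loss):
            raise FloatingPointError(
                "LSTM training diverged (NaN loss); lower the learning rate"
            )
        losses[ep] = loss
        grads, dWy, dby = _backward(params, Wy, by, probs, O, h, cache)
        gnorm = np.sqrt(
            sum(np.sum(g**2) for g in grads.values())
            + np.sum(dWy**2)
            + np.sum(dby**2)
        )
        scale = lr * (clip / gnorm if gnorm > clip else 1.0)
        for name in params.fields():
            setattr(params, name, getattr(params, name) - scale * grads[name])
        Wy -= scale * dWy
        by -= scale * dby
    return LSTMClassifier(
        params=params, Wy=Wy, by=by, classes=classes,
        history={"loss": losses, "final_loss": float(losses[-1]) if epochs else None},
    )


def lstm_predict(clf: LSTMClassifier, sequences: np.ndarray) -> np.ndarray:
    X = np.asarray(sequences, dtype=float)
    if X.ndim == 2:
        X = X[:, None, :]
    _, probs, _ = _forward(clf.params, clf.Wy, clf.by, X)
    return clf.classes[probs.argmax(axis=1)]
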