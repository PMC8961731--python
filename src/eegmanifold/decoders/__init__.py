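"""The four decoding models behind one fit/predict contract.

Every decoder exposes ``fit(X, y, groups=None)`` and
``predict(X, groups=None)`` over per-epoch feature rows.  ``groups`` carries
trial membership: the Kalman decoder filters each trial's epochs as a
time-ordered sequence and broadcasts the trial decision to its epochs; the
other decoders ignore it.
"""

from __future__ import annotations

import numpy as np

from .bayes import NBModel, nb_fit, nb_predict
from .fcm import FCMResult, fcm
from .kalman import KFModel, kf_decode, kf_filter, kf_fit, steady_state_gain
from .lstm import (
    LSTMClassifier,
    LSTMParams,
    lstm_fit,
    lstm_predict,
    lstm_step,
)
from .tsk import (
    FuzzyRule,
    TSKModel,
    design_matrix,
    export_rules,
    firing_strengths,
    membership_eval,
    one_hot,
    rule_eval,
    tsk_fit,
    tsk_predict,
    tsk_scores,
)

__all__ = [
    "FCMResult", "fcm",
    "FuzzyRule", "TSKModel", "tsk_fit", "tsk_predict", "tsk_scores",
    "rule_eval", "membership_eval", "firing_strengths", "design_matrix",
    "export_rules", "one_hot",
    "NBModel", "nb_fit", "nb_predict",
    "KFModel", "kf_fit", "kf_decode", "kf_filter", "steady_state_gain",
    "LSTMParams", "LSTMClassifier", "lstm_step", "lstm_fit", "lstm_predict",
    "TSKDecoder", "NBDecoder", "KalmanDecoder", "LSTMDecoder", "make_decoder",
    "DECODERS",
]


class TSKDecoder:
    """TSK fuzzy system under the common decoder contract."""

    def __init__(self, K: int = 5, scale: float = 1.0, m: float = 2.0,
                 ridge: float = 1e-6, seed: int | None = 0):
        self.K, self.scale, self.m, self.ridge, self.seed = K, scale, m, ridge, seed
        self.model: TSKModel | None = None

    def fit(self, X, y, groups=None):
        self.model = tsk_fit(X, y, K=self.K, scale=self.scale, m=self.m,
                             ridge=self.ridge, seed=self.seed)
        return self

    def predict(self, X, groups=None):
        _, _, labels = tsk_predict(self.model, np.atleast_2d(X))
        return labels


class NBDecoder:
    def __init__(self, seed: int | None = None):
        self.model: NBModel | None = None

    def fit(self, X, y, groups=None):
        self.model = nb_fit(X, y)
        return self

    def predict(self, X, groups=None):
        _, labels = nb_predict(self.model, np.atleast_2d(X))
        return labels


class KalmanDecoder:
    """Per-trial sequence filtering; the trial label is broadcast to epochs."""

    def __init__(self, seed: int | None = None, n_init: int = 3):
        self.n_init = n_init
        self.model: KFModel | None = None

    def fit(self, X, y, groups=None):
        self.model = kf_fit(X, y, trial_ids=groups, n_init=self.n_init)
        return self

    def predict(self, X, groups=None):
        X = np.atleast_2d(X)
        if groups is None:
            groups = np.arange(len(X))
        groups = np.asarray(groups)
        out = np.empty(len(X), dtype=self.model.classes.dtype)
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            _, label = kf_decode(self.model, X[idx])
            out[idx] = label
        return out


class LSTMDecoder:
    """Each epoch's feature vector is a single-step sequence."""

    def __init__(self, hidden_size: int = 16, epochs: int = 150, lr: float = 0.5,
                 seed: int = 0):
        self.hidden_size, self.epochs, self.lr, self.seed = hidden_size, epochs, lr, seed
        self.clf: LSTMClassifier | None = None

    def fit(self, X, y, groups=None):
        self.clf = lstm_fit(np.atleast_2d(X), y, hidden_size=self.hidden_size,
                            epochs=self.epochs, lr=self.lr, seed=self.seed)
        return self

    def predict(self, X, groups=None):
        return lstm_predict(self.clf, np.atleast_2d(X))


DECODERS = {
    "tsk": TSKDecoder,
    "nb": NBDecoder,
    "lstm": LSTMDecoder,
    "kf": KalmanDecoder,
    "kalman": KalmanDecoder,
}


def make_decoder(name: str, seed: int | None = 0, **kwargs):
    """Instantiate a decoder by name ('tsk', 'nb', 'lstm', 'kf')."""
    try:
        cls = DECODERS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown decoder {name!r}; choose from {sorted(set(DECODERS))}")
    return cls(seed=seed, **kwargs)
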