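"""Takagi-Sugeno-Kang (TSK) fuzzy-system decoder.

Each of K rules pairs a Gaussian antecedent over the d inputs,

    mu_k(u) = prod_i exp( -(u_i - c_i^k)^2 / delta_i^k ),

with an affine consequent f_k(u) = beta_0^k + beta_1^k u_1 + ... per output
class.  Rule centers come from fuzzy c-means; widths are the
membership-weighted variances about each center scaled by a constant l.  The
decoder output is the firing-strength-weighted mixture of rule consequents,
written compactly as o = beta_g^T rho(u) with
rho(u) = [mu~_1(u)(1,u), ..., mu~_K(u)(1,u)], and beta_g is fitted by
ridge-regularized least squares against one-hot class labels (the minimal
objective consistent with the linear readout).  The predicted class is the
argmax score, lowest index winning ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcm import FCMResult, fcm


@dataclass
class FuzzyRule:
    center: np.ndarray        # (d,)
    width: np.ndarray         # (d,), positive
    coeffs: np.ndarray | None = None  # (J, d+1); [:, 0] are intercepts

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.width = np.asarray(self.width, dtype=float)
        if np.any(self.width <= 0):
            raise ValueError("rule widths must be strictly positive")
        if self.coeffs is not None:
            self.coeffs = np.asarray(self.coeffs, dtype=float)


@dataclass
class TSKModel:
    rules: list[FuzzyRule]
    beta_g: np.ndarray                # (K*(d+1), J)
    classes: np.ndarray
    scale: float
    m: float
    ridge: float
    fcm_result: FCMResult | None = field(default=None, repr=False)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def n_inputs(self) -> int:
        return len(self.rules[0].center)


def membership_eval(center, width, u) -> float | np.ndarray:
    """Gaussian rule membership: product over input dimensions.

    Equals 1 exactly at u == center and decreases monotonically with
    |u - center|; larger widths give larger memberships off-center.
    """
    center = np.asarray(center, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(width <= 0):
        raise ValueError("width must be strictly positive")
    u = np.asarray(u, dtype=float)
    z = (u - center) ** 2 / width
    return np.exp(-z.sum(axis=-1))


def rule_eval(coeffs, u) -> np.ndarray:
    """Affine consequent f_k(u): one value per output class.

    ``coeffs`` is (J, d+1) with intercepts in column 0.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    u = np.asarray(u, dtype=float)
    if coeffs.shape[1] != u.shape[-1] + 1:
        raise ValueError("coefficient/input dimension mismatch")
    return coeffs[:, 0] + u @ coeffs[:, 1:].T


def _log_memberships(model: TSKModel, U: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log mu_k(u_n)."""
    logs = np.empty((U.shape[0], model.n_rules))
    for k, rule in enumerate(model.rules):
        z = (U - rule.center) ** 2 / rule.width
        logs[:, k] = -z.sum(axis=1)
    return logs


def firing_strengths(model: TSKModel, U: np.ndarray) -> np.ndarray:
    """Normalized strengths mu~_k(u); rows sum to 1 (softmax of log mu)."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    logs = _log_memberships(model, U)
    logs -= logs.max(axis=1, keepdims=True)
    w = np.exp(logs)
    return w / w.sum(axis=1, keepdims=True)


def design_matrix(model: TSKModel, U: np.ndarray) -> np.ndarray:
    """Rows rho(u_n) = [mu~_1 (1,u), ..., mu~_K (1,u)] of shape (n, K(d+1))."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    n, d = U.shape
    strengths = firing_strengths(model, U)
    ue = np.concatenate([np.ones((n, 1)), U], axis=1)  # (n, d+1)
    return (strengths[:, :, None] * ue[:, None, :]).reshape(n, -1)


def one_hot(labels, classes=None) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes)
    O = (labels[:, None] == classes[None, :]).astype(float)
    if not np.all(O.sum(axis=1) == 1):
        raise ValueError("labels contain values outside the class set")
    return O, classes


def tsk_fit(
    U: np.ndarray,
    labels: np.ndarray,
    K: int = 5,
    scale: float = 1.0,
    m: float = 2.0,
    ridge: float = 1e-6,
    seed: int | None = None,
    classes=None,
) -> TSKModel:
    """Fit a K-rule TSK decoder to labelled points.

    Antecedents from FCM (centers; widths = scale x membership-weighted
    variance per dimension); consequents by ridge least squares of the
    design matrix against one-hot labels.
    """
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if not np.all(np.isfinite(U)):
        raise ValueError("inputs contain non-finite values")
    n, d = U.shape
    if K > n:
        raise ValueError("cannot have more rules than samples")
    O, classes = one_hot(labels, classes)

    result = fcm(U, K, m=m, seed=seed)
    x = result.memberships  # (n, K)
    rules = []
    for k in range(K):
        w = x[:, k]
        denom = max(w.sum(), 1e-12)
        var = (w[:, None] * (U - result.centers[k]) ** 2).sum(axis=0) / denom
        width = scale * var
        if np.any(width <= 0):
            raise ValueError(
                f"rule {k} got a non-positive width; cluster is degenerate "
                "(try fewer rules or jittered inputs)"
            )
        rules.append(FuzzyRule(center=result.centers[k], width=width))

    model = TSKModel(
        rules=rules,
        beta_g=np.zeros((K * (d + 1), len(classes))),
        classes=classes,
        scale=scale,
        m=m,
        ridge=ridge,
        fcm_result=result,
    )
    R = design_matrix(model, U)
    G = R.T @ R
    if ridge > 0:
        G = G + ridge * np.eye(G.shape[0])
    try:
        beta_g = np.linalg.solve(G, R.T @ O)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular design matrix; refit with ridge > 0"
        ) from exc
    model.beta_g = beta_g
    # expose per-rule consequents (J, d+1) for inspection/export
    for k, rule in enumerate(model.rules):
        rule.coeffs = beta_g[k * (d + 1) : (k + 1) * (d + 1)].T
    return model


def tsk_scores(model: TSKModel, U: np.ndarray) -> np.ndarray:
    """Class scores o~ = beta_g^T rho(u) for each input row."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if not np.all(np.isfinite(U)):
        raise ValueError("inputs contain non-finite values")
    return design_matrix(model, U) @ model.beta_g


def tsk_predict(model: TSKModel, u: np.ndarray):
    """Scores, one-hot decision and label for one input (or a batch).

    The decision sets the maximal score to 1 and the rest to 0; ties go to
    the lowest class index.
    """
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    scores = tsk_scores(model, u)
    idx = scores.argmax(axis=1)  # np.argmax takes the first (lowest) maximum
    decision = np.zeros_like(scores)
    decision[np.arange(len(idx)), idx] = 1.0
    labels = model.classes[idx]
    if single:
        return scores[0], decision[0], labels[0]
    return scores, decision, labels


def export_rules(model: TSKModel) -> list[dict]:
    """Human-readable IF-THEN rules with linguistic labels by center rank.

    Each input dimension's rule centers are ranked and named very low … very
    high (as many distinct labels as rules), mirroring how fitted fuzzy sets
    are usually displayed.
    """
    K = model.n_rules
    base = ["very low", "low", "medium", "high", "very high"]
    if K <= len(base):
        names = [base[int(round(i * (len(base) - 1) / max(K - 1, 1)))] for i in range(K)]
    else:
        names = [f"level {i+1}" for i in range(K)]
    centers = np.stack([r.center for r in model.rules])
    out = []
    for k, rule in enumerate(model.rules):
        terms = []
        for i in range(model.n_inputs):
            rank = int(np.argsort(np.argsort(centers[:, i]))[k])
            terms.append(f"x{i+1} is {names[min(rank, len(names) - 1)]}")
        out.append(
            {
                "rule": k + 1,
                "if": " AND ".join(terms),
                "center": rule.center.tolist(),
                "width": rule.width.tolist(),
                "consequents": None if rule.coeffs is None else rule.coeffs.tolist(),
            }
        )
    return out
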