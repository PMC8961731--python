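"""Latent-factor extraction and manifold-dynamics analyses.

Brain states (epoch feature vectors) are smoothed within trials, reduced to
two latent factors by PCA or t-SNE, and examined as population dynamics:
cluster similarity across tasks, per-trial temporal trajectories with a
closure measure, and a bifurcation view that projects each state onto two
reference states through partial correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .tsne import tsne_embed

logger = logging.getLogger(__name__)


@dataclass
class Embedding:
    """n x d latent factors plus per-point metadata."""

    points: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    labels: np.ndarray | None = None
    trial_ids: np.ndarray | None = None
    time_ids: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("embedding contains non-finite coordinates")
        for meta in (self.labels, self.trial_ids, self.time_ids):
            if meta is not None and len(meta) != len(self.points):
                raise ValueError("metadata length must match number of points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.points, columns=[f"dim{i+1}" for i in range(self.points.shape[1])]
        )
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        if self.trial_ids is not None:
            df.insert(0, "trial", self.trial_ids)
        if self.time_ids is not None:
            df.insert(1, "time", self.time_ids)
        return df


@dataclass
class SimilarityMatrix:
    """Task-pair similarity; higher is more similar, self-similarity maximal."""

    values: pd.DataFrame
    convention: str


def smooth(
    features: np.ndarray,
    kernel_width: float,
    trial_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Per-feature temporal Gaussian smoothing, independently within each trial.

    ``kernel_width`` is the Gaussian sigma in samples (rows); 0 is the
    identity.  Rows are assumed time-ordered within each trial.
    """
    features = np.asarray(features, dtype=float)
    if kernel_width < 0:
        raise ValueError("kernel_width must be non-negative")
    if kernel_width == 0:
        return features.copy()
    if trial_ids is None:
        trial_ids = np.zeros(len(features), dtype=int)
    trial_ids = np.asarray(trial_ids)
    out = np.empty_like(features)
    for t in np.unique(trial_ids):
        mask = trial_ids == t
        n = int(mask.sum())
        if kernel_width > n:
            raise ValueError(
                f"kernel width {kernel_width} exceeds trial length {n}"
            )
        out[mask] = gaussian_filter1d(features[mask], sigma=kernel_width, axis=0)
    return out


def pca(
    features: np.ndarray,
    n_components: int = 2,
    labels=None,
    trial_ids=None,
    time_ids=None,
) -> Embedding:
    """Mean-centered SVD projection onto the leading principal components.

    The returned embedding's params carry the per-component explained
    variance fractions and the cumulative curve over all components.
    """
    X = np.asarray(features, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_components > p:
        raise ValueError("n_components cannot exceed feature dimension")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2 / (n - 1)
    total = var.sum()
    evr = var / total if total > 0 else np.zeros_like(var)
    points = U[:, :n_components] * S[:n_components]
    return Embedding(
        points=points,
        method="pca",
        params={
            "explained_variance_ratio": evr,
            "cumulative_explained_variance": np.cumsum(evr),
            "components": Vt[:n_components],
        },
        labels=None if labels is None else np.asarray(labels),
        trial_ids=None if trial_ids is None else np.asarray(trial_ids),
        time_ids=None if time_ids is None else np.asarray(time_ids),
    )


def dims_for_variance(embedding_or_evr, fraction: float = 0.8) -> int:
    """Number of leading components needed to explain ``fraction`` of variance."""
    if isinstance(embedding_or_evr, Embedding):
        cum = embedding_or_evr.params["cumulative_explained_variance"]
    else:
        cum = np.cumsum(np.asarray(embedding_or_evr))
    return int(np.searchsorted(cum, fraction - 1e-12) + 1)


def tsne(
    features: np.ndarray,
    perplexity: float = 30.0,
    n_dims: int = 2,
    n_iter: int = 1000,
    seed: int = 0,
    labels=None,
    trial_ids=None,
    time_ids=None,
    **kwargs,
) -> Embedding:
    """t-SNE embedding of epoch features; see :mod:`eegmanifold.tsne`."""
    Y, diag = tsne_embed(
        features,
        perplexity=perplexity,
        n_dims=n_dims,
        n_iter=n_iter,
        seed=seed,
        **kwargs,
    )
    return Embedding(
        points=Y,
        method="tsne",
        params=diag,
        labels=None if labels is None else np.asarray(labels),
        trial_ids=None if trial_ids is None else np.asarray(trial_ids),
        time_ids=None if time_ids is None else np.asarray(time_ids),
    )


def cluster_similarity(emb: Embedding) -> SimilarityMatrix:
    """Similarity between task clusters in the embedding.

    similarity(A, B) = 1 / (1 + mean Euclidean distance over all point pairs
    (a in A, b in B)); the full cross product is used for within-cluster
    similarity too, so two coincident clusters score exactly their common
    within-cluster value.  The matrix is symmetric with maximal diagonal.
    """
    if emb.labels is None:
        raise ValueError("embedding has no labels")
    labels = np.asarray(emb.labels)
    uniq = [u for u in pd.unique(labels)]
    if len(uniq) < 2:
        raise ValueError("need at least two labelled clusters")
    groups = {u: emb.points[labels == u] for u in uniq}
    mat = np.empty((len(uniq), len(uniq)))
    for i, a in enumerate(uniq):
        for j, b in enumerate(uniq):
            if j < i:
                continue
            d = np.linalg.norm(groups[a][:, None] - groups[b][None, :], axis=-1)
            mat[i, j] = mat[j, i] = 1.0 / (1.0 + d.mean())
    df = pd.DataFrame(mat, index=uniq, columns=uniq)
    return SimilarityMatrix(
        values=df, convention="1/(1 + mean pairwise Euclidean distance)"
    )


@dataclass
class TrajectorySet:
    """Time-ordered per-trial paths in the embedding, plus per-task means."""

    paths: dict[int, np.ndarray]
    trial_labels: dict[int, object]
    closure: dict[int, float]
    mean_paths: dict[object, np.ndarray]
    resample_points: int


def _resample_path(path: np.ndarray, n: int) -> np.ndarray:
    t_old = np.linspace(0, 1, len(path))
    t_new = np.linspace(0, 1, n)
    return np.stack(
        [np.interp(t_new, t_old, path[:, j]) for j in range(path.shape[1])], axis=1
    )


def path_length(path: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def trajectories(emb: Embedding, resample_points: int = 100) -> TrajectorySet:
    """Connect consecutive brain states within each trial.

    Trials shorter than 3 points are excluded (logged).  Each trial path is
    reported with a closure metric, distance(first, last)/path length, small
    for cyclic manifolds.  Per-task average paths are pointwise means after
    linear resampling of every trial to a common length.
    """
    if emb.trial_ids is None or emb.time_ids is None:
        raise ValueError("embedding needs trial and time indices")
    paths, trial_labels, closure = {}, {}, {}
    for t in np.unique(emb.trial_ids):
        mask = emb.trial_ids == t
        if mask.sum() < 3:
            logger.info("trial %s has fewer than 3 points; excluded", t)
            continue
        order = np.argsort(emb.time_ids[mask])
        path = emb.points[mask][order]
        paths[int(t)] = path
        trial_labels[int(t)] = emb.labels[mask][0] if emb.labels is not None else None
        L = path_length(path)
        closure[int(t)] = float(
            np.linalg.norm(path[-1] - path[0]) / L if L > 0 else 0.0
        )
    mean_paths = {}
    by_label: dict[object, list] = {}
    for t, path in paths.items():
        by_label.setdefault(trial_labels[t], []).append(
            _resample_path(path, resample_points)
        )
    for lab, plist in by_label.items():
        mean_paths[lab] = np.mean(plist, axis=0)
    return TrajectorySet(
        paths=paths,
        trial_labels=trial_labels,
        closure=closure,
        mean_paths=mean_paths,
        resample_points=resample_points,
    )


def _partial_correlation(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """corr(x, a | b): correlate residuals after regressing b (plus intercept) out."""
    design = np.stack([np.ones_like(b), b], axis=1)
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ra = a - design @ np.linalg.lstsq(design, a, rcond=None)[0]
    nx, na = np.linalg.norm(rx), np.linalg.norm(ra)
    if nx < 1e-12 or na < 1e-12:
        return 0.0
    return float(np.clip(rx @ ra / (nx * na), -1.0, 1.0))


def bifurcation_projection(
    states: np.ndarray, ref_a: np.ndarray, ref_b: np.ndarray
) -> np.ndarray:
    """Project states onto a 2-D plane spanned by two reference states.

    Coordinate 1 is the partial correlation of the state with ``ref_a``
    controlling for ``ref_b``; coordinate 2 the converse.  A zero-variance
    state yields a NaN row (missing point).
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    ref_a = np.asarray(ref_a, dtype=float)
    ref_b = np.asarray(ref_b, dtype=float)
    if states.shape[1] != ref_a.size or ref_a.size != ref_b.size:
        raise ValueError("states and references must share dimensionality")
    out = np.empty((states.shape[0], 2))
    for i, s in enumerate(states):
        if s.std() < 1e-15:
            out[i] = np.nan
            continue
        out[i, 0] = _partial_correlation(s, ref_a, ref_b)
        out[i, 1] = _partial_correlation(s, ref_b, ref_a)
    return out
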