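"""Cross-validated decoding experiments and pipeline-level analyses.

The decoding sample unit is one 1-s epoch (0.5-s overlap) cut from the early
stimulus window of each trial; trial labels are broadcast to epochs.  Two
latent-factor paths feed the decoders:

* **t-SNE path** — per-channel alpha band power per epoch, smoothed within
  trials, embedded to two dimensions; the embedding coordinates are the
  decoder inputs.  t-SNE has no out-of-sample transform, so the default
  reproduces the transductive embed-then-split protocol (all epochs embedded
  once, folds split afterwards).  This leaks test epochs into the embedding;
  ``strict=True`` keeps folds trial-grouped so overlapping epochs of one
  trial can never straddle a fold boundary.
* **PCA path** — the multichannel epoch series is projected onto the two
  leading spatial principal components and the alpha band power of each
  projected series over the epoch is the (2-D) decoder input.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .decoders import make_decoder
from .io import EpochSet, Recording
from .manifold import pca, smooth, tsne
from .montage import LOBES
from .preprocess import BAND_EDGES, band_filter, bandpass, epoch, select_lobes
from .spectral import band_power, batch_band_power

ALPHA = BAND_EDGES["alpha"]


@dataclass
class CVReport:
    """Repeated stratified k-fold results for one decoder on one feature set."""

    accuracies: np.ndarray          # (repeats, k)
    confusion: np.ndarray           # summed over folds and repeats
    classes: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean(axis=1).mean())

    @property
    def std(self) -> float:
        """Standard deviation over the repeats' averages."""
        return float(self.accuracies.mean(axis=1).std(ddof=1)) if len(self.accuracies) > 1 else 0.0

    def __repr__(self):
        return f"CVReport(mean={self.mean:.4f}, std={self.std:.4f}, {self.metadata})"


def crossval(
    features: np.ndarray,
    labels: np.ndarray,
    decoder,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    groups: np.ndarray | None = None,
    decoder_kwargs: dict | None = None,
) -> CVReport:
    """Repeated stratified k-fold cross-validation of one decoder.

    ``decoder`` is a name ('tsk', 'nb', 'lstm', 'kf') or a factory
    ``f(seed) -> object`` with fit/predict.  With ``groups`` set, folds are
    stratified *and* group-aware (epochs of one trial stay together) and the
    group ids are forwarded to the decoder.  The report aggregates each
    repeat's fold-average accuracy; mean and s.d. are over repeats.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    if groups is not None:
        groups = np.asarray(groups)

    if isinstance(decoder, str):
        name = decoder
        kwargs = decoder_kwargs or {}

        def factory(s):
            return make_decoder(name, seed=s, **kwargs)
    else:
        factory = decoder
        name = getattr(decoder, "__name__", repr(decoder))

    rng = np.random.default_rng(seed)
    accs = np.empty((repeats, k))
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for rep in range(repeats):
        rep_seed = int(rng.integers(2**31 - 1))
        if groups is None:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            splits = splitter.split(X, y)
        else:
            splitter = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=rep_seed)
            splits = splitter.split(X, y, groups)
        for fold, (tr, te) in enumerate(splits):
            model = factory(rep_seed + fold)
            model.fit(X[tr], y[tr], groups=None if groups is None else groups[tr])
            pred = model.predict(X[te], groups=None if groups is None else groups[te])
            accs[rep, fold] = float(np.mean(pred == y[te]))
            conf += confusion_matrix(y[te], pred, labels=classes)
    return CVReport(
        accuracies=accs,
        confusion=conf,
        classes=classes,
        metadata={
            "decoder": name,
            "k": k,
            "repeats": repeats,
            "seed": seed,
            "n_samples": len(y),
            "grouped": groups is not None,
        },
    )


# ---------------------------------------------------------------------------
# feature paths


def alpha_epochs(
    rec: Recording,
    window: float = 1.0,
    overlap: float = 0.5,
    cap: float = 10.0,
    classes=None,
) -> EpochSet:
    """Broadband (0.1-50 Hz) epochs from the early stimulus window of each trial.

    The AR spectrum is fitted on the broadband signal and averaged over the
    alpha grid afterwards; fitting on an already band-limited signal leaves a
    near-line spectrum whose needle peaks a coarse grid samples erratically.
    """
    if classes is None:
        classes = sorted({ev.label for ev in rec.events if ev.label != 0})
    high = min(50.0, 0.45 * rec.fs)
    broad = bandpass(rec, 0.1, high, order=4)
    return epoch(broad, window=window, overlap=overlap, restrict_to=classes,
                 max_duration=cap)


def alpha_power_features(
    epochs: EpochSet,
    order: int = 16,
    smooth_width: float = 1.0,
) -> np.ndarray:
    """Per-epoch, per-channel alpha band power, Gaussian-smoothed within trials."""
    bp = band_power(epochs, ALPHA, order=order)
    return smooth(bp, smooth_width, trial_ids=epochs.trial_ids)


def tsne_features(
    epochs: EpochSet,
    order: int = 16,
    smooth_width: float = 1.0,
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
) -> np.ndarray:
    """2-D t-SNE latent factors of the alpha band-power feature table."""
    bp = alpha_power_features(epochs, order=order, smooth_width=smooth_width)
    emb = tsne(bp, perplexity=min(perplexity, (len(bp) - 1) / 3), seed=seed,
               n_iter=n_iter, labels=epochs.labels, trial_ids=epochs.trial_ids,
               time_ids=epochs.time_ids)
    return emb.points


def pca_features(epochs: EpochSet, order: int = 16) -> np.ndarray:
    """Alpha band power of the two leading spatial PCs, per epoch.

    PCA is fitted over all epoch samples stacked in time (samples x
    channels), each epoch is projected to two component series, and the band
    power of each projected series is the feature.
    """
    N, C, W = epochs.data.shape
    stacked = epochs.data.transpose(0, 2, 1).reshape(N * W, C)
    emb = pca(stacked, n_components=2)
    comps = emb.params["components"]  # (2, C)
    projected = np.einsum("ncw,jc->njw", epochs.data - stacked.mean(axis=0)[None, :, None],
                          comps)  # (N, 2, W)
    flat = projected.reshape(N * 2, W)
    powers = batch_band_power(flat, epochs.fs, ALPHA, order=order)
    return powers.reshape(N, 2)


# ---------------------------------------------------------------------------
# experiment grids


def reducer_decoder_grid(
    epochs: EpochSet,
    reducers: tuple[str, ...] = ("pca", "tsne"),
    decoders: tuple[str, ...] = ("tsk", "nb", "lstm", "kf"),
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    order: int = 16,
    strict: bool = False,
    tsne_iter: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Accuracy for every reducer x decoder combination.

    Returns (accuracy DataFrame reducers x decoders, dict of CVReports keyed
    by (reducer, decoder)).
    """
    feats = {}
    for red in reducers:
        if red == "tsne":
            feats[red] = tsne_features(epochs, order=order, seed=seed, n_iter=tsne_iter)
        elif red == "pca":
            feats[red] = pca_features(epochs, order=order)
        else:
            raise ValueError(f"unknown reducer {red!r}")
    groups = epochs.trial_ids if strict else None
    reports = {}
    table = pd.DataFrame(index=list(reducers), columns=list(decoders), dtype=float)
    for red, dec in itertools.product(reducers, decoders):
        rep = crossval(feats[red], epochs.labels, dec, k=k, repeats=repeats,
                       seed=seed, groups=groups)
        rep.metadata["reducer"] = red
        reports[(red, dec)] = rep
        table.loc[red, dec] = rep.mean
    return table, reports


def lobe_combinations() -> list[tuple[str, ...]]:
    """4 singles, 6 pairs and 4 triples of the four lobes (14 rows)."""
    combos = []
    for r in (1, 2, 3):
        combos.extend(itertools.combinations(LOBES, r))
    return combos


def lobe_grid(
    epochs: EpochSet,
    decoder: str = "tsk",
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    order: int = 16,
    strict: bool = False,
    tsne_iter: int = 1000,
) -> pd.DataFrame:
    """Rerun the t-SNE + decoder pipeline on every lobe subset.

    Per-channel band powers are computed once on the full montage and
    subset per combination (band power is channel-local), then each subset
    gets its own t-SNE embedding and cross-validated decoding.  Returns a
    table ranked by accuracy within each combination size.
    """
    bp = alpha_power_features(epochs, order=order)
    names = epochs.channel_names
    groups = epochs.trial_ids if strict else None
    rows = []
    for combo in lobe_combinations():
        idx = [i for i, ch in enumerate(names) if epochs.lobe_map[ch] in combo]
        emb = tsne(bp[:, idx], perplexity=min(30.0, (len(bp) - 1) / 3), seed=seed,
                   n_iter=tsne_iter)
        rep = crossval(emb.points, epochs.labels, decoder, k=k, repeats=repeats,
                       seed=seed, groups=groups)
        rows.append(
            {
                "lobes": "+".join(combo),
                "n_lobes": len(combo),
                "n_channels": len(idx),
                "accuracy": rep.mean,
                "std": rep.std,
            }
        )
    df = pd.DataFrame(rows)
    df["rank_within_size"] = df.groupby("n_lobes")["accuracy"].rank(
        ascending=False, method="min"
    )
    return df.sort_values(["n_lobes", "accuracy"], ascending=[True, False]).reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# band-power report


def band_report(
    rec: Recording,
    window: float = 1.0,
    overlap: float = 0.5,
    order: int = 16,
    delta_low: float = 0.5,
) -> pd.DataFrame:
    """Per-band, per-state mean power by lobe, with change versus baseline.

    States are pre-stimulus rest, stimulus, and post-stimulus rest (rest
    events are tagged by their position relative to the neighbouring
    stimulus).  The change column is power relative to the pre-stimulus
    rest mean of the same band and lobe.  Group comparisons of such tables
    are standard ANOVA territory and are left to off-the-shelf routines.
    """
    from .preprocess import band_edges as make_edges

    states = _tag_states(rec)
    edges = make_edges(delta_low)
    rows = []
    eps = epoch(rec, window=window, overlap=overlap, restrict_to=None)
    for state, labels in states.items():
        if not labels:
            continue
        mask = np.isin(eps.trial_ids, labels)
        sub = eps.data[mask]
        if len(sub) == 0:
            continue
        sub_set = EpochSet(
            data=sub, labels=eps.labels[mask], trial_ids=eps.trial_ids[mask],
            time_ids=eps.time_ids[mask], fs=eps.fs, window=window, overlap=overlap,
            channel_names=eps.channel_names, lobe_map=eps.lobe_map,
        )
        for band, (lo, hi) in edges.items():
            bp = band_power(sub_set, (lo, hi), order=order)  # (n, C)
            per_channel = bp.mean(axis=0)
            for lobe in LOBES:
                idx = [i for i, ch in enumerate(eps.channel_names)
                       if eps.lobe_map[ch] == lobe]
                if idx:
                    rows.append({"band": band, "state": state, "lobe": lobe,
                                 "power": float(per_channel[idx].mean())})
    df = pd.DataFrame(rows)
    base = df[df.state == "pre"].set_index(["band", "lobe"])["power"]
    df["change_vs_pre"] = [
        row.power / base.get((row.band, row.lobe), np.nan) for row in df.itertuples()
    ]
    return df


def _tag_states(rec: Recording) -> dict[str, list[int]]:
    """Event index lists for pre-rest, stimulus, post-rest states."""
    states = {"pre": [], "stim": [], "post": []}
    evs = rec.events
    for i, ev in enumerate(evs):
        if ev.label != 0:
            states["stim"].append(i)
            if i > 0 and evs[i - 1].label == 0:
                states["pre"].append(i - 1)
            if i + 1 < len(evs) and evs[i + 1].label == 0:
                states["post"].append(i + 1)
    return states


# ---------------------------------------------------------------------------
# end-to-end convenience


def decode_recording(
    rec: Recording,
    reducer: str = "tsne",
    decoder: str = "tsk",
    lobes=None,
    window: float = 1.0,
    overlap: float = 0.5,
    cap: float = 10.0,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    order: int = 16,
    strict: bool = False,
    tsne_iter: int = 1000,
) -> CVReport:
    """Full pipeline on one recording: epochs -> latent factors -> CV decoding."""
    eps = alpha_epochs(rec, window=window, overlap=overlap, cap=cap)
    if lobes is not None:
        eps = select_lobes(eps, lobes)
    if reducer == "tsne":
        X = tsne_features(eps, order=order, seed=seed, n_iter=tsne_iter)
    elif reducer == "pca":
        X = pca_features(eps, order=order)
    else:
        raise ValueError(f"unknown reducer {reducer!r}")
    rep = crossval(X, eps.labels, decoder, k=k, repeats=repeats, seed=seed,
                   groups=eps.trial_ids if strict else None)
    rep.metadata.update({"reducer": reducer, "lobes": lobes, "strict": strict})
    return rep
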