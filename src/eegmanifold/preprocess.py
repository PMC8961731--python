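"""Temporal filtering, subband decomposition, epoching and lobe selection.

Filtering follows common EEG practice: a zero-phase (forward-backward)
Butterworth band-pass for the broadband 0.1-50 Hz stage, and an FFT-masking
(frequency-sampling FIR) filter for the delta/theta/alpha/beta split, so each
subband copy is exactly band-limited and sample-aligned with its source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .io import EpochSet, Event, Recording

logger = logging.getLogger(__name__)

#: Canonical subband edges in Hz.  The delta band is 0.5-4 Hz by default; a
#: 1 Hz lower edge is also in circulation and can be requested explicitly.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 15.0),
    "beta": (15.0, 30.0),
}


def band_edges(delta_low: float = 0.5) -> dict[str, tuple[float, float]]:
    edges = dict(BAND_EDGES)
    edges["delta"] = (delta_low, 4.0)
    return edges


@dataclass
class BandSignals:
    """One band-limited copy of a recording per subband."""

    bands: dict[str, Recording]
    edges: dict[str, tuple[float, float]]

    def __getitem__(self, name: str) -> Recording:
        return self.bands[name]


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass; shape and timing preserved."""
    nyq = rec.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"need 0 < low < high < fs/2, got ({low}, {high}) at fs={rec.fs}")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=1)
    if not np.all(np.isfinite(out)):
        raise ValueError(
            f"Butterworth design of order {order} is numerically unstable for "
            f"({low}, {high}) Hz at fs={rec.fs}; lower the order"
        )
    return rec.with_data(out)


def band_filter(rec: Recording, low: float, high: float) -> Recording:
    """FFT-masking band filter: zero all Fourier bins outside [low, high)."""
    n = rec.n_samples
    if low > 0 and n < 2 * rec.fs / low:
        raise ValueError(
            f"record of {n} samples is shorter than two cycles of {low} Hz; "
            "too short for this band filter"
        )
    spec = np.fft.rfft(rec.data, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    mask = (freqs >= low) & (freqs < high)
    out = np.fft.irfft(spec * mask, n=n, axis=1)
    return rec.with_data(out)


def decompose_bands(rec: Recording, delta_low: float = 0.5) -> BandSignals:
    """Split a recording into delta/theta/alpha/beta band-limited copies."""
    if rec.fs < 60:
        raise ValueError("sampling rate must be at least 60 Hz for the 15-30 Hz band")
    edges = band_edges(delta_low)
    bands = {name: band_filter(rec, lo, hi) for name, (lo, hi) in edges.items()}
    return BandSignals(bands=bands, edges=edges)


def remove_artifacts(rec: Recording, method=None) -> Recording:
    """Artifact-removal hook.

    Real recordings would be cleaned here (e.g. ICA-based component
    rejection); ``method`` may be any callable Recording -> Recording.  The
    default is a pass-through, appropriate for artifact-free synthetic data.
    """
    if method is None:
        return rec
    return method(rec)


def n_windows(duration_samples: int, window_samples: int, step_samples: int) -> int:
    """Number of sliding windows fully inside a segment."""
    if duration_samples < window_samples:
        return 0
    return (duration_samples - window_samples) // step_samples + 1


def epoch(
    rec: Recording,
    window: float = 1.0,
    overlap: float = 0.5,
    restrict_to: Iterable[int] | None = None,
    max_duration: float | None = None,
) -> EpochSet:
    """Cut labelled fixed-length windows out of a recording.

    Windows are slid within each event segment, so no window ever straddles a
    condition boundary; the trailing remainder of each segment is dropped and
    logged.  ``restrict_to`` keeps only events with the given labels and
    ``max_duration`` caps each kept segment (e.g. the first 10 s of each
    stimulus, where the evoked oscillation lives).
    """
    if not rec.events:
        raise ValueError("recording has no events to epoch against")
    if not 0 <= overlap < window:
        raise ValueError("need 0 <= overlap < window")
    if window > rec.duration:
        raise ValueError("window longer than the recording")
    w = int(round(window * rec.fs))
    step = int(round((window - overlap) * rec.fs))
    if step < 1:
        raise ValueError("window - overlap must be at least one sample")

    keep = None if restrict_to is None else set(restrict_to)
    chunks, labels, trial_ids, time_ids = [], [], [], []
    for trial, ev in enumerate(rec.events):
        if keep is not None and ev.label not in keep:
            continue
        dur = ev.duration
        if max_duration is not None:
            dur = min(dur, int(round(max_duration * rec.fs)))
        k = n_windows(dur, w, step)
        dropped = dur - ((k - 1) * step + w) if k else dur
        if dropped:
            logger.debug("event %d: dropping %d trailing samples", trial, dropped)
        for i in range(k):
            start = ev.onset + i * step
            chunks.append(rec.data[:, start : start + w])
            labels.append(ev.label)
            trial_ids.append(trial)
            time_ids.append(i)
    if not chunks:
        raise ValueError("no epochs produced; check window/restrict_to")
    return EpochSet(
        data=np.stack(chunks),
        labels=np.asarray(labels),
        trial_ids=np.asarray(trial_ids),
        time_ids=np.asarray(time_ids),
        fs=rec.fs,
        window=window,
        overlap=overlap,
        channel_names=list(rec.channel_names),
        lobe_map=dict(rec.lobe_map),
    )


def select_lobes(x: Recording | EpochSet, lobes: Sequence[str]):
    """Restrict a recording or epoch set to channels of the given lobes.

    Channel order is preserved; passing all four lobes is the identity.
    """
    lobes = set(lobes)
    if not lobes:
        raise ValueError("empty lobe selection")
    unknown = lobes - set(x.lobe_map.values()) - {"frontal", "temporal", "parietal", "occipital"}
    if unknown:
        raise ValueError(f"unknown lobes: {sorted(unknown)}")
    idx = [i for i, ch in enumerate(x.channel_names) if x.lobe_map[ch] in lobes]
    if not idx:
        raise ValueError(f"no channels mapped to lobes {sorted(lobes)}")
    names = [x.channel_names[i] for i in idx]
    lmap = {ch: x.lobe_map[ch] for ch in names}
    if isinstance(x, Recording):
        return Recording(
            data=x.data[idx],
            fs=x.fs,
            channel_names=names,
            lobe_map=lmap,
            events=list(x.events),
        )
    return EpochSet(
        data=x.data[:, idx, :],
        labels=x.labels,
        trial_ids=x.trial_ids,
        time_ids=x.time_ids,
        fs=x.fs,
        window=x.window,
        overlap=x.overlap,
        channel_names=names,
        lobe_map=lmap,
    )
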