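"""Recording/epoch containers and on-disk interchange.

A session is stored as a plain whitespace-delimited numeric matrix
(channels x samples, one row per channel) next to a JSON sidecar holding the
sampling rate, channel names, channel->lobe map and the event timeline.  The
round trip is lossless (floats are written with 17 significant digits).
EDF files can be read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import json

import numpy as np

from .montage import LOBES


class SchemaError(ValueError):
    """Sidecar is missing a required field or has the wrong structure."""


class Event(NamedTuple):
    """A labelled segment of the recording, in samples.

    ``label`` is 0 for rest and the digit (1-5) during a stimulus.
    """

    onset: int
    duration: int
    label: int


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples in microvolt-scale units."""

    data: np.ndarray
    fs: float
    channel_names: list[str]
    lobe_map: dict[str, str]
    events: list[Event] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN or infinite samples")
        for ch in self.channel_names:
            if ch not in self.lobe_map:
                raise ValueError(f"channel {ch!r} missing from lobe_map")
            if self.lobe_map[ch] not in LOBES:
                raise ValueError(f"unknown lobe {self.lobe_map[ch]!r}")
        self.events = [Event(*e) for e in self.events]
        for ev in self.events:
            if ev.onset < 0 or ev.onset + ev.duration > self.n_samples:
                raise ValueError(f"event {ev} outside record bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def label_timeline(self) -> np.ndarray:
        """Per-sample task label (0 = unlabelled/rest)."""
        out = np.zeros(self.n_samples, dtype=int)
        for ev in self.events:
            out[ev.onset : ev.onset + ev.duration] = ev.label
        return out

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


@dataclass
class EpochSet:
    """Fixed-length windows cut from a recording.

    ``data`` is epochs x channels x window_samples; ``labels`` holds the task
    label of each epoch; ``trial_ids`` indexes the source event and
    ``time_ids`` the window position within it.
    """

    data: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    time_ids: np.ndarray
    fs: float
    window: float
    overlap: float
    channel_names: list[str]
    lobe_map: dict[str, str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.trial_ids = np.asarray(self.trial_ids)
        self.time_ids = np.asarray(self.time_ids)
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.trial_ids) == len(self.time_ids) == n):
            raise ValueError("labels/trial_ids/time_ids must have one entry per epoch")
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if round(self.window * self.fs) != self.data.shape[2]:
            raise ValueError("window length inconsistent with sample count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# matrix + JSON sidecar interchange


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> Path:
    """Write ``rec`` as a text matrix plus JSON sidecar; returns the data path."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    np.savetxt(path, rec.data, fmt="%.17g", delimiter="\t")
    sidecar = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "lobe_map": dict(rec.lobe_map),
        "events": [[int(e.onset), int(e.duration), int(e.label)] for e in rec.events],
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh)
    return path


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise SchemaError(f"sidecar {sidecar_path} not found")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    for key in ("fs", "channel_names", "lobe_map", "events"):
        if key not in sidecar:
            raise SchemaError(f"sidecar missing required field {key!r}")
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    if not np.all(np.isfinite(data)):
        raise ValueError("data file contains NaN or infinite samples")
    return Recording(
        data=data,
        fs=float(sidecar["fs"]),
        channel_names=list(sidecar["channel_names"]),
        lobe_map=dict(sidecar["lobe_map"]),
        events=[Event(*map(int, e)) for e in sidecar["events"]],
    )


def read_edf(path, lobe_map: dict[str, str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (requires ``mne``).

    ``lobe_map`` may override the rule-based 10-10 assignment, e.g. for
    non-standard channel names.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF files requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    names = list(raw.ch_names)
    if lobe_map is None:
        from .montage import lobe_of

        lobe_map = {ch: lobe_of(ch) for ch in names}
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=names,
        lobe_map=lobe_map,
        events=[],
    )
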