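"""Standard 64-electrode 10-10 montage and its lobe partition.

The decoding pipeline groups scalp electrodes into four coarse regions
(frontal, temporal, parietal, occipital).  Published figures of such montages
show the grouping but rarely list it, so the partition here is rule-based on
the 10-10 electrode names and shipped as an editable JSON file alongside the
package: prefix rules are applied in order, with fronto-central (FC*) sites
counted as frontal and central (C*, CP*) sites as parietal.
"""

from __future__ import annotations

import json
from importlib import resources

LOBES = ("frontal", "temporal", "parietal", "occipital")

#: Electrode-name prefix -> lobe, applied in order (first match wins).
#: Longer prefixes come first so e.g. "FT7" is temporal, not frontal.
_PREFIX_RULES: tuple[tuple[str, str], ...] = (
    ("FT", "temporal"),
    ("TP", "temporal"),
    ("FP", "frontal"),
    ("AF", "frontal"),
    ("FC", "frontal"),
    ("PO", "occipital"),
    ("CP", "parietal"),
    ("T", "temporal"),
    ("F", "frontal"),
    ("C", "parietal"),
    ("P", "parietal"),
    ("O", "occipital"),
    ("I", "occipital"),   # Iz (inion)
    ("M", "temporal"),    # mastoids
)

#: 64 channels of an extended 10-10 layout.
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
)


def lobe_of(channel: str) -> str:
    """Assign a 10-10 electrode name to one of the four lobes."""
    name = channel.upper()
    for prefix, lobe in _PREFIX_RULES:
        if name.startswith(prefix):
            return lobe
    raise ValueError(f"cannot assign channel {channel!r} to a lobe")


def default_lobe_map(channels=CHANNELS_64) -> dict[str, str]:
    return {ch: lobe_of(ch) for ch in channels}


def load_montage(path=None) -> tuple[list[str], dict[str, str]]:
    """Load (channel names, lobe map) from a montage JSON file.

    With no path, the packaged 64-channel 10-10 montage is returned.
    """
    if path is None:
        ref = resources.files("eegmanifold.data") / "montage_10_10_64.json"
        raw = json.loads(ref.read_text())
    else:
        with open(path) as fh:
            raw = json.load(fh)
    channels = list(raw["channels"])
    lobe_map = dict(raw["lobe_map"])
    for ch in channels:
        if ch not in lobe_map:
            raise ValueError(f"montage file lacks a lobe for channel {ch!r}")
        if lobe_map[ch] not in LOBES:
            raise ValueError(f"unknown lobe {lobe_map[ch]!r} for channel {ch!r}")
    return channels, lobe_map
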