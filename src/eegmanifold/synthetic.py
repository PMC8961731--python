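"""Synthetic visual-stimulus EEG sessions with known ground truth.

The generator emulates the study conditions the pipeline was designed for:
64 scalp channels sampled at 1,000 Hz, trials of rest -> 30-s digit stimulus
-> rest for five digit classes, an alpha-band (8-15 Hz) power increase during
the stimulus concentrated in frontal and occipital channels (persisting for
the first part of the stimulus only), a delta-band power decrease, and a 1/f
background plus ongoing delta/theta/alpha/beta rhythms.

Each digit class is given its own signature: a distinct alpha carrier
frequency and a distinct random spatial weight vector with most of its mass
on frontal+occipital channels.  The class-conditional spectral differences of
real digit viewing are not characterised anywhere; this scheme simply makes
the classes separable through alpha-band features while keeping the
task-versus-rest physiology that *is* reported.

The evoked alpha amplitude is chosen so that in a fully weighted channel the
stimulus/rest alpha power ratio equals ``alpha_gain**2`` exactly (before
noise dilution): the added carrier has amplitude
``snr * sqrt(alpha_gain**2 - 1) * a0 * w`` on top of the baseline alpha
rhythm of amplitude ``a0``.  Setting ``snr=0`` therefore removes every
class-specific component while leaving the background untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Event, Recording
from .montage import CHANNELS_64, default_lobe_map

#: Baseline rhythm amplitudes (arbitrary microvolt-scale units) and carrier
#: frequencies for the ongoing background oscillations.
_BASELINE_RHYTHMS = {
    "delta": (2.5, 1.5),
    "theta": (6.0, 0.8),
    "alpha": (10.0, 1.0),
    "beta": (20.0, 0.5),
}
_ALPHA_BASE_AMP = _BASELINE_RHYTHMS["alpha"][1]
_NOISE_RMS = 0.5  # 1/f background RMS at noise_level = 1


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.

    Defaults mirror the emulated study: 64 channels, 1 kHz sampling, 30-s
    stimuli flanked by 30-s rests (60 s between consecutive stimuli), five
    digit classes, and an alpha response persisting for the first third
    (~10 s) of each stimulus.
    """

    n_channels: int = 64
    fs: float = 1000.0
    n_trials_per_class: int = 10
    classes: tuple[int, ...] = (1, 2, 3, 4, 5)
    stim_duration: float = 30.0
    rest_duration: float = 30.0
    alpha_gain: float = 2.0
    delta_attenuation: float = 0.7
    noise_exponent: float = 1.0
    snr: float = 1.0
    noise_level: float = 1.0
    responsive_mass: float = 0.8
    response_fraction: float = 1.0 / 3.0
    seed: int | None = None
    channel_names: tuple[str, ...] | None = None
    lobe_map: dict[str, str] | None = None

    def __post_init__(self):
        if self.stim_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("durations must be positive")
        if self.alpha_gain < 1:
            raise ValueError("alpha_gain must be >= 1")
        if not 0 < self.delta_attenuation <= 1:
            raise ValueError("delta_attenuation must be in (0, 1]")
        if self.snr < 0 or self.noise_level < 0:
            raise ValueError("snr and noise_level must be non-negative")
        if not 0 < self.response_fraction <= 1:
            raise ValueError("response_fraction must be in (0, 1]")
        if not 0 < self.responsive_mass <= 1:
            raise ValueError("responsive_mass must be in (0, 1]")
        highest = max(f for f, _ in _BASELINE_RHYTHMS.values())
        if self.fs <= 2 * highest:
            raise ValueError(f"fs must exceed twice the highest rhythm ({highest} Hz)")
        if self.channel_names is None:
            if self.n_channels == 64:
                self.channel_names = CHANNELS_64
            else:
                self.channel_names = tuple(f"ch{i:02d}" for i in range(self.n_channels))
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if self.lobe_map is None:
            if self.n_channels == 64:
                self.lobe_map = default_lobe_map(self.channel_names)
            else:
                # spread generic channels over the four lobes round-robin
                from .montage import LOBES

                self.lobe_map = {
                    ch: LOBES[i % 4] for i, ch in enumerate(self.channel_names)
                }


@dataclass
class GroundTruth:
    """What was injected: per-sample labels and per-class signatures."""

    timeline: np.ndarray
    spatial_patterns: dict[int, np.ndarray]
    carrier_freqs: dict[int, float]
    responsive_mask: np.ndarray = field(repr=False, default=None)


def _class_patterns(cfg: SessionConfig, rng: np.random.Generator):
    """Random per-class channel weights.

    A fraction ``responsive_mass`` of the total weight mass (default 80%)
    lies on frontal+occipital channels; ``responsive_mass=1`` confines the
    signal to those lobes entirely.
    """
    responsive = np.array(
        [cfg.lobe_map[ch] in ("frontal", "occipital") for ch in cfg.channel_names]
    )
    n_resp = int(responsive.sum())
    n_other = cfg.n_channels - n_resp
    other_over_resp = (1.0 - cfg.responsive_mass) / cfg.responsive_mass
    patterns = {}
    for label in cfg.classes:
        for _ in range(100):
            w = np.zeros(cfg.n_channels)
            w[responsive] = rng.uniform(0.2, 1.0, size=n_resp)
            if n_other and other_over_resp > 0:
                other = rng.uniform(0.2, 1.0, size=n_other)
                other *= other_over_resp * w[responsive].sum() / other.sum()
                w[~responsive] = other
            w /= w.max()
            ok = all(
                _cosine(w, p) < 0.95 for p in patterns.values()
            )
            if ok:
                patterns[label] = w
                break
        else:  # pragma: no cover - 100 draws of continuous vectors
            raise RuntimeError("could not draw distinct spatial patterns")
    return patterns, responsive


def _cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def _narrowband_source(
    rng, n_samples, fs, center, bandwidth: float = 1.0
) -> np.ndarray:
    """Narrowband stochastic oscillation at ``center`` Hz, RMS 1/sqrt(2).

    White noise band-limited to center +/- bandwidth/2 by FFT masking; its
    power matches a unit-amplitude sinusoid, so amplitude scalings translate
    directly into band-power ratios.
    """
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= center - bandwidth / 2) & (freqs <= center + bandwidth / 2)
    out = np.fft.irfft(spec * mask, n=n_samples)
    rms = out.std()
    return out / (rms if rms > 0 else 1.0) / np.sqrt(2.0)


def _pink_noise(rng, n_channels, n_samples, fs, exponent, rms):
    """1/f^exponent noise by spectral shaping of white noise."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    f0 = 0.5  # knee to keep DC finite
    shape[nz] = (freqs[nz] + f0) ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    std = out.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return out / std * rms


def generate_recording(cfg: SessionConfig) -> tuple[Recording, GroundTruth]:
    """Synthesize one labelled session.

    Deterministic: the same config (including seed) yields bit-identical
    output.  A seed is required.
    """
    if cfg.seed is None:
        raise ValueError("SessionConfig.seed must be set for a reproducible session")
    rng = np.random.default_rng(cfg.seed)

    patterns, responsive = _class_patterns(cfg, rng)
    carriers = {
        label: f
        for label, f in zip(
            cfg.classes, np.linspace(8.5, 14.5, len(cfg.classes))
        )
    }

    n_rest = int(round(cfg.rest_duration * cfg.fs))
    n_stim = int(round(cfg.stim_duration * cfg.fs))
    n_resp = int(round(cfg.response_fraction * cfg.stim_duration * cfg.fs))
    n_trial = 2 * n_rest + n_stim

    order = np.repeat(cfg.classes, cfg.n_trials_per_class)
    rng.shuffle(order)

    n_total = n_trial * len(order)
    data = np.empty((cfg.n_channels, n_total))
    events: list[Event] = []
    t_trial = np.arange(n_trial) / cfg.fs
    stim_slice = slice(n_rest, n_rest + n_stim)
    resp_slice = slice(n_rest, n_rest + n_resp)

    evoked_scale = cfg.snr * np.sqrt(cfg.alpha_gain**2 - 1.0) * _ALPHA_BASE_AMP

    for trial, label in enumerate(order):
        seg = np.zeros((cfg.n_channels, n_trial))
        # ongoing rhythms, random phase per trial and channel
        for name, (f, amp) in _BASELINE_RHYTHMS.items():
            phase = rng.uniform(0, 2 * np.pi, size=(cfg.n_channels, 1))
            wave = np.sin(2 * np.pi * f * t_trial[None, :] + phase)
            if name == "delta":
                env = np.ones(n_trial)
                env[stim_slice] = cfg.delta_attenuation
                wave = wave * env[None, :]
            seg += amp * wave
        # class-specific alpha carrier during the responsive window: one
        # narrowband source time course, coherent across channels and scaled
        # by the class's spatial weights (RMS 1/sqrt(2), i.e. unit-sinusoid power)
        if evoked_scale > 0:
            carrier = _narrowband_source(rng, n_resp, cfg.fs, carriers[label])
            seg[:, resp_slice] += (
                evoked_scale * patterns[label][:, None] * carrier[None, :]
            )
        seg += _pink_noise(
            rng,
            cfg.n_channels,
            n_trial,
            cfg.fs,
            cfg.noise_exponent,
            _NOISE_RMS * cfg.noise_level,
        )
        start = trial * n_trial
        data[:, start : start + n_trial] = seg
        events.append(Event(start, n_rest, 0))
        events.append(Event(start + n_rest, n_stim, int(label)))
        events.append(Event(start + n_rest + n_stim, n_rest, 0))

    rec = Recording(
        data=data,
        fs=cfg.fs,
        channel_names=list(cfg.channel_names),
        lobe_map=dict(cfg.lobe_map),
        events=events,
    )
    truth = GroundTruth(
        timeline=rec.label_timeline(),
        spatial_patterns=patterns,
        carrier_freqs=carriers,
        responsive_mask=responsive,
    )
    return rec, truth


def generate_feature_table(
    n: int,
    d: int = 2,
    classes: tuple[int, ...] = (1, 2, 3, 4, 5),
    separation: float = 1.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional Gaussian clusters for decoder unit tests.

    Cluster centroids are spaced ``separation`` times the (unit) within-class
    standard deviation; ``separation=0`` collapses all classes onto one
    distribution (chance-level decodability).
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    if d < 2:
        raise ValueError("need at least two feature dimensions")
    J = len(classes)
    if n < J:
        raise ValueError(f"need at least {J} points for {J} classes")
    rng = np.random.default_rng(seed)
    centers = rng.standard_normal((J, d))
    centers -= centers.mean(axis=0)
    if separation > 0:
        dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        min_d = dists[~np.eye(J, dtype=bool)].min()
        centers *= separation / min_d
    else:
        centers[:] = 0.0
    labels = np.asarray([classes[i % J] for i in range(n)])
    rng.shuffle(labels)
    pos = {c: i for i, c in enumerate(classes)}
    idx = np.asarray([pos[l] for l in labels])
    X = centers[idx] + rng.standard_normal((n, d))
    return X, labels
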