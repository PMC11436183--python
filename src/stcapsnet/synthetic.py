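"""Seeded synthetic EEG epoch generator.

Emulates the geometry of a perception-vs-imagination semantic-concept EEG
experiment (124 scalp channels sampled at 1024 Hz, three-second visual or
two-second auditory epochs) without any physiological forward model. Each
class owns

* a fixed random spatial mixing matrix (channels x sources), and
* band-limited oscillatory source waveforms with class-specific
  frequencies, phases and amplitude envelopes,

so class information lives both in the spatial pattern (exercising the
spatial (C, 1) convolution) and in the temporal dynamics (exercising the
temporal (1, TI) convolution). An observed trial is the class's mixed
source template plus spatially correlated 1/f (pink) noise scaled to a
configurable SNR; ``snr_db = +inf`` disables noise entirely, making every
trial exactly its class template. Identical seeds give bit-identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ShapeError

MODALITIES = ("pictorial", "orthographic", "audio", "synthetic")


@dataclass
class GenConfig:
    """Generator settings; defaults mirror the visual-modality geometry."""

    n_trials_per_class: int = 10
    n_channels: int = 124
    sfreq: float = 1024.0
    duration: float = 3.0
    snr_db: float = 10.0
    n_sources: int = 4
    band: tuple[float, float] = (4.0, 30.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ConfigurationError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.sfreq <= 0:
            raise ConfigurationError(f"sfreq must be positive, got {self.sfreq}")
        if self.duration <= 0:
            raise ConfigurationError(f"duration must be positive, got {self.duration}")
        if self.n_trials_per_class < 1:
            raise ConfigurationError(
                f"n_trials_per_class must be >= 1, got {self.n_trials_per_class}"
            )
        if self.n_sources < 1:
            raise ConfigurationError(f"n_sources must be >= 1, got {self.n_sources}")
        if np.isnan(self.snr_db) or self.snr_db == -np.inf:
            raise ConfigurationError(
                f"snr_db must be finite or +inf (noise off), got {self.snr_db}"
            )
        lo, hi = self.band
        if not (0 < lo < hi < self.sfreq / 2):
            raise ConfigurationError(f"band {self.band} must satisfy 0 < low < high < Nyquist")

    @property
    def n_samples(self) -> int:
        # matches the convention: 3 s @ 1024 Hz -> 3073 samples, 2 s -> 2049
        return int(round(self.duration * self.sfreq)) + 1


@dataclass
class EEGEpochSet:
    """Labeled multichannel EEG trials with sampling-rate metadata."""

    data: np.ndarray  # (trials, channels, samples)
    labels: np.ndarray  # per-trial class: 0 = imagination, 1 = perception
    sfreq: float
    modality: str = "synthetic"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise ShapeError(f"data must be (trials, channels, samples), got {self.data.shape}")
        if self.labels.ndim != 1 or len(self.labels) != self.data.shape[0]:
            raise ShapeError(
                f"labels length {self.labels.shape} does not match "
                f"{self.data.shape[0]} trials"
            )
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ShapeError(f"labels must be binary, got {sorted(set(self.labels))}")
        if not np.all(np.isfinite(self.data)):
            raise ShapeError("data contains non-finite values")
        if self.modality not in MODALITIES:
            raise ShapeError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "EEGEpochSet":
        idx = np.asarray(idx)
        return EEGEpochSet(self.data[idx], self.labels[idx], self.sfreq, self.modality)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """Temporal 1/f noise per channel, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0  # no DC drift
    noise = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    noise /= noise.std(axis=1, keepdims=True) + 1e-30
    return noise


def class_template(cfg: GenConfig, label: int) -> np.ndarray:
    """Deterministic noise-free (channels, samples) template of one class."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + label]))
    T = cfg.n_samples
    t = np.arange(T) / cfg.sfreq
    lo, hi = cfg.band
    mixing = rng.normal(0.0, 1.0, size=(cfg.n_channels, cfg.n_sources)) / np.sqrt(cfg.n_sources)
    sources = np.empty((cfg.n_sources, T))
    for s in range(cfg.n_sources):
        freq = rng.uniform(lo, hi)
        phase = rng.uniform(0.0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.5)
        # Hann-tapered burst with a class/source-specific center and width
        center = rng.uniform(0.25, 0.75) * cfg.duration
        width = rng.uniform(0.3, 0.8) * cfg.duration
        env = np.clip(1.0 - ((t - center) / (width / 2.0)) ** 2, 0.0, None)
        sources[s] = amp * env * np.sin(2 * np.pi * freq * t + phase)
    return mixing @ sources


def generate_epochs(cfg: GenConfig) -> EEGEpochSet:
    """Generate a balanced two-class epoch set under ``cfg``.

    Trials are ordered class 0 first, then class 1; downstream fold
    builders shuffle. SNR convention: ``snr_db = 10 log10(Ps / Pn)`` where
    Ps and Pn are template and noise power averaged over channels and
    samples; each trial's noise is scaled to hit the ratio exactly.
    """
    T = cfg.n_samples
    templates = {c: class_template(cfg, c) for c in (0, 1)}
    noise_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2000]))
    # random spatial correlation shared by all trials' noise
    spat = noise_rng.normal(0.0, 1.0, size=(cfg.n_channels, cfg.n_channels))
    spat /= np.sqrt(cfg.n_channels)

    n = cfg.n_trials_per_class
    data = np.empty((2 * n, cfg.n_channels, T))
    labels = np.repeat([0, 1], n)
    for i, label in enumerate(labels):
        tpl = templates[label]
        if np.isinf(cfg.snr_db):
            data[i] = tpl
            continue
        noise = spat @ _pink_noise(noise_rng, cfg.n_channels, T)
        p_sig = np.mean(tpl**2)
        p_noise = np.mean(noise**2)
        target_noise_power = p_sig / (10.0 ** (cfg.snr_db / 10.0))
        data[i] = tpl + noise * np.sqrt(target_noise_power / p_noise)
    return EEGEpochSet(data=data, labels=labels, sfreq=cfg.sfreq, modality="synthetic")


def make_fixture_suite(seed: int = 0) -> dict[str, EEGEpochSet]:
    """Small deterministic epoch sets for fast tests.

    ``tiny``: 8 trials, 8 channels, 128 samples; ``pictorial`` /
    ``audio``: 4 trials at the full visual / auditory geometry.
    """
    tiny = generate_epochs(GenConfig(
        n_trials_per_class=4, n_channels=8, sfreq=127.0, duration=1.0,
        snr_db=10.0, n_sources=3, band=(4.0, 30.0), seed=seed,
    ))
    pictorial = generate_epochs(GenConfig(
        n_trials_per_class=2, n_channels=124, sfreq=1024.0, duration=3.0,
        snr_db=10.0, seed=seed + 1,
    ))
    pictorial.modality = "pictorial"
    audio = generate_epochs(GenConfig(
        n_trials_per_class=2, n_channels=124, sfreq=1024.0, duration=2.0,
        snr_db=10.0, seed=seed + 2,
    ))
    audio.modality = "audio"
    return {"tiny": tiny, "pictorial": pictorial, "audio": audio}
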