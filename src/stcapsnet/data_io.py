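"""Epoch-set persistence, duration standardization, and CV fold building.

The canonical on-disk form is a compressed named-array archive (NumPy
``.npz``) holding ``data`` (trials x channels x samples), ``labels``
(binary, per trial), scalar ``sfreq`` and a ``modality`` tag. EDF
recordings can be imported through the optional :func:`import_edf`
helper, which converts to the same in-memory container.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ConfigurationError, FormatError
from .synthetic import EEGEpochSet


def save_epochs(eset: EEGEpochSet, path) -> None:
    """Write an epoch set losslessly to a compressed archive."""
    eset.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path, data=eset.data, labels=eset.labels,
        sfreq=np.float64(eset.sfreq), modality=np.str_(eset.modality),
    )


def load_epochs(path) -> EEGEpochSet:
    """Read an epoch set, validating every field."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=False) as arch:
        for key in ("data", "labels", "sfreq"):
            if key not in arch:
                raise FormatError(f"epoch container {path} is missing array '{key}'")
        data = np.asarray(arch["data"], dtype=np.float64)
        labels = np.asarray(arch["labels"])
        sfreq = float(arch["sfreq"])
        modality = str(arch["modality"]) if "modality" in arch else "synthetic"
    if data.ndim != 3:
        raise FormatError(f"'data' must be 3-D (trials, channels, samples), got {data.shape}")
    if labels.ndim != 1 or len(labels) != data.shape[0]:
        raise FormatError(
            f"'labels' length {labels.shape} does not match 'data' trials {data.shape[0]}"
        )
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError(f"'labels' must be integers, got dtype {labels.dtype}")
    if not set(np.unique(labels)) <= {0, 1}:
        raise FormatError(f"'labels' must be binary 0/1, got {sorted(set(labels))}")
    return EEGEpochSet(data=data, labels=labels, sfreq=sfreq, modality=modality)


def crop_to_duration(eset: EEGEpochSet, seconds: float) -> EEGEpochSet:
    """Keep the leading round(seconds * sfreq) + 1 samples of every trial.

    The leading (stimulus-locked) window is the conventional epoching
    choice when standardizing heterogeneous epoch durations.
    """
    n_keep = int(round(seconds * eset.sfreq)) + 1
    if n_keep > eset.n_samples:
        raise ConfigurationError(
            f"requested {seconds} s = {n_keep} samples, but trials hold "
            f"only {eset.n_samples}"
        )
    return EEGEpochSet(
        data=eset.data[:, :, :n_keep], labels=eset.labels,
        sfreq=eset.sfreq, modality=eset.modality,
    )


@dataclass
class FoldPlan:
    """Stratified partition of trials into k cross-validation folds."""

    k: int
    assignments: np.ndarray  # per-trial fold index in [0, k)

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        counts = np.bincount(self.assignments, minlength=self.k)
        if len(counts) != self.k or np.any(counts == 0):
            raise ConfigurationError(f"every fold must be non-empty, got sizes {counts}")

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for one fold."""
        test = np.flatnonzero(self.assignments == fold)
        train = np.flatnonzero(self.assignments != fold)
        return train, test


def make_cv_folds(labels, k: int, seed: int = 0) -> FoldPlan:
    """Seeded stratified k-fold assignment over trials."""
    labels = np.asarray(labels)
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    min_class = np.bincount(labels).min()
    if k > min_class:
        raise ConfigurationError(
            f"k={k} exceeds the smallest class count ({min_class} trials)"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments)


def holdout_split(eset: EEGEpochSet, test_fraction: float = 0.2, seed: int = 0):
    """Seeded stratified hold-out split; the default when CV is not requested."""
    idx = np.arange(eset.n_trials)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=eset.labels
    )
    return eset.subset(np.sort(train_idx)), eset.subset(np.sort(test_idx))


def import_edf(path, labels, duration: float, modality: str = "synthetic") -> EEGEpochSet:
    """Import an EDF recording as consecutive fixed-length labeled epochs.

    Requires ``mne`` (optional dependency). The recording is cut into
    ``len(labels)`` back-to-back windows of ``round(duration * sfreq) + 1``
    samples from the start of the file.
    """
    import mne  # deferred: optional dependency

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    sfreq = float(raw.info["sfreq"])
    signal = raw.get_data()
    labels = np.asarray(labels, dtype=np.int64)
    n_keep = int(round(duration * sfreq)) + 1
    needed = n_keep * len(labels)
    if signal.shape[1] < needed:
        raise FormatError(
            f"recording holds {signal.shape[1]} samples, need {needed} "
            f"for {len(labels)} epochs of {duration} s"
        )
    data = np.stack([
        signal[:, i * n_keep : (i + 1) * n_keep] for i in range(len(labels))
    ])
    return EEGEpochSet(data=data, labels=labels, sfreq=sfreq, modality=modality)
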