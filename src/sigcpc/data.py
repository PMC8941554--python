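"""Synthetic multi-class epoch datasets and label-budget utilities.

A dataset is a stack of fixed-length signal *epochs* (windows of a
physiological recording, e.g. 30 s of single-channel EEG at 100 Hz) with one
integer class label per epoch.  The synthetic generator emulates the one
property the contrastive pretext task relies on: epochs of the same class
share latent structure (here, a class-specific oscillation frequency and
amplitude) while individual epochs differ (random phase, additive noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

__all__ = [
    "SynthConfig",
    "EpochDataset",
    "generate_dataset",
    "split_dataset",
    "label_mask",
]

#: default sleep-band oscillation frequencies (Hz), one per class, loosely
#: mirroring alpha (wake), theta (N1), sigma/spindle (N2), delta (N3) and
#: mixed-theta (REM) rhythms.
DEFAULT_FREQS = (10.0, 5.0, 13.0, 1.5, 7.5)
DEFAULT_AMPS = (1.0, 0.8, 1.2, 2.0, 0.9)
DEFAULT_CLASS_NAMES = ("W", "N1", "N2", "N3", "REM")


class ConfigError(ValueError):
    """Raised when a :class:`SynthConfig` violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Recipe for a synthetic multi-class epoch dataset.

    Each class ``c`` produces epochs of the form
    ``amp[c] * sin(2*pi*freq[c]*t + phi) + noise`` with a fresh uniform phase
    ``phi`` per epoch and i.i.d. Gaussian noise of standard deviation
    ``noise_sd``.  The same config (including ``seed``) reproduces the same
    dataset bit for bit.
    """

    n_classes: int = 5
    n_per_class: int = 100
    epoch_length: int = 3000
    sampling_rate: float = 100.0
    class_freqs: tuple[float, ...] = DEFAULT_FREQS
    class_amps: tuple[float, ...] = DEFAULT_AMPS
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ConfigError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_per_class < 1:
            raise ConfigError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if self.epoch_length < 8:
            raise ConfigError(f"epoch_length must be >= 8, got {self.epoch_length}")
        if self.sampling_rate <= 0:
            raise ConfigError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if len(self.class_freqs) < self.n_classes:
            raise ConfigError(
                f"class_freqs supplies {len(self.class_freqs)} frequencies "
                f"for {self.n_classes} classes"
            )
        if len(self.class_amps) < self.n_classes:
            raise ConfigError(
                f"class_amps supplies {len(self.class_amps)} amplitudes "
                f"for {self.n_classes} classes"
            )
        freqs = self.class_freqs[: self.n_classes]
        if len(set(freqs)) != len(freqs):
            raise ConfigError(f"class_freqs must be pairwise distinct, got {freqs}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass
class EpochDataset:
    """Fixed-length signal epochs with per-epoch integer class labels.

    ``epochs`` is an ``(n_epochs, epoch_length)`` float array; ``labels`` an
    ``(n_epochs,)`` integer array with values in ``0..n_classes-1``.
    """

    epochs: np.ndarray
    labels: np.ndarray
    sampling_rate: float = 100.0
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 2:
            raise ValueError(f"epochs must be 2-D, got shape {self.epochs.shape}")
        if self.epochs.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.epochs.shape[0]} epochs but {self.labels.shape[0]} labels"
            )
        if len(self) and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative class ids")
        if self.class_names is not None and len(self) and (
            self.labels.max() >= len(self.class_names)
        ):
            raise ValueError("label exceeds the class_names list")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def epoch_length(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_classes(self) -> int:
        if self.class_names is not None:
            return len(self.class_names)
        return int(self.labels.max()) + 1 if len(self) else 0

    def class_indices(self, class_id: int) -> np.ndarray:
        """Indices of all epochs carrying ``class_id``."""
        return np.flatnonzero(self.labels == class_id)

    def subset(self, indices: np.ndarray) -> "EpochDataset":
        indices = np.asarray(indices, dtype=np.int64)
        return EpochDataset(
            self.epochs[indices],
            self.labels[indices],
            sampling_rate=self.sampling_rate,
            class_names=self.class_names,
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


def generate_dataset(config: SynthConfig) -> EpochDataset:
    """Generate a balanced multi-class dataset of noisy class-toned sinusoids.

    Epoch ``i`` of class ``c`` is
    ``amps[c] * sin(2*pi*freqs[c]*t + phi_i) + eps`` with ``phi_i`` uniform on
    ``[0, 2*pi)`` and ``eps ~ N(0, noise_sd^2)`` elementwise.  Labels come out
    grouped by class (class 0 first); shuffle downstream if order matters.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.epoch_length) / config.sampling_rate
    blocks = []
    for c in range(config.n_classes):
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(config.n_per_class, 1))
        clean = config.class_amps[c] * np.sin(
            2.0 * np.pi * config.class_freqs[c] * t[None, :] + phases
        )
        noise = rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd else 0.0
        blocks.append(clean + noise)
    epochs = np.concatenate(blocks, axis=0)
    labels = np.repeat(np.arange(config.n_classes), config.n_per_class)
    names = None
    if config.n_classes == len(DEFAULT_CLASS_NAMES):
        names = list(DEFAULT_CLASS_NAMES)
    return EpochDataset(epochs, labels, sampling_rate=config.sampling_rate, class_names=names)


def split_dataset(
    dataset: EpochDataset, test_fraction: float, seed: int
) -> tuple[EpochDataset, EpochDataset]:
    """Stratified train/test split (e.g. ``test_fraction=0.1`` for a 9:1 split).

    Per-class proportions are preserved up to rounding; the two returned
    datasets partition the input exhaustively and disjointly.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    counts = dataset.class_counts()
    thin = np.flatnonzero(counts < 2)
    if thin.size:
        raise ValueError(
            f"cannot stratify: class(es) {thin.tolist()} have fewer than 2 epochs"
        )
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=dataset.labels,
    )
    return dataset.subset(np.sort(train_idx)), dataset.subset(np.sort(test_idx))


def label_mask(dataset: EpochDataset, labeled_fraction: float, seed: int) -> np.ndarray:
    """Class-stratified subset of epoch indices to treat as labeled.

    Used by the label-efficiency study: downstream training sees only
    ``round(labeled_fraction * n_c)`` labels per class ``c``.
    """
    if not 0.0 < labeled_fraction <= 1.0:
        raise ValueError(f"labeled_fraction must lie in (0, 1], got {labeled_fraction}")
    if labeled_fraction == 1.0:
        return np.arange(len(dataset))
    rng = np.random.default_rng(seed)
    chosen = []
    for c in range(dataset.n_classes):
        members = dataset.class_indices(c)
        if members.size == 0:
            continue
        k = int(round(labeled_fraction * members.size))
        if k == 0:
            raise ValueError(
                f"labeled_fraction={labeled_fraction} leaves class {c} with no labels"
            )
        chosen.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(chosen))
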