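"""Positive/negative sample-pair construction for the contrastive pretext task.

A *sample pair* is 8 epochs arranged 4 + 4.  The left block is the "training
set" half whose encodings the context model summarizes; the right block is
the "waiting training set" half whose encodings the context must predict.
A pair is positive (label 1) when all 8 epochs share one class, negative
(label 0) when the two halves come from two different classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import EpochDataset

__all__ = ["SamplePair", "build_positive_pair", "build_negative_pair", "pair_batch", "BLOCK_SIZE"]

#: epochs per half-pair (the 4 + 4 layout)
BLOCK_SIZE = 4


class PairSamplingError(RuntimeError):
    """Raised when a dataset cannot furnish the requested pair."""


@dataclass
class SamplePair:
    left_block: np.ndarray  # (4, epoch_length)
    right_block: np.ndarray  # (4, epoch_length)
    pair_label: int  # 1 positive, 0 negative
    left_class: int
    right_class: int
    left_indices: np.ndarray  # source epoch indices, for auditability
    right_indices: np.ndarray

    def __post_init__(self) -> None:
        self.left_block = np.asarray(self.left_block, dtype=float)
        self.right_block = np.asarray(self.right_block, dtype=float)
        if self.left_block.shape[0] != BLOCK_SIZE or self.right_block.shape[0] != BLOCK_SIZE:
            raise ValueError(
                f"each block must hold exactly {BLOCK_SIZE} epochs, got "
                f"{self.left_block.shape[0]} / {self.right_block.shape[0]}"
            )
        if self.pair_label not in (0, 1):
            raise ValueError(f"pair_label must be 0 or 1, got {self.pair_label}")
        same = self.left_class == self.right_class
        if self.pair_label == 1 and not same:
            raise ValueError("positive pair must draw both halves from one class")
        if self.pair_label == 0 and same:
            raise ValueError("negative pair must draw its halves from two classes")


def build_positive_pair(
    dataset: EpochDataset, class_id: int, rng: np.random.Generator
) -> SamplePair:
    """Draw 8 distinct epochs of ``class_id``, split 4 left / 4 right, label 1."""
    members = dataset.class_indices(class_id)
    if members.size < 2 * BLOCK_SIZE:
        raise PairSamplingError(
            f"class {class_id} has {members.size} epochs; a positive pair needs "
            f"{2 * BLOCK_SIZE} distinct ones"
        )
    idx = rng.choice(members, size=2 * BLOCK_SIZE, replace=False)
    return SamplePair(
        left_block=dataset.epochs[idx[:BLOCK_SIZE]],
        right_block=dataset.epochs[idx[BLOCK_SIZE:]],
        pair_label=1,
        left_class=class_id,
        right_class=class_id,
        left_indices=idx[:BLOCK_SIZE],
        right_indices=idx[BLOCK_SIZE:],
    )


def build_negative_pair(
    dataset: EpochDataset, class_a: int, class_b: int, rng: np.random.Generator
) -> SamplePair:
    """Draw 4 distinct epochs of ``class_a`` (left) and 4 of ``class_b`` (right)."""
    if class_a == class_b:
        raise ValueError(f"negative pair requires two distinct classes, got {class_a} twice")
    left_members = dataset.class_indices(class_a)
    right_members = dataset.class_indices(class_b)
    for cid, members in ((class_a, left_members), (class_b, right_members)):
        if members.size < BLOCK_SIZE:
            raise PairSamplingError(
                f"class {cid} has {members.size} epochs; a negative pair needs "
                f"{BLOCK_SIZE} distinct ones per half"
            )
    left = rng.choice(left_members, size=BLOCK_SIZE, replace=False)
    right = rng.choice(right_members, size=BLOCK_SIZE, replace=False)
    return SamplePair(
        left_block=dataset.epochs[left],
        right_block=dataset.epochs[right],
        pair_label=0,
        left_class=class_a,
        right_class=class_b,
        left_indices=left,
        right_indices=right,
    )


def pair_batch(
    dataset: EpochDataset,
    batch_size: int,
    positive_fraction: float = 0.5,
    rng: np.random.Generator | None = None,
) -> list[SamplePair]:
    """Random batch of pairs with ``round(positive_fraction * batch_size)`` positives.

    Classes are drawn uniformly: positives over all classes, negatives over
    all ordered unequal class pairs.  Epochs recur freely ACROSS pairs (each
    epoch is revisited over many iterations) but never WITHIN one pair.
    """
    if batch_size < 2:
        raise ValueError(f"batch_size must be >= 2, got {batch_size}")
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError(f"positive_fraction must lie in [0, 1], got {positive_fraction}")
    if rng is None:
        rng = np.random.default_rng()
    n_classes = dataset.n_classes
    if n_classes < 2:
        raise PairSamplingError("need at least 2 classes to form negative pairs")
    n_pos = int(round(positive_fraction * batch_size))
    pairs: list[SamplePair] = []
    for _ in range(n_pos):
        cid = int(rng.integers(n_classes))
        pairs.append(build_positive_pair(dataset, cid, rng))
    for _ in range(batch_size - n_pos):
        a = int(rng.integers(n_classes))
        b = int(rng.integers(n_classes - 1))
        if b >= a:
            b += 1  # uniform over ordered unequal (a, b)
        pairs.append(build_negative_pair(dataset, a, b, rng))
    perm = rng.permutation(len(pairs))
    return [pairs[i] for i in perm]


def batch_arrays(pairs: list[SamplePair]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a pair batch into (left, right, labels) arrays for model training.

    Returns ``left`` and ``right`` of shape ``(B, 4, epoch_length)`` and the
    binary label vector of shape ``(B,)``.
    """
    left = np.stack([p.left_block for p in pairs])
    right = np.stack([p.right_block for p in pairs])
    y = np.array([p.pair_label for p in pairs], dtype=float)
    return left, right, y
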