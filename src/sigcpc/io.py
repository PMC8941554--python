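"""Epoch-matrix file I/O and signal preprocessing utilities.

The native on-disk form of an :class:`~sigcpc.data.EpochDataset` is the
*epoch matrix*: one epoch per row, integer label first, amplitudes after.
Two dialects are supported and selected by file extension:

* text (any extension other than ``.npz``): ``#``-prefixed header lines
  carrying ``key=value`` metadata, then space-separated rows — greppable and
  language-neutral;
* binary (``.npz``): a compressed numpy container, bit-exact round trip.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

from .data import EpochDataset

__all__ = [
    "read_epoch_matrix",
    "write_epoch_matrix",
    "resample_epoch",
    "normalize_epoch",
    "ParseError",
]

FORMAT_TAG = "epoch-matrix v1"


class ParseError(ValueError):
    """Malformed epoch-matrix file; message carries the offending line number."""


def write_epoch_matrix(dataset: EpochDataset, path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path,
            epochs=dataset.epochs,
            labels=dataset.labels,
            sampling_rate=np.array(dataset.sampling_rate),
            class_names=np.array(dataset.class_names or [], dtype=str),
        )
        return
    with open(path, "w") as fh:
        fh.write(f"# {FORMAT_TAG}\n")
        fh.write(
            f"# n_epochs={len(dataset)} epoch_length={dataset.epoch_length} "
            f"sampling_rate={dataset.sampling_rate!r}\n"
        )
        if dataset.class_names:
            fh.write(f"# class_names={','.join(dataset.class_names)}\n")
        for label, row in zip(dataset.labels, dataset.epochs):
            fh.write(str(int(label)) + " " + " ".join(f"{v:.10g}" for v in row) + "\n")


def read_epoch_matrix(path) -> EpochDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            names = [str(s) for s in npz["class_names"]] or None
            return EpochDataset(
                npz["epochs"],
                npz["labels"],
                sampling_rate=float(npz["sampling_rate"]),
                class_names=names,
            )
    meta: dict[str, str] = {}
    rows: list[np.ndarray] = []
    labels: list[int] = []
    epoch_length = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                continue
            parts = line.split()
            try:
                label = int(parts[0])
                values = np.array([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: unparseable row ({exc})") from exc
            if label < 0:
                raise ParseError(f"{path}:{lineno}: negative class label {label}")
            if epoch_length is None:
                epoch_length = values.size
            elif values.size != epoch_length:
                raise ParseError(
                    f"{path}:{lineno}: ragged row, expected {epoch_length} "
                    f"values but found {values.size}"
                )
            labels.append(label)
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no epoch rows found")
    if "n_epochs" in meta and int(meta["n_epochs"]) != len(rows):
        raise ParseError(
            f"{path}: header declares {meta['n_epochs']} epochs, body has {len(rows)}"
        )
    if "epoch_length" in meta and int(meta["epoch_length"]) != epoch_length:
        raise ParseError(
            f"{path}: header declares epoch_length {meta['epoch_length']}, "
            f"body rows have {epoch_length}"
        )
    names = meta.get("class_names")
    return EpochDataset(
        np.vstack(rows),
        np.array(labels),
        sampling_rate=float(meta.get("sampling_rate", 100.0)),
        class_names=names.split(",") if names else None,
    )


def resample_epoch(epoch: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Band-limited (polyphase) resampling of one epoch.

    Output length is ``round(len * rate_out / rate_in)`` up to the ceiling
    convention of the polyphase filter; tones below both Nyquist limits keep
    their frequency and, away from the band edge, their energy.  Handles
    non-integer rate ratios (e.g. 128 Hz → 251 Hz beat epochs) through a
    rational approximation of the ratio.
    """
    if rate_in <= 0 or rate_out <= 0:
        raise ValueError(f"sampling rates must be positive, got {rate_in} -> {rate_out}")
    x = np.asarray(epoch, dtype=float)
    if rate_in == rate_out:
        return x.copy()
    ratio = Fraction(rate_out) / Fraction(rate_in)
    ratio = ratio.limit_denominator(10_000)
    return resample_poly(x, ratio.numerator, ratio.denominator)


def normalize_epoch(epoch: np.ndarray) -> np.ndarray:
    """Per-epoch standardization to mean 0, sd 1; constant epochs map to zeros.

    Accepts a single epoch or a 2-D stack (normalized row-wise).
    """
    x = np.asarray(epoch, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty epoch")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    out = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out
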