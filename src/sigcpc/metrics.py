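"""Confusion-matrix evaluation: per-class precision/recall/F1, macro F1, accuracy.

Conventions: confusion rows index the true class, columns the predicted
class.  Percentages are carried at full precision internally and rounded
half-up to two decimals for display, matching how sleep-staging benchmarks
print their tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["EvalReport", "confusion_matrix", "report_metrics", "round_half_up"]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round with ties away from zero (5 rounds up), as printed tables do."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    """Confusion matrix with the derived per-class and aggregate metrics.

    ``precision``, ``recall``, ``f1`` are per-class percentages at full
    precision; ``accuracy`` and ``macro_f1`` likewise.  ``degenerate``
    flags classes that were never predicted or never present.
    """

    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    accuracy: float
    class_names: list[str] | None = None
    degenerate: list[int] | None = None

    def rounded(self) -> dict:
        """Two-decimal display values (half-up), mirroring printed tables."""
        return {
            "precision": [round_half_up(v) for v in self.precision],
            "recall": [round_half_up(v) for v in self.recall],
            "f1": [round_half_up(v) for v in self.f1],
            "macro_f1": round_half_up(self.macro_f1),
            "accuracy": round_half_up(self.accuracy),
        }

    def to_text(self) -> str:
        """Human-readable table: matrix columns, then PR/RE/F1, ACC footer."""
        n = self.confusion.shape[0]
        names = self.class_names or [f"class{i}" for i in range(n)]
        r = self.rounded()
        width = max(8, max(len(s) for s in names) + 2)
        head = "".join(f"{s:>{width}}" for s in ["true\\pred", *names, "PR(%)", "RE(%)", "F1(%)"])
        lines = [head]
        for i in range(n):
            cells = "".join(f"{int(v):>{width}}" for v in self.confusion[i])
            lines.append(
                f"{names[i]:>{width}}{cells}"
                f"{r['precision'][i]:>{width}.2f}{r['recall'][i]:>{width}.2f}"
                f"{r['f1'][i]:>{width}.2f}"
            )
        lines.append(f"{'Macro avg':>{width}}" + " " * width * n
                     + " " * width * 2 + f"{r['macro_f1']:>{width}.2f}")
        lines.append(f"{'ACC':>{width}}{r['accuracy']:>{width}.2f}%")
        return "\n".join(lines)

    def to_delimited(self, sep: str = "\t") -> str:
        n = self.confusion.shape[0]
        names = self.class_names or [f"class{i}" for i in range(n)]
        r = self.rounded()
        rows = [sep.join(["class", *["n_" + s for s in names], "precision", "recall", "f1"])]
        for i in range(n):
            rows.append(sep.join(
                [names[i], *[str(int(v)) for v in self.confusion[i]],
                 f"{r['precision'][i]:.2f}", f"{r['recall'][i]:.2f}", f"{r['f1'][i]:.2f}"]
            ))
        rows.append(sep.join(["macro_f1", f"{r['macro_f1']:.2f}"]))
        rows.append(sep.join(["accuracy", f"{r['accuracy']:.2f}"]))
        return "\n".join(rows) + "\n"


def confusion_matrix(
    true_labels: np.ndarray, predicted_labels: np.ndarray, n_classes: int
) -> np.ndarray:
    """Integer matrix whose entry (i, j) counts true class i predicted as j."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(predicted_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label vectors differ in length: {t.shape} vs {p.shape}")
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"labels must lie in 0..{n_classes - 1}")
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (t, p), 1)
    return m


def report_metrics(confusion: np.ndarray, class_names: list[str] | None = None) -> EvalReport:
    """Per-class precision/recall/F1 (percent), macro F1 and accuracy.

    precision_c = 100 * diag_c / column-sum_c, recall_c = 100 * diag_c /
    row-sum_c, F1_c their harmonic mean, macro F1 the unweighted mean of the
    per-class F1 values.  A class never predicted (zero column) or never
    present (zero row) gets 0 for the undefined ratio and is flagged in
    ``degenerate``.
    """
    m = np.asarray(confusion)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {m.shape}")
    if np.any(m < 0):
        raise ValueError("confusion matrix entries must be nonnegative")
    total = m.sum()
    if total <= 0:
        raise ValueError("confusion matrix has zero grand total")
    diag = np.diag(m).astype(float)
    col = m.sum(axis=0).astype(float)
    row = m.sum(axis=1).astype(float)
    degenerate = sorted(set(np.flatnonzero(col == 0)) | set(np.flatnonzero(row == 0)))
    if degenerate:
        warnings.warn(
            f"class(es) {list(map(int, degenerate))} never predicted or never "
            "present; their precision/recall reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / col, 0.0) * 100.0
        recall = np.where(row > 0, diag / row, 0.0) * 100.0
        denom = precision + recall
        f1 = np.where(denom > 0, 2.0 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    return EvalReport(
        confusion=m.astype(np.int64),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=float(f1.mean()),
        accuracy=float(100.0 * diag.sum() / total),
        class_names=class_names,
        degenerate=[int(i) for i in degenerate] or None,
    )
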