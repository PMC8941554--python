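"""Published five-stage sleep-staging benchmark counts used as fixtures.

These are the printed confusion matrix (rows = true stage, columns =
predicted stage) and per-stage epoch totals of a full-dataset evaluation of
the CPC-pretrained classifier on the sleep-EDF Fpz-Cz recordings.  They are
kept as an in-repo fixture so that the metric arithmetic
(:func:`sigcpc.metrics.report_metrics`) can be validated against an
independently published table without any download.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "SLEEP_STAGE_NAMES",
    "SLEEP_STAGE_TOTALS",
    "SLEEP_STAGE_CONFUSION",
]

SLEEP_STAGE_NAMES = ["Awake", "N1", "N2", "N3", "REM"]

#: per-stage epoch totals of the dataset (sums to 42,308)
SLEEP_STAGE_TOTALS = np.array([8285, 2804, 17799, 5703, 7717], dtype=np.int64)

#: full-dataset confusion matrix, rows true / columns predicted
SLEEP_STAGE_CONFUSION = np.array(
    [
        [7270, 235, 349, 79, 352],
        [55, 2572, 75, 4, 98],
        [278, 269, 15418, 396, 1438],
        [69, 2, 506, 5126, 0],
        [183, 195, 186, 10, 7143],
    ],
    dtype=np.int64,
)
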