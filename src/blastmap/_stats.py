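"""Small order-statistic conventions shared across modules.

These are pinned so that every reported table is bit-reproducible:
lower median for even counts, linear-interpolation quartiles for the
IQR, and the n-1 denominator for standard deviations.
"""

from __future__ import annotations

import numpy as np


def lower_median(values) -> float:
    """Median with the lower order statistic taken for even counts."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("median of empty set")
    return float(v[(v.size - 1) // 2])


def interp_quartiles(values) -> tuple[float, float]:
    """(Q1, Q3) under the linear-interpolation quantile convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("quartiles of empty set")
    q1, q3 = np.quantile(v, [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def sample_sd(values) -> float:
    """Standard deviation with the n-1 denominator."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("sample SD needs at least two values")
    return float(np.std(v, ddof=1))
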