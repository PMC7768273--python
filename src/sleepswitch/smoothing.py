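"""Centered moving-average smoothing with shrinking windows at the edges.

This mirrors the behaviour of the classic ``smooth`` convention used in many
EEG pipelines: interior samples get a full centered window of odd width ``w``;
the first and last samples get symmetric windows of width 1, 3, 5, ... so the
output never shortens and the edges are not padded with invented data.
"""

from __future__ import annotations

import numpy as np


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average of odd width ``window`` with shrinking edges.

    NaNs are ignored within each window (a window that is all-NaN stays NaN),
    so invalid epochs neither poison their neighbours nor get silently
    interpolated away: an all-NaN input position remains NaN only if its whole
    window is NaN; the sample itself keeps whatever its window average is.
    To preserve explicit gaps, callers should re-mask invalid positions after
    smoothing (see ``compute_trajectory``).
    """
    x = np.asarray(x, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    n = x.size
    if n == 0:
        return x.copy()
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        seg = x[i - k : i + k + 1]
        good = np.isfinite(seg)
        out[i] = seg[good].mean() if good.any() else np.nan
    return out
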