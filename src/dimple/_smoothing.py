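"""Running-median smoothing shared by the spectrum and linescan filters."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["running_median"]


def running_median(values: np.ndarray, width: int) -> np.ndarray:
    """Sliding median over a 1D sequence with truncated edge windows.

    For odd ``width`` the window is centred on each element.  For even
    ``width`` the extra element sits on the leading (lower-index) side, and
    the lower median of the window is taken, so the filter stays value-
    preserving (output values are drawn from the input).  Windows are
    truncated at the sequence ends rather than padded.
    """
    if width < 1:
        raise ValueError("filter width must be >= 1")
    x = np.asarray(values, dtype=np.float64)
    n = len(x)
    if width == 1 or n == 0:
        return x.copy()
    before = width // 2 if width % 2 == 0 else (width - 1) // 2
    after = (width - 1) // 2
    out = np.empty_like(x)

    def lower_median(window: np.ndarray) -> float:
        return np.sort(window)[(len(window) - 1) // 2]

    if n >= width:
        # full windows, vectorized; partial edge windows handled below
        windows = np.sort(sliding_window_view(x, width), axis=1)
        out[before : n - after] = windows[:, (width - 1) // 2]
        edge_idx = list(range(before)) + list(range(n - after, n))
    else:
        edge_idx = range(n)
    for i in edge_idx:
        out[i] = lower_median(x[max(0, i - before) : min(n, i + after + 1)])
    return out
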