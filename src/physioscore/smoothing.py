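"""Boundary-aware centered moving average used by both signal pipelines."""

from __future__ import annotations

import numpy as np


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge windows truncated to the data.

    Near the edges the window is clipped to the available samples and the
    mean is taken over the actual count, so the output has no zero-padding
    droop and preserves the signal length.  ``window`` is forced odd so the
    filter is symmetric (zero group delay).
    """
    x = np.asarray(x, dtype=float)
    window = int(window)
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if window % 2 == 0:
        window += 1
    if window == 1 or x.size == 0:
        return x.copy()
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den
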