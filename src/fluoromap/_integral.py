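"""Exact integer box sums via a summed-area table (integral image)."""

from __future__ import annotations

import numpy as np


def box_sums(arr: np.ndarray, win: int, row_starts: np.ndarray,
             col_starts: np.ndarray) -> np.ndarray:
    """Sum of each ``win`` x ``win`` box with the given top-left corners.

    Exact for integer input (the table is built in int64).  Returns an array
    of shape ``(len(row_starts), len(col_starts))``.
    """
    arr = np.asarray(arr)
    h, w = arr.shape
    table = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(arr, axis=0, dtype=np.int64), axis=1,
              out=table[1:, 1:])
    r0 = np.asarray(row_starts, dtype=np.intp)
    c0 = np.asarray(col_starts, dtype=np.intp)
    r1, c1 = r0 + win, c0 + win
    return (table[np.ix_(r1, c1)] - table[np.ix_(r0, c1)]
            - table[np.ix_(r1, c0)] + table[np.ix_(r0, c0)])
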