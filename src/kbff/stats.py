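"""Shared statistics utilities (block averaging)."""

from __future__ import annotations

import numpy as np

__all__ = ["block_average_error", "block_means"]


def block_means(series, n_blocks: int = 5) -> np.ndarray:
    """Means of ``n_blocks`` contiguous equal blocks of ``series``.

    The remainder at the end of the series (``len(series) % n_blocks``
    frames) is discarded.  Works on 1-D scalar series and on (n, d)
    vector series, blocking along the first axis.
    """
    series = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError(f"n_blocks must be >= 2, got {n_blocks}")
    n = series.shape[0]
    if n < n_blocks:
        raise ValueError(
            f"series of length {n} is shorter than n_blocks={n_blocks}"
        )
    block_len = n // n_blocks
    trimmed = series[: block_len * n_blocks]
    blocks = trimmed.reshape(n_blocks, block_len, *series.shape[1:])
    return blocks.mean(axis=1)


def block_average_error(series, n_blocks: int = 5) -> float:
    """Standard error of the mean of ``series`` from block averaging.

    The series is split into ``n_blocks`` contiguous equal blocks
    (remainder discarded from the end) and the sample standard deviation
    of the block means divided by sqrt(n_blocks) is returned.  Five
    blocks is the conventional default used for all error bars in this
    package.
    """
    means = block_means(series, n_blocks)
    if means.ndim > 1:
        raise ValueError("block_average_error expects a scalar series")
    return float(np.std(means, ddof=1) / np.sqrt(n_blocks))
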