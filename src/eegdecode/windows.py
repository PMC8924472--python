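"""Sliding analysis windows over an epoch.

Features are computed inside short sliding windows (default 50 ms wide,
advanced in 5 ms steps). A window of ``w`` samples around a center index
``c`` covers samples ``c - w//2 .. c - w//2 + w - 1`` (for w=50 at 1000 Hz:
-25..+24 relative to the center), and a center is valid only where the full
window fits inside the epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .datasets import ConfigurationError, EpochedDataset

__all__ = ["WindowSpec", "sliding_windows", "round_half_up"]


def round_half_up(x: float) -> int:
    """Round to nearest integer, ties away from zero (12.5 -> 13)."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in milliseconds."""

    width_ms: float = 50.0
    step_ms: float = 5.0

    def n_samples(self, fs: float) -> int:
        w = round_half_up(self.width_ms * fs / 1000.0)
        if w < 8:
            raise ConfigurationError(
                f"window of {self.width_ms} ms at {fs} Hz has only {w} samples (< 8)"
            )
        return w

    def step_samples(self, fs: float) -> int:
        return max(1, round_half_up(self.step_ms * fs / 1000.0))


def window_centers(
    dataset: EpochedDataset, spec: WindowSpec
) -> tuple[np.ndarray, np.ndarray, int]:
    """Valid center indices and their times in ms, plus window length w."""
    w = spec.n_samples(dataset.fs)
    step = spec.step_samples(dataset.fs)
    n = dataset.n_samples
    half = w // 2
    first = half
    last = n - 1 - (w - 1 - half)
    if last < first:
        raise ConfigurationError("window larger than epoch")
    idx = np.arange(first, last + 1, step)
    times = dataset.t_first_sample + idx * 1000.0 / dataset.fs
    return idx, times, w


def sliding_windows(
    dataset: EpochedDataset, spec: WindowSpec
) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(center_ms, block)`` with block shape (trials, electrodes, w).

    Deterministic, ordered by center time; each slice has exactly ``w``
    samples and only centers where the full window fits are produced.
    """
    idx, times, w = window_centers(dataset, spec)
    half = w // 2
    for c, t in zip(idx, times):
        yield float(t), dataset.data[:, :, c - half : c - half + w]
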