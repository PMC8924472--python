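"""Core data containers for epoched multi-channel recordings.

An :class:`EpochedDataset` holds one participant's trials as a
``(n_trials, n_electrodes, n_samples)`` array of amplitudes in microvolts,
with a category label per trial, the sampling rate, and the time of the
first sample relative to stimulus onset. Epochs bracket the stimulus so a
pre-stimulus baseline exists (the study convention is -200..+1000 ms).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochedDataset", "ConfigurationError", "baseline_correct"]


class ConfigurationError(ValueError):
    """Raised when a configuration or contract precondition is violated."""


@dataclass
class EpochedDataset:
    """Epoched trials for a single participant.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_electrodes, n_samples)
        Amplitudes in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Category id per trial.
    fs : float
        Sampling rate in Hz.
    t_first_sample : float
        Time of the first sample in ms relative to stimulus onset
        (negative: epoch starts before onset).
    participant_id : str
    rt : ndarray or None
        Optional reaction time in ms per trial; must be positive.
    category_names : list of str or None
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    t_first_sample: float
    participant_id: str = "p0"
    rt: np.ndarray | None = None
    category_names: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ConfigurationError(
                f"data must be (trials, electrodes, samples); got ndim={self.data.ndim}"
            )
        if not np.isfinite(self.data).all():
            raise ConfigurationError("data contains non-finite values")
        if self.labels.shape != (self.data.shape[0],):
            raise ConfigurationError("labels must have one entry per trial")
        if np.unique(self.labels).size < 2:
            raise ConfigurationError("labels must span at least 2 categories")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.t_first_sample >= 0:
            raise ConfigurationError(
                "t_first_sample must be negative so a pre-stimulus baseline exists"
            )
        if self.rt is not None:
            self.rt = np.asarray(self.rt, dtype=float)
            if self.rt.shape != (self.data.shape[0],):
                raise ConfigurationError("rt must have one value per trial")
            if not (self.rt > 0).all():
                raise ConfigurationError("reaction times must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t_first_sample + np.arange(self.n_samples) * 1000.0 / self.fs

    def replace(self, **changes) -> "EpochedDataset":
        return dataclasses.replace(self, **changes)


def baseline_correct(
    dataset: EpochedDataset, window: tuple[float, float] = (-200.0, 0.0)
) -> EpochedDataset:
    """Subtract the mean pre-stimulus amplitude from each trial and electrode.

    ``window`` is the (start, stop) baseline span in ms relative to stimulus
    onset; the mean over samples with ``start <= t < stop`` is removed per
    trial and electrode. Idempotent up to floating-point noise.
    """
    t = dataset.times
    lo, hi = window
    if lo < t[0] - 1e-9 or hi > t[-1] + 1000.0 / dataset.fs + 1e-9:
        raise ConfigurationError(
            f"baseline window {window} outside epoch [{t[0]}, {t[-1]}] ms"
        )
    mask = (t >= lo) & (t < hi)
    if not mask.any():
        raise ConfigurationError(f"baseline window {window} contains no samples")
    baseline = dataset.data[:, :, mask].mean(axis=2, keepdims=True)
    return dataset.replace(data=dataset.data - baseline)
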