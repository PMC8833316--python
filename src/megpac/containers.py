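"""Core in-memory containers shared across the pipeline.

Trial-epoched data are held as plain numpy arrays with an explicit time
axis referenced to stimulus onset (t = 0).  Epochs carry optional padding
on both sides of the analysis window; padding is kept through filtering
and time-frequency decomposition and trimmed only when averaging, so edge
artefacts never enter any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["EpochSet", "VirtualElectrode"]


@dataclass
class EpochSet:
    """Trial-epoched multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Epoched time series.
    fs : float
        Sampling rate in Hz.
    times : ndarray, shape (n_samples,)
        Time axis in seconds, zero at stimulus onset.
    subject_id : str
        Identifier of the (real or simulated) subject.
    group : str
        Group label, e.g. ``"patient"`` or ``"control"``.
    pad_s : float
        Duration of edge padding (seconds) included on each side of the
        analysis window.
    meta : dict
        Free-form metadata; the simulator stores ground-truth values here
        (programmed dB changes, coupling depth, ...).
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    subject_id: str = ""
    group: str = ""
    pad_s: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (n_trials, n_channels, n_samples), got shape {self.data.shape}"
            )
        if self.times.shape != (self.data.shape[2],):
            raise ValueError(
                f"times length {self.times.shape} does not match n_samples {self.data.shape[2]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def time_mask(self, t_start: float, t_end: float) -> np.ndarray:
        """Boolean mask selecting samples with ``t_start <= t < t_end``."""
        return (self.times >= t_start - 1e-12) & (self.times < t_end - 1e-12)

    def copy_with(self, data: np.ndarray, times: np.ndarray | None = None,
                  fs: float | None = None) -> "EpochSet":
        return EpochSet(
            data=data,
            fs=self.fs if fs is None else fs,
            times=self.times if times is None else times,
            subject_id=self.subject_id,
            group=self.group,
            pad_s=self.pad_s,
            meta=dict(self.meta),
        )


@dataclass
class VirtualElectrode:
    """Single-channel trial series from one source grid point.

    Produced either by projecting sensor epochs through an LCMV spatial
    filter or directly by the simulator.
    """

    data: np.ndarray  # (n_trials, n_samples)
    fs: float
    times: np.ndarray
    subject_id: str = ""
    group: str = ""
    pad_s: float = 0.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"data must be (n_trials, n_samples), got {self.data.shape}")
        if self.times.shape != (self.data.shape[1],):
            raise ValueError("times length does not match n_samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def time_mask(self, t_start: float, t_end: float) -> np.ndarray:
        return (self.times >= t_start - 1e-12) & (self.times < t_end - 1e-12)

    @classmethod
    def from_epochs(cls, epochs: EpochSet, channel: int = 0) -> "VirtualElectrode":
        """View a single channel of an EpochSet as a virtual electrode."""
        return cls(
            data=epochs.data[:, channel, :],
            fs=epochs.fs,
            times=epochs.times,
            subject_id=epochs.subject_id,
            group=epochs.group,
            pad_s=epochs.pad_s,
            meta=dict(epochs.meta),
        )
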