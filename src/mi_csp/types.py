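"""Shared containers: continuous recordings and epoched trial sets.

A :class:`Recording` holds a continuous multichannel EEG signal in microvolts
together with its sampling rate, channel labels and cue markers.  An
:class:`EpochSet` holds the fixed-length trial windows cut around those
markers, plus the binary class label of every trial.  Both are thin,
validated wrappers around NumPy arrays; all signal processing lives in the
functional modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = ["Recording", "EpochSet"]


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
        One label per channel (e.g. ``"Fp1"``, ``"C3"``).
    markers : sequence of (int, int)
        ``(onset_sample, label)`` pairs with labels in ``{1, 2}``; onsets are
        0-based sample indices into ``data``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    markers: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ConfigurationError(
                f"recording data must be 2-D (channels x samples), got ndim={self.data.ndim}"
            )
        if not np.isfinite(self.data).all():
            raise ConfigurationError("recording contains NaN or Inf samples")
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"CH{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ConfigurationError(
                f"{len(self.channel_labels)} channel labels for {self.n_channels} channels"
            )
        self.channel_labels = [str(c) for c in self.channel_labels]
        self.markers = [(int(o), int(l)) for o, l in self.markers]
        for onset, label in self.markers:
            if not 0 <= onset < self.n_samples:
                raise ConfigurationError(f"marker onset {onset} outside recording")
            if label not in (1, 2):
                raise ConfigurationError(f"marker label must be 1 or 2, got {label}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "Recording":
        """Copy of this recording with the signal replaced (same metadata)."""
        return Recording(
            data=np.asarray(data, dtype=np.float64),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            markers=list(self.markers),
        )

    def marker_labels(self) -> np.ndarray:
        return np.array([l for _, l in self.markers], dtype=np.int64)


@dataclass
class EpochSet:
    """Epoched two-class trials.

    ``data`` has shape ``(n_trials, n_channels, n_samples)``; ``labels`` is the
    per-trial class in ``{1, 2}``.  ``window`` records the epoch boundaries in
    seconds relative to the cue, so ``n_samples == round((end - start) * fs)``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    window: tuple[float, float] = (0.5, 2.5)
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ConfigurationError(
                f"epoch data must be 3-D (trials x channels x samples), got ndim={self.data.ndim}"
            )
        if self.labels.shape != (self.n_trials,):
            raise ConfigurationError(
                f"labels shape {self.labels.shape} does not match {self.n_trials} trials"
            )
        self.window = (float(self.window[0]), float(self.window[1]))
        expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[2] != expected:
            raise ConfigurationError(
                f"window {self.window} at fs={self.fs} implies {expected} samples per "
                f"trial, data has {self.data.shape[2]}"
            )
        if self.channel_labels and len(self.channel_labels) != self.n_channels:
            raise ConfigurationError(
                f"{len(self.channel_labels)} channel labels for {self.n_channels} channels"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "EpochSet":
        """New EpochSet containing the trials at ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            window=self.window,
            channel_labels=list(self.channel_labels),
        )

    def equals(self, other: "EpochSet") -> bool:
        """Bit-exact equality of data, labels and metadata."""
        return (
            np.array_equal(self.data, other.data)
            and np.array_equal(self.labels, other.labels)
            and self.fs == other.fs
            and self.window == other.window
            and list(self.channel_labels) == list(other.channel_labels)
        )
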