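"""Core in-memory containers for multichannel EEG data.

A :class:`Recording` is a channels-by-time array in microvolts with a
sampling rate, ordered channel labels and an event table (sample-index
onsets).  A :class:`LabeledEpochSet` holds fixed-length per-trial segments
cut from recordings together with facial-expression class labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical electrode order used throughout the pipeline (10-20 positions
#: over the prefrontal and motor cortices).
CHANNELS = ("FC5", "FC6", "C3", "C4")

#: The four facial-expression classes: raising brow, furrowing brow,
#: left smirking, right smirking.
CLASSES = ("RB", "FB", "LS", "RS")


@dataclass
class Recording:
    """Multichannel time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs_hz : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Unique ordered channel names.
    events : list of (int, str)
        ``(sample_index, label)`` markers; task onsets carry labels of the
        form ``"task:FB"``.
    """

    samples: np.ndarray
    fs_hz: float
    channel_labels: tuple = CHANNELS
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = tuple(self.channel_labels)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs_hz

    def copy(self) -> "Recording":
        return replace(self, samples=self.samples.copy(),
                       events=list(self.events))


@dataclass
class LabeledEpochSet:
    """Per-trial fixed-length segments with class labels.

    ``epochs`` has shape (n_trials, n_channels, n_times); ``window`` is the
    (start_s, end_s) of each epoch relative to its trial onset.
    """

    epochs: np.ndarray
    labels: list
    fs_hz: float
    channel_labels: tuple = CHANNELS
    window: tuple = (0.0, 4.0)
    session_idx: np.ndarray | None = None
    trial_idx: np.ndarray | None = None

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.size and self.epochs.ndim != 3:
            raise ValueError("epochs must be (trials, channels, times)")
        self.labels = list(self.labels)
        if self.epochs.size and len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal number of epochs")

    @property
    def n_epochs(self) -> int:
        return 0 if self.epochs.size == 0 else self.epochs.shape[0]

    def __len__(self) -> int:
        return self.n_epochs
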