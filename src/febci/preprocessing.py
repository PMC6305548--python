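"""Resampling, band-pass filtering and epoching of raw recordings.

The acquisition chain runs at 1,000 Hz; all analysis happens after
polyphase resampling to 250 Hz and a zero-phase Butterworth band-pass to
3-30 Hz.  The filter order (4) and forward-backward application are this
package's choices; only the band and the Butterworth family are fixed by
the protocol.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .recording import LabeledEpochSet, Recording

log = logging.getLogger(__name__)


def resample(recording: Recording, target_fs_hz: float) -> Recording:
    """Polyphase anti-aliased resampling; event indices are rescaled."""
    if target_fs_hz <= 0:
        raise ValueError("target_fs_hz must be positive")
    if target_fs_hz == recording.fs_hz:
        return recording.copy()
    frac = Fraction(target_fs_hz / recording.fs_hz).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    samples = sps.resample_poly(recording.samples, up, down, axis=1)
    scale = target_fs_hz / recording.fs_hz
    events = [(int(round(idx * scale)), lab) for idx, lab in recording.events]
    return Recording(samples, target_fs_hz, recording.channel_labels, events)


def bandpass(recording: Recording, low_hz: float = 3.0,
             high_hz: float = 30.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel."""
    nyq = recording.fs_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz")
    sos = sps.butter(order, (low_hz, high_hz), btype="bandpass",
                     fs=recording.fs_hz, output="sos")
    samples = sps.sosfiltfilt(sos, recording.samples, axis=1)
    return Recording(samples, recording.fs_hz, recording.channel_labels,
                     list(recording.events))


def epoch(recording: Recording, window_s=(0.0, 4.0)) -> LabeledEpochSet:
    """Cut one epoch per ``task:<label>`` event.

    ``window_s`` is (start, end) in seconds relative to the event sample.
    Epochs that would run past the recording are dropped with a warning.
    """
    start, end = window_s
    n_win = int(round((end - start) * recording.fs_hz))
    epochs, labels = [], []
    for idx, lab in recording.events:
        if not lab.startswith("task:"):
            continue
        i0 = idx + int(round(start * recording.fs_hz))
        i1 = i0 + n_win
        if i0 < 0 or i1 > recording.n_times:
            log.warning("dropping epoch at sample %d: window outside "
                        "recording bounds", idx)
            continue
        epochs.append(recording.samples[:, i0:i1])
        labels.append(lab.split(":", 1)[1])
    if not epochs:
        return LabeledEpochSet(np.empty((0, recording.n_channels, n_win)),
                               [], recording.fs_hz,
                               recording.channel_labels, window_s)
    return LabeledEpochSet(np.stack(epochs), labels, recording.fs_hz,
                           recording.channel_labels, window_s)


def preprocess_trial(recording: Recording, target_fs_hz: float = 250.0,
                     low_hz: float = 3.0, high_hz: float = 30.0) -> Recording:
    """The standard chain: resample then band-pass."""
    return bandpass(resample(recording, target_fs_hz), low_hz, high_hz)
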