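"""File formats: CSV + JSON-sidecar recordings, IMF archives, model files.

The on-disk recording format is a plain columnar CSV (one column per
channel, header row with channel labels) plus a ``<stem>.json`` sidecar
holding the sampling rate, units, labels and the event table.  EDF ingest
is available when ``mne`` is installed (the ``edf`` extra).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import CHANNELS, Recording


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(recording: Recording, path) -> None:
    path = Path(path)
    df = pd.DataFrame(recording.samples.T, columns=recording.channel_labels)
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "fs_hz": recording.fs_hz,
        "units": "uV",
        "channel_labels": list(recording.channel_labels),
        "events": [[int(i), str(lab)] for i, lab in recording.events],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path) -> Recording:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    labels = meta["channel_labels"]
    if list(df.columns) != list(labels):
        raise ValueError(
            f"channel mismatch: CSV columns {list(df.columns)} vs sidecar "
            f"labels {labels}")
    events = [(int(i), str(lab)) for i, lab in meta.get("events", [])]
    return Recording(df.to_numpy().T, float(meta["fs_hz"]),
                     tuple(labels), events)


def read_edf(path, channel_labels=CHANNELS) -> Recording:
    """Read an EDF file, reordering its signals to the canonical channel
    order regardless of the order in the file.  Requires ``mne``."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF support needs the 'edf' extra "
                          "(pip install febci[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    missing = [ch for ch in channel_labels if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"EDF file lacks channels {missing}")
    data = np.stack([raw.get_data(picks=ch)[0] for ch in channel_labels])
    return Recording(data * 1e6, float(raw.info["sfreq"]),
                     tuple(channel_labels))


def write_imfset(imfset, path) -> None:
    """IMFSet to a single .npz archive."""
    np.savez(Path(path), imfs=imfset.imfs, residual=imfset.residual,
             labels=np.array(imfset.channel_labels),
             fs=np.array([imfset.fs_hz]))


def read_imfset(path):
    from .namemd import IMFSet

    with np.load(Path(path), allow_pickle=False) as z:
        return IMFSet(z["imfs"], z["residual"],
                      tuple(str(s) for s in z["labels"]), float(z["fs"][0]))


def save_model(net, scaler, path, extra=None) -> None:
    """BPNN + scaler to a single JSON file."""
    from .classifier import LABEL_CODING

    blob = {
        "params": dict(net.params.__dict__),
        "weights": {k: getattr(net, k).tolist()
                    for k in ("W_in", "b_in", "W_out", "b_out")},
        "scaler": None if scaler is None else {
            "min": scaler.min_.tolist(), "range": scaler.range_.tolist()},
        "coding": {k: list(v) for k, v in LABEL_CODING.items()},
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(blob))


def load_model(path):
    from .classifier import BPNN, NetworkParams
    from .features import MinMaxScaler

    blob = json.loads(Path(path).read_text())
    net = BPNN(NetworkParams(**blob["params"]))
    for k, v in blob["weights"].items():
        setattr(net, k, np.asarray(v, dtype=float))
    scaler = None
    if blob.get("scaler"):
        scaler = MinMaxScaler()
        scaler.min_ = np.asarray(blob["scaler"]["min"], dtype=float)
        scaler.range_ = np.asarray(blob["scaler"]["range"], dtype=float)
    return net, scaler


def write_features_csv(matrix, labels, path) -> None:
    from .features import FEATURE_NAMES

    df = pd.DataFrame(np.asarray(matrix), columns=list(FEATURE_NAMES))
    df.insert(0, "label", list(labels))
    df.to_csv(Path(path), index=False)


def read_features_csv(path):
    df = pd.read_csv(Path(path))
    labels = df.pop("label").tolist()
    return df.to_numpy(dtype=float), labels
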