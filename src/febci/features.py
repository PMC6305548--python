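"""Wavelet band features: db-3 five-level DWT, alpha/theta energy and
variance per channel.

At 250 Hz a 5-level dyadic decomposition splits the 0-125 Hz range into
detail bands halving from 62.5-125 Hz down to 3.90625-7.8125 Hz plus a
0-3.90625 Hz approximation.  The level-4 detail (7.8125-15.625 Hz) is the
alpha band of this paradigm and the level-5 detail (3.90625-7.8125 Hz)
the theta band.  For each of the four channels the feature set is the
coefficient energy (sum of squares) and the population variance of the
alpha and theta coefficients, concatenated into a 16-element vector

    W = [P_a(FC5..C4), P_t(FC5..C4), D_a(FC5..C4), D_t(FC5..C4)].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

log = logging.getLogger(__name__)

FEATURE_NAMES = tuple(
    f"{stat}_{band}_{ch}"
    for stat in ("energy", "variance")
    for band in ("alpha", "theta")
    for ch in ("FC5", "FC6", "C3", "C4")
)

#: canonical rhythm ranges (Hz) used to attach labels to dyadic bands
_RHYTHM_RANGES = {"delta": (0.0, 4.0), "theta": (4.0, 8.0),
                  "alpha": (8.0, 16.0), "beta": (16.0, 32.0),
                  "gamma": (32.0, np.inf)}


@dataclass(frozen=True)
class WaveletConfig:
    basis: str = "db3"
    levels: int = 5
    boundary_mode: str = "symmetric"

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")


@dataclass
class BandCoefficients:
    """Coefficient arrays keyed by rhythm label with their dyadic
    frequency edges in Hz."""

    coeffs: dict
    edges: dict


def dwt_bands(channel_epoch, config: WaveletConfig | None = None,
              fs_hz: float = 250.0) -> BandCoefficients:
    """Decompose a 1-D epoch and map detail levels to rhythm labels.

    Dyadic edges: detail level l spans fs/2**(l+1) .. fs/2**l; the
    approximation spans 0 .. fs/2**(levels+1).  Each rhythm label is
    attached to the band whose centre falls inside its canonical range;
    bands above the labelled range are pooled into gamma.
    """
    config = config or WaveletConfig()
    x = np.asarray(channel_epoch, dtype=float).ravel()
    if x.size < 2 ** config.levels:
        raise ValueError("epoch shorter than 2**levels samples")
    arrs = pywt.wavedec(x, config.basis, mode=config.boundary_mode,
                        level=config.levels)
    # arrs = [cA_L, cD_L, cD_{L-1}, ..., cD_1]
    bands = {}
    edges = {}
    approx_hi = fs_hz / 2 ** (config.levels + 1)
    _assign(bands, edges, arrs[0], (0.0, approx_hi))
    for i, cd in enumerate(arrs[1:]):
        level = config.levels - i
        lo, hi = fs_hz / 2 ** (level + 1), fs_hz / 2 ** level
        _assign(bands, edges, cd, (lo, hi))
    return BandCoefficients(bands, edges)


def _assign(bands, edges, arr, band_edges):
    lo, hi = band_edges
    centre = (lo + min(hi, lo * 2 if lo else hi)) / 2 if np.isinf(hi) else (lo + hi) / 2
    for label, (rlo, rhi) in _RHYTHM_RANGES.items():
        if rlo <= centre < rhi:
            break
    else:  # pragma: no cover
        label = "gamma"
    if label in bands:
        bands[label] = np.concatenate([bands[label], arr])
        edges[label] = (min(edges[label][0], lo), max(edges[label][1], hi))
    else:
        bands[label] = arr
        edges[label] = (lo, hi)


def band_energy(coeffs) -> float:
    """Sum of squared coefficients."""
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("empty coefficient array")
    return float(np.sum(c ** 2))


def band_variance(coeffs) -> float:
    """Population variance (1/n normalisation) of the coefficients."""
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("empty coefficient array")
    return float(np.mean((c - c.mean()) ** 2))


def build_feature_vector(epoch_4ch, config: WaveletConfig | None = None,
                         fs_hz: float = 250.0) -> np.ndarray:
    """16-element feature vector for one 4-channel epoch.

    Layout: alpha energies (4 channels), theta energies, alpha variances,
    theta variances, channels ordered FC5, FC6, C3, C4.
    """
    epoch = np.atleast_2d(np.asarray(epoch_4ch, dtype=float))
    if epoch.shape[0] != 4:
        raise ValueError(f"expected 4 channels, got {epoch.shape[0]}")
    p_a, p_t, d_a, d_t = [], [], [], []
    for c in range(4):
        bands = dwt_bands(epoch[c], config, fs_hz)
        if "alpha" not in bands.coeffs or "theta" not in bands.coeffs:
            raise ValueError(
                f"no dyadic band maps to alpha/theta at fs={fs_hz} Hz with "
                f"{(config or WaveletConfig()).levels} levels; resample to "
                "250 Hz (or deepen the decomposition) first")
        p_a.append(band_energy(bands.coeffs["alpha"]))
        p_t.append(band_energy(bands.coeffs["theta"]))
        d_a.append(band_variance(bands.coeffs["alpha"]))
        d_t.append(band_variance(bands.coeffs["theta"]))
    return np.array(p_a + p_t + d_a + d_t)


def feature_matrix(epochset, config: WaveletConfig | None = None) -> np.ndarray:
    """Stack feature vectors for every epoch in a LabeledEpochSet."""
    return np.array([build_feature_vector(ep, config, epochset.fs_hz)
                     for ep in epochset.epochs])


class MinMaxScaler:
    """Per-feature min-max scaling to [0, 1], fit on training data only.

    Held-out values outside the training range map outside [0, 1] (no
    clipping).  Zero-range features scale to 0 with a logged warning.
    """

    def __init__(self):
        self.min_ = None
        self.range_ = None

    def fit(self, X):
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        if np.any(rng == 0):
            log.warning("zero-range feature(s) at indices %s scaled to 0",
                        np.flatnonzero(rng == 0).tolist())
        self.range_ = np.where(rng == 0, 1.0, rng)
        return self

    def transform(self, X):
        if self.min_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(X, dtype=float) - self.min_) / self.range_

    def fit_transform(self, X):
        return self.fit(X).transform(X)


def normalize_features(train_matrix, apply_matrix=None):
    """Fit a min-max scaler on ``train_matrix`` and apply it to both.

    Returns ``(scaled_train, scaled_apply, scaler)``; ``scaled_apply`` is
    None when no apply matrix is given.
    """
    scaler = MinMaxScaler()
    train_scaled = scaler.fit_transform(train_matrix)
    apply_scaled = None if apply_matrix is None else scaler.transform(apply_matrix)
    return train_scaled, apply_scaled, scaler
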