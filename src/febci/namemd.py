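"""Noise-assisted multivariate empirical mode decomposition (NA-MEMD).

Multivariate EMD decomposes an n-channel signal y(t) into J aligned
intrinsic mode functions plus a residual, y(t) = sum_j h_j(t) + r(t), by
sifting against the mean of envelopes taken along K quasi-uniform
direction vectors on the (n-1)-sphere:

1. generate K direction vectors from a Hammersley point set;
2. project y(t) onto each direction;
3. locate the maxima of each projected signal;
4. interpolate the multivariate signal at those instants to get one
   envelope per direction (directions cover the whole sphere, so antipodal
   directions capture the minima);
5. average the envelopes into m(t);
6. subtract: h(t) = y(t) - m(t);
7. repeat until the sifting stop criterion holds, then peel the IMF off
   and continue on the residual.

The noise-assisted variant appends M white-Gaussian-noise channels before
decomposition and discards their rows of each IMF afterwards; the
broadband noise enforces the quasi-dyadic filter-bank structure of MEMD
and reduces mode mixing.

The sifting stop rule is the multivariate Rilling criterion (the
literature's standard; the amplitude ratio ||m(t)|| / a(t), where a(t) is
the mean spread of the direction envelopes, must fall below theta_1 on at
least (1 - tol) of samples and below theta_2 everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.stats import beta as beta_dist

from .recording import Recording

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37)


@dataclass(frozen=True)
class NAMEMDConfig:
    """NA-MEMD tuning parameters.

    ``n_noise_channels`` (M) white-noise channels are appended at
    ``noise_variance_ratio`` times the mean EEG channel variance.
    ``n_directions`` (K) Hammersley directions are used for projection.
    """

    n_noise_channels: int = 2
    noise_variance_ratio: float = 0.02
    n_directions: int = 64
    max_imfs: int = 10
    sift_thresholds: tuple = (0.075, 0.75, 0.05)
    max_sifts: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_noise_channels < 0 or self.n_directions < 1 \
                or self.max_imfs < 1:
            raise ValueError("invalid NA-MEMD configuration")


@dataclass
class DirectionSet:
    """K unit vectors on the (dim-1)-sphere with their hyperspherical
    angles."""

    vectors: np.ndarray  # (K, dim)
    angles: np.ndarray   # (K, dim-1)


@dataclass
class IMFSet:
    """Aligned IMFs (J x n_channels x T) plus residual (n_channels x T)."""

    imfs: np.ndarray
    residual: np.ndarray
    channel_labels: tuple
    fs_hz: float

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct_full(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residual


def _radical_inverse(i: int, base: int) -> float:
    inv, f = 0.0, 1.0 / base
    while i > 0:
        inv += f * (i % base)
        i //= base
        f /= base
    return inv


def hammersley_directions(K: int, dim: int) -> DirectionSet:
    """Quasi-uniform unit vectors on the (dim-1)-sphere.

    A Hammersley point set in the (dim-1)-cube is pushed through the
    area-preserving hyperspherical map: the i-th polar angle has density
    proportional to sin^(dim-1-i), realised through the Beta quantile of
    its cosine; the final azimuth is uniform on [0, 2*pi).
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if K < 1:
        raise ValueError("K must be >= 1")
    u = np.empty((K, dim - 1))
    u[:, 0] = (np.arange(K) + 0.5) / K
    for j in range(1, dim - 1):
        base = _PRIMES[j - 1]
        u[:, j] = [_radical_inverse(i + 1, base) for i in range(K)]

    angles = np.empty((K, dim - 1))
    vectors = np.ones((K, dim))
    # polar angles theta_i in [0, pi], density ~ sin^(dim-1-i)
    for i in range(dim - 2):
        p = dim - 2 - i  # sin exponent of the i-th polar angle
        a = (p + 1) / 2.0  # cos(theta) ~ shifted Beta((p+1)/2, (p+1)/2)
        cos_t = 2.0 * beta_dist.ppf(u[:, i], a, a) - 1.0
        theta = np.arccos(np.clip(cos_t, -1, 1))
        angles[:, i] = theta
        vectors[:, i] *= np.cos(theta)
        for k in range(i + 1, dim):
            vectors[:, k] *= np.sin(theta)
    phi = 2 * np.pi * u[:, dim - 2]
    angles[:, dim - 2] = phi
    vectors[:, dim - 2] *= np.cos(phi)
    vectors[:, dim - 1] *= np.sin(phi)
    vectors /= np.linalg.norm(vectors, axis=1, keepdims=True)
    return DirectionSet(vectors, angles)


def add_noise_channels(signals: np.ndarray, config: NAMEMDConfig,
                       rng=None) -> np.ndarray:
    """Append M seeded white-Gaussian-noise rows to an (N, T) array."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.size == 0:
        raise ValueError("signals must be non-empty")
    if config.n_noise_channels == 0:
        return signals
    rng = np.random.default_rng(config.seed) if rng is None else rng
    var = config.noise_variance_ratio * signals.var(axis=1).mean()
    noise = rng.standard_normal((config.n_noise_channels,
                                 signals.shape[1])) * np.sqrt(var)
    return np.vstack([signals, noise])


def _natural_spline(knots: np.ndarray, vals: np.ndarray,
                    t: np.ndarray) -> np.ndarray:
    """Natural cubic spline through (knots, vals) evaluated at t.

    ``vals`` is (n_ch, n_knots); all channels share the knot grid, so the
    tridiagonal system is solved once with multiple right-hand sides.
    Falls back to linear interpolation for two knots.
    """
    x = np.asarray(knots, dtype=float)
    n = x.size
    h = np.diff(x)
    if n == 2:
        M = np.zeros_like(vals)
    else:
        # second derivatives: natural ends, tridiagonal interior
        rhs = 6.0 * (np.diff(vals[:, 1:], axis=1) / h[1:]
                     - np.diff(vals[:, :-1], axis=1) / h[:-1])
        ab = np.zeros((3, n - 2))
        ab[0, 1:] = h[1:-1]
        ab[1] = 2.0 * (h[:-1] + h[1:])
        ab[2, :-1] = h[1:-1]
        M = np.zeros_like(vals)
        M[:, 1:-1] = solve_banded((1, 1), ab, rhs.T).T
    idx = np.clip(np.searchsorted(x, t, side="right") - 1, 0, n - 2)
    hl = h[idx]
    dl = t - x[idx]
    dr = x[idx + 1] - t
    y0, y1 = vals[:, idx], vals[:, idx + 1]
    m0, m1 = M[:, idx], M[:, idx + 1]
    return (m0 * dr ** 3 + m1 * dl ** 3) / (6.0 * hl) \
        + (y0 / hl - m0 * hl / 6.0) * dr + (y1 / hl - m1 * hl / 6.0) * dl


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict-then-flat local maxima of a 1-D array."""
    dx = np.diff(x)
    rising = dx > 0
    falling = dx < 0
    idx = np.flatnonzero(rising[:-1] & falling[1:]) + 1
    return idx


def _envelope_mean(y: np.ndarray, dirs: np.ndarray):
    """Mean envelope m(t) and mean envelope spread a(t).

    Returns (m, amp, n_usable) where m is (n_ch, T), amp is (T,), and
    n_usable counts directions with at least two projection maxima.
    """
    n_ch, T = y.shape
    proj = dirs @ y  # (K, T)
    t = np.arange(T)
    m = np.zeros_like(y)
    amp = np.zeros(T)
    usable = 0
    envs = []
    for k in range(proj.shape[0]):
        pk = _local_maxima(proj[k])
        if pk.size < 2:
            continue
        # mirror two extrema about each end to stabilise the spline edges
        left_t = 2 * 0 - pk[:2][::-1]
        right_t = 2 * (T - 1) - pk[-2:][::-1]
        knots = np.concatenate([left_t, pk, right_t])
        vals = np.concatenate([y[:, pk[:2][::-1]], y[:, pk],
                               y[:, pk[-2:][::-1]]], axis=1)
        # mirrored knots can coincide with originals for edge extrema
        knots, uniq = np.unique(knots, return_index=True)
        vals = vals[:, uniq]
        if knots.size < 2:
            continue
        env = _natural_spline(knots, vals, t)
        envs.append(env)
        usable += 1
    if usable == 0:
        return None, None, 0
    envs = np.asarray(envs)          # (usable, n_ch, T)
    m = envs.mean(axis=0)
    amp = np.linalg.norm(envs - m[None], axis=1).mean(axis=0)
    return m, amp, usable


def _n_extrema(x: np.ndarray) -> int:
    return _local_maxima(x).size + _local_maxima(-x).size


def _is_monotone_residual(y: np.ndarray, dirs: np.ndarray) -> bool:
    """True when every projection has fewer than 3 extrema."""
    proj = dirs @ y
    return all(_n_extrema(proj[k]) < 3 for k in range(proj.shape[0]))


def _sift(y: np.ndarray, dirs: np.ndarray, config: NAMEMDConfig):
    th1, th2, tol = config.sift_thresholds
    h = y.copy()
    for _ in range(config.max_sifts):
        m, amp, usable = _envelope_mean(h, dirs)
        if usable == 0:
            break
        sx = np.linalg.norm(m, axis=0) / (amp + 1e-30)
        if (np.mean(sx > th1) < tol) and np.all(sx < th2):
            break
        h = h - m
    return h


def memd(signals: np.ndarray, config: NAMEMDConfig | None = None) -> tuple:
    """Plain multivariate EMD of an (n_ch, T) array.

    Returns ``(imfs, residual)`` with imfs of shape (J, n_ch, T).  The
    decomposition is complete by construction: the IMFs and residual sum
    back to the input exactly up to floating-point error.
    """
    config = config or NAMEMDConfig()
    y = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch, T = y.shape
    if n_ch < 2:
        raise ValueError("multivariate EMD needs at least 2 channels")
    if T < 16:
        raise ValueError("signal too short to sift")
    dirs = hammersley_directions(config.n_directions, n_ch).vectors

    imfs = []
    r = y.copy()
    for _ in range(config.max_imfs):
        if _is_monotone_residual(r, dirs):
            break
        h = _sift(r, dirs, config)
        if not np.any(np.abs(h) > 0):
            break
        imfs.append(h)
        r = r - h
    if not imfs:
        imfs = [np.zeros_like(y)]
    return np.stack(imfs), r


def namemd_decompose(recording_or_array, config: NAMEMDConfig | None = None,
                     fs_hz: float | None = None,
                     channel_labels=None) -> IMFSet:
    """NA-MEMD of an EEG recording: append noise channels, decompose
    jointly, keep only the EEG rows of each IMF."""
    config = config or NAMEMDConfig()
    if isinstance(recording_or_array, Recording):
        y = recording_or_array.samples
        fs_hz = recording_or_array.fs_hz
        channel_labels = recording_or_array.channel_labels
    else:
        y = np.atleast_2d(np.asarray(recording_or_array, dtype=float))
        fs_hz = fs_hz or 1.0
        channel_labels = tuple(channel_labels or
                               [f"ch{i}" for i in range(y.shape[0])])
    n_eeg = y.shape[0]
    aug = add_noise_channels(y, config)
    imfs, residual = memd(aug, config)
    return IMFSet(imfs[:, :n_eeg, :], residual[:n_eeg], channel_labels, fs_hz)


def mean_frequency(x: np.ndarray, fs_hz: float) -> float:
    """Power-weighted mean frequency of a 1-D signal (periodogram based)."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs_hz)
    total = spec.sum()
    if total == 0:
        return 0.0
    return float((freqs * spec).sum() / total)
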