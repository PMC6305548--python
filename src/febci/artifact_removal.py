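"""Sample-entropy scoring of IMFs and EMG-artifact rejection.

Sample entropy SampEn(m, r, N) = -ln(A^m(r) / B^m(r)) measures signal
irregularity: B counts pairs of length-m templates within Chebyshev
distance r (self-matches excluded) and A the same for length m+1.  Facial
EMG is far more irregular than the underlying EEG rhythms, so IMFs whose
channel-averaged SampEn exceeds a fixed threshold (0.45, with m = 2 and
r = 0.2 x the standard deviation of the series being scored) are marked
as artifacts and dropped before reconstruction.  The residual trend is
always retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .namemd import IMFSet
from .recording import Recording

SAMPEN_THRESHOLD = 0.45


@dataclass(frozen=True)
class SampEnParams:
    m: int = 2
    r_factor: float = 0.2

    def __post_init__(self):
        if self.m < 1 or self.r_factor <= 0:
            raise ValueError("require m >= 1 and r_factor > 0")


@dataclass
class ImfMask:
    """Keep/discard decision per IMF with the underlying SampEn matrix
    (n_imfs x n_channels)."""

    keep: np.ndarray
    sampen_values: np.ndarray
    threshold: float = SAMPEN_THRESHOLD


def sample_entropy(series, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r, N) with Chebyshev distance, self-matches excluded.

    Both template lengths use the same N - m starting points (the
    canonical estimator).  Returns ``inf`` when no length-(m+1) pair
    matches; raises if no length-m pair matches (the statistic is then
    undefined).
    """
    x = np.asarray(series, dtype=float).ravel()
    N = x.size
    if N <= m + 1:
        raise ValueError(f"series length {N} too short for m={m}")
    if r is None:
        r = 0.2 * x.std()
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    # template distances by running Chebyshev max over the point-wise
    # |x_i - x_j| matrix; both lengths share the same N - m start points
    D = np.abs(x[:, None] - x[None, :])
    n_t = N - m
    dist = D[:n_t, :n_t].copy()
    for k in range(1, m + 1):
        if k == m:
            dm = dist.copy()  # length-m template distances
        dist = np.maximum(dist, D[k:n_t + k, k:n_t + k])
    dm1 = dist  # length-(m+1) template distances
    iu = np.triu_indices(n_t, k=1)
    B = int(np.count_nonzero(dm[iu] <= r))
    A = int(np.count_nonzero(dm1[iu] <= r))
    if B == 0:
        raise ValueError("degenerate series: no length-m template matches")
    if A == 0:
        return float("inf")
    return float(-np.log(A / B))


def classify_imfs(imfset: IMFSet, params: SampEnParams | None = None,
                  threshold: float = SAMPEN_THRESHOLD) -> ImfMask:
    """Score every IMF channel and discard IMFs whose channel-averaged
    SampEn exceeds ``threshold``.

    The tolerance is ``r_factor`` times the standard deviation of the
    individual IMF channel being scored, so each mode is judged on its own
    scale.  An exactly constant channel scores 0 (perfect regularity).
    """
    params = params or SampEnParams()
    J = imfset.n_imfs if imfset.imfs.size else 0
    if J == 0:
        return ImfMask(np.zeros(0, dtype=bool), np.zeros((0, 0)), threshold)
    n_ch = imfset.imfs.shape[1]
    values = np.zeros((J, n_ch))
    for j in range(J):
        for c in range(n_ch):
            series = imfset.imfs[j, c]
            sd = series.std()
            if sd == 0:
                values[j, c] = 0.0
            else:
                values[j, c] = sample_entropy(series, params.m,
                                              params.r_factor * sd)
    keep = np.nanmean(values, axis=1) <= threshold
    return ImfMask(keep, values, threshold)


def reconstruct(imfset: IMFSet, mask: ImfMask) -> Recording:
    """Clean signal = sum of kept IMFs + residual (always kept)."""
    if mask.keep.size != imfset.n_imfs:
        raise ValueError("mask length does not match IMF count")
    clean = imfset.residual.copy()
    for j in np.flatnonzero(mask.keep):
        clean = clean + imfset.imfs[j]
    return Recording(clean, imfset.fs_hz, imfset.channel_labels)


def denoise(recording: Recording, namemd_config=None,
            params: SampEnParams | None = None,
            threshold: float = SAMPEN_THRESHOLD):
    """Full artifact-removal chain: NA-MEMD -> SampEn mask -> reconstruct.

    Returns ``(clean_recording, mask, imfset)``.
    """
    from .namemd import NAMEMDConfig, namemd_decompose

    imfset = namemd_decompose(recording, namemd_config or NAMEMDConfig())
    mask = classify_imfs(imfset, params, threshold)
    return reconstruct(imfset, mask), mask, imfset
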