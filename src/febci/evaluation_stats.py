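"""Statistical machinery for classifier evaluation.

* exact binomial chance level for an n-trial, c-class experiment;
* one-way fixed-effects ANOVA with eta-squared and Cohen's f;
* power-based total sample size from the noncentral F distribution;
* class-pair correlation topography over grand-average waveforms;
* FFT periodogram and STFT spectrogram diagnostics.

The chance level is the smallest achievable accuracy a random classifier
exceeds with probability at most alpha: with X ~ Binomial(n, 1/c), it is
100 * k*/n where k* is the smallest integer whose binomial CDF reaches
1 - alpha.  The inversion is exact (no normal approximation); at
alpha = 0.05 and 4 classes it gives 29.58% for 240 trials, 35% for 60
trials and 26.09% for 4,320 trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

#: Cohen's f benchmarks: small / medium / large.
COHENS_F_BENCHMARKS = (("small", 0.10), ("medium", 0.25), ("large", 0.40))


@dataclass
class AnovaResult:
    F: float
    p: float
    eta_squared: float
    cohens_f: float
    df_between: int
    df_error: int
    effect_label: str


def chance_level(n_trials: int, n_classes: int, alpha: float = 0.05) -> float:
    """Chance-level accuracy in percent via exact binomial inversion."""
    if n_trials < 1 or n_classes < 2 or not 0 < alpha < 1:
        raise ValueError("invalid chance-level query")
    # smallest k with CDF(k) >= 1 - alpha
    k_star = int(stats.binom.ppf(1 - alpha, n_trials, 1.0 / n_classes))
    # ppf guarantees CDF(k_star) >= 1 - alpha; guard against edge rounding
    while stats.binom.cdf(k_star, n_trials, 1.0 / n_classes) < 1 - alpha:
        k_star += 1  # pragma: no cover
    return 100.0 * k_star / n_trials


def classify_effect_size(f: float) -> str:
    """Map Cohen's f onto the small/medium/large benchmark labels."""
    label = "negligible"
    for name, cut in COHENS_F_BENCHMARKS:
        if f >= cut:
            label = name
    return label


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA from the sums-of-squares decomposition.

    ``groups`` is a sequence of 1-D samples.  eta^2 = SS_between/SS_total
    and Cohen's f = sqrt(eta^2 / (1 - eta^2)).
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ss_total = ss_between + ss_within
    df_b = len(groups) - 1
    df_e = all_x.size - len(groups)
    if ss_total == 0:
        raise ValueError("degenerate groups: zero total variance, "
                         "F undefined")
    ms_b, ms_e = ss_between / df_b, ss_within / df_e
    if ms_e == 0:
        F = np.inf
        p = 0.0
    else:
        F = ms_b / ms_e
        p = float(stats.f.sf(F, df_b, df_e))
    eta2 = ss_between / ss_total
    cohens_f = np.sqrt(eta2 / (1 - eta2)) if eta2 < 1 else np.inf
    return AnovaResult(float(F), p, float(eta2), float(cohens_f),
                       df_b, df_e, classify_effect_size(cohens_f))


def anova_power(f: float, n_total: int, k_groups: int,
                alpha: float = 0.05) -> float:
    """Power of a one-way fixed-effects ANOVA with noncentrality
    lambda = f**2 * N."""
    df_b, df_e = k_groups - 1, n_total - k_groups
    if df_e < 1:
        return 0.0
    crit = stats.f.isf(alpha, df_b, df_e)
    return float(stats.ncf.sf(crit, df_b, df_e, f ** 2 * n_total))


def anova_sample_size(f: float, alpha: float = 0.05, power: float = 0.8,
                      k_groups: int = 4, n_max: int = 10 ** 6) -> int:
    """Smallest total N whose one-way ANOVA reaches the requested power."""
    if f <= 0 or not 0 < alpha < 1 or not 0 < power < 1 or k_groups < 2:
        raise ValueError("invalid power query")
    for n in range(k_groups + 1, n_max + 1):
        if anova_power(f, n, k_groups, alpha) >= power:
            return n
    raise ValueError(f"requested power unreachable within N <= {n_max}")


def correlation_map(grand_averages_by_class) -> dict:
    """Pearson correlation between class grand-average waveforms, per
    channel.

    ``grand_averages_by_class`` maps class label -> (n_channels, T) array.
    Returns {(class_a, class_b): r-vector over channels}; zero-variance
    waveforms yield NaN with a flag left to the caller (NaN propagates).
    """
    items = sorted(grand_averages_by_class.items())
    shapes = {np.asarray(v).shape for _, v in items}
    if len(shapes) != 1:
        raise ValueError("grand averages must share channels and length")
    out = {}
    for i, (la, wa) in enumerate(items):
        for lb, wb in items[i + 1:]:
            wa_, wb_ = np.atleast_2d(wa), np.atleast_2d(wb)
            rs = []
            for c in range(wa_.shape[0]):
                a, b = wa_[c] - wa_[c].mean(), wb_[c] - wb_[c].mean()
                denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
                rs.append(np.nan if denom == 0 else float((a * b).sum() / denom))
            out[(la, lb)] = np.array(rs)
    return out


def spectrum(signal, fs_hz: float):
    """One-sided periodogram (rectangular window): (freqs, power)."""
    x = np.asarray(signal, dtype=float).ravel()
    freqs, pxx = sps.periodogram(x, fs=fs_hz, window="boxcar",
                                 scaling="spectrum", detrend=False)
    return freqs, pxx


def band_power(signal, fs_hz: float, low_hz: float, high_hz: float) -> float:
    """Integrated periodogram power inside [low_hz, high_hz)."""
    freqs, pxx = spectrum(signal, fs_hz)
    sel = (freqs >= low_hz) & (freqs < high_hz)
    return float(pxx[sel].sum())


def time_frequency(signal, fs_hz: float, window_s: float = 0.5,
                   overlap_frac: float = 0.9):
    """Hann-window magnitude spectrogram: (freqs, times, |S|)."""
    x = np.asarray(signal, dtype=float).ravel()
    nper = int(round(window_s * fs_hz))
    if nper > x.size:
        raise ValueError("window longer than signal")
    nover = int(nper * overlap_frac)
    freqs, times, S = sps.stft(x, fs=fs_hz, window="hann", nperseg=nper,
                               noverlap=nover, boundary=None, padded=False)
    return freqs, times, np.abs(S)
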