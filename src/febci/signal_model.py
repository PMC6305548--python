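"""Synthetic 4-channel EEG generator with class-conditioned band signatures.

Real recordings for the facial-expression paradigm are not publicly
available, so this module synthesises trials whose task windows carry the
qualitative alpha/theta signatures reported for the four expressions:

* RB (raising brow)   — theta increase over the prefrontal pair (FC5, FC6);
* FB (furrowing brow) — alpha increase with theta decrease, stronger over
  the right hemisphere (FC6, C4);
* LS / RS (smirking)  — contralateral alpha increase and ipsilateral alpha
  decrease over the motor pair (C3, C4).

Each trial is pink (1/f) background noise plus amplitude-modulated alpha
and theta oscillations whose amplitudes are scaled by per-channel class
gains during the task window, plus band-limited (30–100 Hz) EMG bursts
gated on during the task window only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .recording import CHANNELS, CLASSES, LabeledEpochSet, Recording

ALPHA_BAND = (8.0, 16.0)
THETA_BAND = (4.0, 8.0)


@dataclass(frozen=True)
class ClassSignature:
    """Per-channel alpha/theta amplitude multipliers for one class.

    Gains are unitless and strictly positive, ordered (FC5, FC6, C3, C4).
    They multiply the oscillation *amplitude* during the task window, so a
    gain g yields a band-power ratio of g**2 against a gain-1 channel.
    """

    class_label: str
    alpha_gain: tuple
    theta_gain: tuple

    def __post_init__(self):
        for name, gains in (("alpha", self.alpha_gain),
                            ("theta", self.theta_gain)):
            if len(gains) != 4:
                raise ValueError(f"{name}_gain needs 4 entries, one per channel")
            if any(g <= 0 for g in gains):
                raise ValueError(f"{name}_gain entries must be positive")


def _fb_gains(base: float, right_depth_scale: float = 1.2):
    # modulation depth (gain - 1) scaled on the right-hemisphere channels
    right = 1.0 + (base - 1.0) * right_depth_scale
    return (base, right, base, right)


#: Default gain table.  Directions follow the reported topography; the
#: magnitudes are configurable stand-ins (roughly 1.5-1.6x amplitude).
DEFAULT_SIGNATURES = {
    "RB": ClassSignature("RB", alpha_gain=(1.0, 1.0, 1.0, 1.0),
                         theta_gain=(1.5, 1.5, 1.0, 1.0)),
    "FB": ClassSignature("FB", alpha_gain=_fb_gains(1.5),
                         theta_gain=_fb_gains(0.6)),
    "LS": ClassSignature("LS", alpha_gain=(1.0, 1.0, 0.6, 1.6),
                         theta_gain=(1.0, 1.0, 1.0, 1.0)),
    "RS": ClassSignature("RS", alpha_gain=(1.0, 1.0, 1.6, 0.6),
                         theta_gain=(1.0, 1.0, 1.0, 1.0)),
}


@dataclass(frozen=True)
class TrialTiming:
    """Trial phase durations in seconds (prep cue, task, rest)."""

    prep_s: float = 2.0
    task_s: float = 4.0
    rest_s: float = 2.0
    trials_per_session: int = 6

    def __post_init__(self):
        if min(self.prep_s, self.task_s, self.rest_s) <= 0:
            raise ValueError("all durations must be positive")
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")

    @property
    def trial_s(self) -> float:
        return self.prep_s + self.task_s + self.rest_s


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    ``background_uV`` is the broadband standard deviation of the 1/f
    background; ``base_alpha_uV``/``base_theta_uV`` are baseline oscillation
    amplitudes (peak, microvolts); ``emg_amp_uV`` is the within-burst EMG
    standard deviation.
    """

    fs_hz: float = 1000.0
    background_exponent: float = 1.0
    background_uV: float = 1.5
    base_alpha_uV: float = 8.0
    base_theta_uV: float = 8.0
    emg_amp_uV: float = 10.0
    emg_band_hz: tuple = (30.0, 100.0)
    emg_tonic_floor: float = 0.7
    ramp_s: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.fs_hz < 2 * self.emg_band_hz[1]:
            raise ValueError("fs_hz must be at least twice the EMG band edge")


def _pink_noise(rng, n, fs, exponent, std):
    """Spectrally shaped Gaussian noise with PSD ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC
    out = np.fft.irfft(spec * shaping, n)
    s = out.std()
    return out * (std / s) if s > 0 else out


def _task_gate(n, fs, prep_s, task_s, ramp_s):
    """0/1 gate over the task window with raised-cosine edges."""
    gate = np.zeros(n)
    i0, i1 = int(round(prep_s * fs)), int(round((prep_s + task_s) * fs))
    gate[i0:i1] = 1.0
    nr = max(1, int(round(ramp_s * fs)))
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
    if i0 + nr <= i1:
        gate[i0:i0 + nr] = ramp
        gate[i1 - nr:i1] = ramp[::-1]
    return gate


def _oscillation(rng, t, band, base_amp):
    """Amplitude-modulated sinusoid: random phase, +/-10% frequency jitter
    around the band centre, slow sinusoidal AM to avoid a line spectrum."""
    f0 = 0.5 * (band[0] + band[1])
    f = f0 * (1.0 + rng.uniform(-0.1, 0.1))
    phase = rng.uniform(0, 2 * np.pi)
    am = 1.0 + 0.1 * np.sin(2 * np.pi * rng.uniform(0.2, 0.6) * t
                            + rng.uniform(0, 2 * np.pi))
    return base_amp * am * np.sin(2 * np.pi * f * t + phase)


def _emg_burst_train(rng, n, fs, prep_s, task_s, band, amp, tonic_floor):
    """Sustained band-limited muscle noise over the task window.

    A held facial expression produces tonic EMG for the full task, so the
    burst envelope rides on a tonic floor: 2-4 random accentuation
    intervals reach full amplitude while the rest of the task window
    stays at ``tonic_floor`` times the burst amplitude.  (A fully gated
    on/off train would leave long silent stretches whose template
    self-similarity masks the irregularity that the sample-entropy
    screen keys on.)
    """
    if amp <= 0:
        return np.zeros(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    noise = sps.sosfilt(sos, rng.standard_normal(n))
    s = noise.std()
    if s > 0:
        noise *= amp / s
    burst = np.zeros(n)
    n_bursts = rng.integers(2, 5)
    t0, t1 = prep_s, prep_s + task_s
    for _ in range(n_bursts):
        dur = rng.uniform(0.3, 1.0)
        start = rng.uniform(t0, max(t0, t1 - dur))
        i0, i1 = int(start * fs), min(n, int((start + dur) * fs))
        burst[i0:i1] = 1.0
    # soften burst edges (20 ms smoothing) so bursts are not step-gated
    k = max(1, int(0.02 * fs))
    burst = np.convolve(burst, np.ones(k) / k, mode="same")
    task = np.zeros(n)
    task[int(t0 * fs):int(t1 * fs)] = 1.0
    envelope = task * (tonic_floor + (1.0 - tonic_floor) * burst)
    return noise * envelope


def generate_trial(class_label, signature=None, timing=None, config=None,
                   seed=None):
    """Generate one synthetic trial as a :class:`Recording`.

    The recording spans prep + task + rest; a ``task:<label>`` event marks
    the task onset.  Oscillation amplitudes are multiplied by the class
    gains during the task window only; EMG bursts appear only during the
    task window.
    """
    timing = timing or TrialTiming()
    config = config or SyntheticConfig()
    if signature is None:
        if class_label not in DEFAULT_SIGNATURES:
            raise KeyError(f"unknown class label {class_label!r}; "
                           f"expected one of {CLASSES}")
        signature = DEFAULT_SIGNATURES[class_label]
    rng = np.random.default_rng(config.seed if seed is None else seed)

    fs = config.fs_hz
    n = int(round(timing.trial_s * fs))
    t = np.arange(n) / fs
    gate = _task_gate(n, fs, timing.prep_s, timing.task_s, config.ramp_s)

    samples = np.empty((4, n))
    for c in range(4):
        bg = _pink_noise(rng, n, fs, config.background_exponent,
                         config.background_uV)
        alpha = _oscillation(rng, t, ALPHA_BAND, config.base_alpha_uV)
        theta = _oscillation(rng, t, THETA_BAND, config.base_theta_uV)
        # amplitude ramps from 1 to the class gain inside the task window
        a_scale = 1.0 + (signature.alpha_gain[c] - 1.0) * gate
        t_scale = 1.0 + (signature.theta_gain[c] - 1.0) * gate
        emg = _emg_burst_train(rng, n, fs, timing.prep_s, timing.task_s,
                               config.emg_band_hz, config.emg_amp_uV,
                               config.emg_tonic_floor)
        samples[c] = bg + a_scale * alpha + t_scale * theta + emg

    onset = int(round(timing.prep_s * fs))
    return Recording(samples, fs, CHANNELS,
                     events=[(onset, f"task:{signature.class_label}")])


def generate_dataset(n_sessions=10, per_class_counts=None, timing=None,
                     config=None, seed=0, signatures=None):
    """Generate a labeled set of task-window epochs.

    With ``per_class_counts=None`` the four classes are cycled in a
    balanced round-robin over ``n_sessions`` sessions of
    ``timing.trials_per_session`` trials.  Epochs are the raw task windows
    at the generator rate (no filtering).
    """
    timing = timing or TrialTiming()
    config = config or SyntheticConfig()
    signatures = signatures or DEFAULT_SIGNATURES

    if per_class_counts is None:
        total = n_sessions * timing.trials_per_session
        labels = [CLASSES[i % 4] for i in range(total)]
    else:
        labels = []
        for cls, cnt in per_class_counts.items():
            if cnt < 0:
                raise ValueError("per-class counts must be >= 0")
            labels.extend([cls] * cnt)
    if not labels:
        raise ValueError("requested dataset has zero trials")

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                   for s in ss.spawn(len(labels))]

    i0 = int(round(timing.prep_s * config.fs_hz))
    i1 = i0 + int(round(timing.task_s * config.fs_hz))
    per = timing.trials_per_session
    epochs, sess_idx, trial_idx = [], [], []
    for k, (lab, s) in enumerate(zip(labels, child_seeds)):
        rec = generate_trial(lab, signatures[lab], timing, config, seed=s)
        epochs.append(rec.samples[:, i0:i1])
        sess_idx.append(k // per)
        trial_idx.append(k % per)

    return LabeledEpochSet(np.stack(epochs), labels, config.fs_hz, CHANNELS,
                           window=(timing.prep_s, timing.prep_s + timing.task_s),
                           session_idx=np.array(sess_idx),
                           trial_idx=np.array(trial_idx))
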