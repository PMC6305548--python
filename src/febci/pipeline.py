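"""End-to-end orchestration of the processing chain.

Offline: simulate (or load) trials -> resample to 250 Hz -> 3-30 Hz
band-pass -> NA-MEMD + SampEn denoising -> wavelet features -> BPNN with
stratified 5-fold cross-validation.

Online: per scripted trial, classify the trailing window at each
scheduled decision point, latch the first decision, drive the prosthesis
state machine and score the session against the drinking-water script.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import artifact_removal, classifier, features, online_control
from .config import PipelineConfig
from .namemd import NAMEMDConfig
from .preprocessing import epoch, preprocess_trial
from .recording import CHANNELS, CLASSES, LabeledEpochSet, Recording
from .signal_model import DEFAULT_SIGNATURES, generate_trial

log = logging.getLogger(__name__)


def _child_seeds(seed: int, n: int):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def make_offline_dataset(config: PipelineConfig, denoise: bool = True,
                         labels=None) -> LabeledEpochSet:
    """Generate, preprocess and (optionally) denoise a labeled epoch set.

    Trials are generated one by one at the acquisition rate, resampled
    and band-passed, cut to the task window and denoised epoch-wise.
    """
    timing, gen = config.timing, config.generator
    if labels is None:
        total = config.n_sessions * timing.trials_per_session
        labels = [CLASSES[i % 4] for i in range(total)]
    seeds = _child_seeds(config.seed, len(labels))
    pp = config.preprocessing
    epochs = []
    for lab, s in zip(labels, seeds):
        rec = generate_trial(lab, DEFAULT_SIGNATURES[lab], timing, gen,
                             seed=s)
        clean = preprocess_trial(rec, pp.target_fs_hz, pp.low_hz, pp.high_hz)
        es = epoch(clean, (0.0, timing.task_s))
        ep = es.epochs[0]
        if denoise:
            ncfg = NAMEMDConfig(**{**config.namemd.__dict__, "seed": s})
            rec_ep = Recording(ep, pp.target_fs_hz, CHANNELS)
            ep = artifact_removal.denoise(rec_ep, ncfg, config.sampen,
                                          config.stats.sampen_threshold
                                          )[0].samples
        epochs.append(ep)
    return LabeledEpochSet(np.stack(epochs), labels, pp.target_fs_hz,
                           CHANNELS, window=(0.0, timing.task_s))


def run_offline(config: PipelineConfig, denoise: bool = True,
                out_dir=None) -> dict:
    """Full offline experiment: dataset -> features -> 5-fold CV report."""
    dataset = make_offline_dataset(config, denoise=denoise)
    X = features.feature_matrix(dataset, config.wavelet)
    cv = classifier.crossvalidate(X, dataset.labels, k=5, seed=config.seed,
                                  params=config.network)
    report = {
        "n_trials": len(dataset),
        "fold_accuracies_pct": cv["fold_accuracies"].tolist(),
        "mean_accuracy_pct": cv["mean"],
        "sd_accuracy_pct": cv["sd"],
        "seed": config.seed,
        "config_hash": config_hash(config),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        from .io import write_features_csv

        write_features_csv(X, dataset.labels, out_dir / "features.csv")
        (out_dir / "cv_report.json").write_text(json.dumps(report, indent=1))
    return {**report, "dataset": dataset, "features": X}


def train_full(config: PipelineConfig, window_s: float | None = None,
               denoise: bool = True, dataset: LabeledEpochSet | None = None):
    """Train one network on the full offline dataset.

    ``window_s`` restricts training epochs to their leading sub-window so
    the classifier sees the same epoch length the online decision loop
    will present (decision windows are ``online.window_s`` long).  A
    pre-built ``dataset`` (e.g. the one used for offline CV) is reused
    when given.
    """
    if dataset is None:
        dataset = make_offline_dataset(config, denoise=denoise)
    eps = dataset.epochs
    if window_s is not None:
        n = int(round(window_s * dataset.fs_hz))
        eps = eps[:, :, :n]
    X = np.array([features.build_feature_vector(ep, config.wavelet,
                                                dataset.fs_hz)
                  for ep in eps])
    Xs, _, scaler = features.normalize_features(X)
    net = classifier.train_classifier(Xs, dataset.labels, config.network)
    return net, scaler


def _online_decider(trial_epoch, fs_hz, net, scaler, config,
                    denoise: bool = True):
    """Build the decide(t_rel) callable for one task-window epoch."""

    def decide(t_rel_s: float):
        i1 = int(round(t_rel_s * fs_hz))
        i0 = max(0, i1 - int(round(config.online.window_s * fs_hz)))
        window = trial_epoch[:, i0:i1]
        if window.shape[1] < 2 ** config.wavelet.levels:
            return None
        try:
            x = window
            if denoise:
                rec = Recording(x, fs_hz, CHANNELS)
                x = artifact_removal.denoise(rec, config.namemd,
                                             config.sampen,
                                             config.stats.sampen_threshold
                                             )[0].samples
            fv = features.build_feature_vector(x, config.wavelet, fs_hz)
            labels, _ = net.predict(scaler.transform(fv[None]))
            return labels[0]
        except Exception as exc:  # classification failure -> skip point
            log.warning("decision point at %.1f s failed: %s", t_rel_s, exc)
            return None

    return decide


def run_online_session(net, scaler, config: PipelineConfig, seed: int,
                       denoise: bool = True):
    """Simulate one scripted six-trial session with a trained network."""
    script_classes = [online_control.CLASS_FOR_COMMAND[c]
                      for c in online_control.SESSION_SCRIPT]
    seeds = _child_seeds(seed, len(script_classes))
    pp, timing = config.preprocessing, config.timing
    deciders = []
    for lab, s in zip(script_classes, seeds):
        rec = generate_trial(lab, DEFAULT_SIGNATURES[lab], timing,
                             config.generator, seed=s)
        clean = preprocess_trial(rec, pp.target_fs_hz, pp.low_hz, pp.high_hz)
        ep = epoch(clean, (0.0, timing.task_s)).epochs[0]
        deciders.append(_online_decider(ep, pp.target_fs_hz, net, scaler,
                                        config, denoise))
    return online_control.run_session(
        deciders, trial_len_s=timing.task_s, first_s=config.online.first_s,
        step_s=config.online.step_s,
        majority_vote=config.online.majority_vote)


def run_online(config: PipelineConfig, net=None, scaler=None,
               denoise: bool = True, out_dir=None,
               dataset: LabeledEpochSet | None = None) -> dict:
    """Train (if needed) and simulate ``online.n_sessions`` sessions."""
    if net is None:
        net, scaler = train_full(config, window_s=config.online.window_s,
                                 denoise=denoise, dataset=dataset)
    seeds = _child_seeds(config.seed + 1, config.online.n_sessions)
    sessions = [run_online_session(net, scaler, config, s, denoise)
                for s in seeds]
    accs = [s.accuracy_pct for s in sessions]
    report = {
        "session_accuracies_pct": accs,
        "mean_accuracy_pct": float(np.mean(accs)),
        "sd_accuracy_pct": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
        "seed": config.seed,
        "config_hash": config_hash(config),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "online_report.json").write_text(
            json.dumps({**report,
                        "sessions": [s.trials for s in sessions]}, indent=1))
    return {**report, "sessions": sessions}


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
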