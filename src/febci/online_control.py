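"""Online protocol simulation: decision scheduling, command latching, the
200-ms actuation delay, the 2-DOF prosthesis state machine and session
scoring against the drinking-water script.

Expression-to-command map: RB -> hand open (HO), FB -> hand close (HC),
LS -> wrist rotate right (WRR), RS -> wrist rotate left (WRL).  During a
trial, decisions are produced every 0.5 s starting 2.5 s after task onset;
the FIRST decision is latched as the trial's command (the classifier is
then idle until the next trial) and reaches the prosthesis 200 ms after
issue.  A session is the fixed six-step script HO-HC-WRR-WRL-HO-HC and is
scored as the fraction of steps whose issued command matches the script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

COMMAND_MAP = {"RB": "HO", "FB": "HC", "LS": "WRR", "RS": "WRL"}
CLASS_FOR_COMMAND = {v: k for k, v in COMMAND_MAP.items()}
SESSION_SCRIPT = ("HO", "HC", "WRR", "WRL", "HO", "HC")
COMMAND_DELAY_S = 0.2


_WRIST_POSITIONS = ("left", "neutral", "right")


@dataclass
class ProsthesisState:
    """2-DOF prosthesis: hand open/closed and a 3-position wrist.

    Wrist rotations are incremental: WRR steps the orientation index
    toward ``right`` and WRL toward ``left`` (clamped at the end stops),
    so the script's WRR-then-WRL pair returns the wrist to neutral.
    """

    hand: str = "open"
    wrist: str = "neutral"
    log: list = field(default_factory=list)

    def apply(self, command: str, time_s: float):
        if command == "HO":
            self.hand = "open"
        elif command == "HC":
            self.hand = "closed"
        elif command in ("WRR", "WRL"):
            idx = _WRIST_POSITIONS.index(self.wrist)
            idx += 1 if command == "WRR" else -1
            self.wrist = _WRIST_POSITIONS[np.clip(idx, 0, 2)]
        else:
            raise ValueError(f"unknown command {command!r}")
        self.log.append((time_s, command, self.hand, self.wrist))


@dataclass
class TrialLog:
    decision_time_s: float | None
    label: str | None
    command: str | None
    executed_at_s: float | None


@dataclass
class SessionResult:
    trials: list
    accuracy_pct: float
    final_state: ProsthesisState


def schedule_decisions(trial_start_s: float, trial_len_s: float,
                       first_s: float = 2.5, step_s: float = 0.5):
    """Decision times ``trial_start + first_s, +step_s, ...`` up to and
    including the trial end."""
    if trial_len_s <= 0:
        raise ValueError("trial_len_s must be positive")
    times = []
    t = first_s
    while t <= trial_len_s + 1e-9:
        times.append(trial_start_s + t)
        t += step_s
    return times


def run_trial(decide, trial_start_s: float, schedule,
              state: ProsthesisState | None = None,
              majority_vote: bool = False) -> TrialLog:
    """Run the decision loop for one trial.

    ``decide(t_rel)`` maps a decision time (seconds relative to task
    onset) to a class label or None (classification failure -> skip to
    next point).  The first successful decision is latched; with
    ``majority_vote`` the labels of all decision points are collected and
    the modal label is issued at the last point instead.
    """
    votes = []
    decision_t = None
    for t_abs in schedule:
        label = decide(t_abs - trial_start_s)
        if label is None:
            continue
        votes.append(label)
        decision_t = t_abs
        if not majority_vote:
            break
    if not votes:
        return TrialLog(None, None, None, None)
    if majority_vote:
        labels, counts = np.unique(votes, return_counts=True)
        label = str(labels[np.argmax(counts)])
    else:
        label = votes[0]
    command = COMMAND_MAP[label]
    exec_t = decision_t + COMMAND_DELAY_S
    if state is not None:
        state.apply(command, exec_t)
    return TrialLog(decision_t, label, command, exec_t)


def run_session(decide_per_trial, trial_len_s: float = 4.0,
                first_s: float = 2.5, step_s: float = 0.5,
                majority_vote: bool = False) -> SessionResult:
    """Score one six-trial session against the drinking-water script.

    ``decide_per_trial`` is a sequence of six per-trial ``decide``
    callables (one per script step).
    """
    if len(decide_per_trial) != len(SESSION_SCRIPT):
        raise ValueError(f"a session has exactly {len(SESSION_SCRIPT)} trials")
    state = ProsthesisState()
    trials = []
    n_correct = 0
    for i, (decide, target) in enumerate(zip(decide_per_trial,
                                             SESSION_SCRIPT)):
        t0 = i * (trial_len_s + first_s)  # nominal trial spacing
        sched = schedule_decisions(t0, trial_len_s, first_s, step_s)
        tl = run_trial(decide, t0, sched, state, majority_vote)
        correct = tl.command == target
        n_correct += int(correct)
        trials.append({"target": target, "issued": tl.command,
                       "label": tl.label, "decision_time_s": tl.decision_time_s,
                       "executed_at_s": tl.executed_at_s, "correct": correct})
    acc = 100.0 * n_correct / len(SESSION_SCRIPT)
    return SessionResult(trials, acc, state)
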