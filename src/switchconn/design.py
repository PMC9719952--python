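"""Cued task-switching trial designs.

The paradigm alternates between two cued tasks (a shape judgement and a
color judgement).  On each trial a cue — either the full task word or its
first letter — announces which task to perform.  A trial is a *switch*
trial when its cued task differs from the task of the immediately
preceding trial and a *repeat* trial otherwise; the first trial has no
predecessor and is counted as a repeat, so the switch/repeat counts always
partition the run exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TASKS = ("shape", "color")
CUES = ("full_word", "single_letter")
SWITCH = "switch"
REPEAT = "repeat"

#: Run layout of the cued task-switching paradigm emulated here.
DEFAULT_N_TRIALS = 96
DEFAULT_N_SWITCH = 24
DEFAULT_TR_S = 2.0
DEFAULT_ITI_S = 6.0


@dataclass(frozen=True)
class Trial:
    """One cued trial: onset (s), task identity, cue form, and condition."""

    onset_s: float
    task: str
    cue: str
    condition: str


@dataclass
class TrialDesign:
    """An ordered run of cued task-switching trials.

    Invariants (checked on construction): onsets strictly increasing and
    inside ``[0, n_scans * tr_s)``; the condition labels are consistent
    with the task sequence (switch iff the task changed; trial 1 repeat).
    """

    trials: list[Trial]
    tr_s: float
    n_scans: int

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        onsets = self.onsets
        if len(onsets) == 0:
            raise ValueError("a design needs at least one trial")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("trial onsets must be strictly increasing")
        run_end = self.n_scans * self.tr_s
        if onsets[0] < 0 or onsets[-1] >= run_end:
            raise ValueError(
                f"onsets must lie in [0, {run_end}); got range "
                f"[{onsets[0]}, {onsets[-1]}]"
            )
        tasks = self.tasks
        for t, trial in enumerate(self.trials):
            expect = REPEAT if t == 0 else (
                SWITCH if tasks[t] != tasks[t - 1] else REPEAT
            )
            if trial.condition != expect:
                raise ValueError(
                    f"trial {t} labeled {trial.condition!r} but task sequence "
                    f"implies {expect!r}"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset_s for t in self.trials], dtype=float)

    @property
    def tasks(self) -> list[str]:
        return [t.task for t in self.trials]

    @property
    def cues(self) -> list[str]:
        return [t.cue for t in self.trials]

    @property
    def conditions(self) -> list[str]:
        return [t.condition for t in self.trials]

    @property
    def n_switch(self) -> int:
        return sum(c == SWITCH for c in self.conditions)

    @property
    def n_repeat(self) -> int:
        return sum(c == REPEAT for c in self.conditions)

    def condition_mask(self, condition: str) -> np.ndarray:
        """Boolean mask over trials for one condition label."""
        return np.array([c == condition for c in self.conditions])


def generate_task_design(
    n_trials: int = DEFAULT_N_TRIALS,
    n_switch: int = DEFAULT_N_SWITCH,
    tr_s: float = DEFAULT_TR_S,
    iti_s: float = DEFAULT_ITI_S,
    jitter_s: float = 1.0,
    start_s: float = 6.0,
    tail_s: float = 24.0,
    seed: int | np.random.Generator | None = None,
) -> TrialDesign:
    """Generate a pseudorandomized cued task-switching run.

    Exactly ``n_switch`` trials have a task different from their
    predecessor; the remaining ``n_trials - n_switch`` (including trial 1)
    are repeats.  Trials sit on a jittered onset grid with mean
    inter-trial interval ``iti_s`` and uniform jitter ``±jitter_s``,
    starting at ``start_s``; the run length leaves ``tail_s`` seconds
    after the last onset for the hemodynamic response to resolve.

    Parameters
    ----------
    n_trials, n_switch:
        Total trial count and exact number of switch trials;
        requires ``0 <= n_switch <= n_trials - 1``.
    seed:
        Any :func:`numpy.random.default_rng` seed; the same seed
        reproduces the design bit for bit.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 <= n_switch <= n_trials - 1:
        raise ValueError(
            f"n_switch must be in [0, {n_trials - 1}] for {n_trials} trials; "
            f"got {n_switch}"
        )
    if iti_s <= 2 * jitter_s:
        raise ValueError("iti_s must exceed twice the jitter to keep onsets ordered")
    rng = np.random.default_rng(seed)

    # Choose which of the n_trials - 1 transitions are switches, then let
    # the task sequence follow from a random starting task.
    transitions = np.zeros(n_trials, dtype=bool)
    if n_trials > 1 and n_switch > 0:
        switch_at = rng.choice(np.arange(1, n_trials), size=n_switch, replace=False)
        transitions[switch_at] = True
    task_idx = np.cumsum(transitions) % 2
    if rng.random() < 0.5:
        task_idx = 1 - task_idx
    tasks = [TASKS[i] for i in task_idx]

    cues = [CUES[i] for i in rng.integers(0, 2, size=n_trials)]

    jitter = rng.uniform(-jitter_s, jitter_s, size=n_trials)
    onsets = start_s + np.arange(n_trials) * iti_s + jitter
    onsets = np.round(onsets, 3)

    n_scans = math.ceil((onsets[-1] + tail_s) / tr_s)

    trials = []
    for t in range(n_trials):
        condition = REPEAT if t == 0 else (
            SWITCH if tasks[t] != tasks[t - 1] else REPEAT
        )
        trials.append(Trial(float(onsets[t]), tasks[t], cues[t], condition))
    return TrialDesign(trials=trials, tr_s=tr_s, n_scans=n_scans)
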