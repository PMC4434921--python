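"""Behavioral summaries of dynamic-reward-task trial logs.

PCRD (probability of choosing the rich deck) curves, the acquisition /
steady learning-state split (within-block trials 1-20 vs the remainder),
game scores (sum of 0/1 rewards, paid 1:1), and consecutive-non-reward
run statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StateSummary",
    "RunStats",
    "pcrd",
    "pcrd_by_position",
    "state_summary",
    "game_score",
    "nonreward_runs",
]

ACQUISITION_TRIALS = 20  # within-block trials 1-20


def _chose_rich(trials: pd.DataFrame, schedule) -> pd.DataFrame:
    sched = schedule.trials.set_index("trial")
    merged = trials.sort_values("trial").copy()
    for col in ("rich_deck", "block", "trial_in_block"):
        merged[col] = sched[col].loc[merged["trial"]].to_numpy()
    merged["chose_rich"] = (merged["choice"] == merged["rich_deck"]).astype(float)
    return merged


def pcrd(trials: pd.DataFrame, schedule, window: int = 10) -> pd.DataFrame:
    """Trailing moving-average rich-choice curve.

    The rich-choice indicator is smoothed by a causal moving average of
    ``window`` trials within each (condition, block) cell, never blending
    across block transitions.  Returns one row per trial with the smoothed
    ``pcrd`` value plus condition/block/trial_in_block bookkeeping.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    merged = _chose_rich(trials, schedule)
    merged["pcrd"] = (
        merged.groupby(["condition", "block"], observed=True)["chose_rich"]
        .transform(lambda s: s.rolling(window, min_periods=1).mean()))
    return merged[["trial", "condition", "block", "trial_in_block", "chose_rich", "pcrd"]]


def pcrd_by_position(trials: pd.DataFrame, schedule, window: int = 10) -> pd.DataFrame:
    """Mean smoothed PCRD per within-block trial position (the learning
    curve averaged over blocks and conditions)."""
    curve = pcrd(trials, schedule, window)
    return curve.groupby("trial_in_block", observed=True)["pcrd"].mean().reset_index()


@dataclass
class StateSummary:
    """Unsmoothed mean rich-choice rate per learning state."""

    acquisition: float
    steady: float
    n_acquisition: int
    n_steady: int

    @property
    def steady_empty(self) -> bool:
        return self.n_steady == 0

    @property
    def overall(self) -> float:
        n = self.n_acquisition + self.n_steady
        return ((self.acquisition * self.n_acquisition
                 + (self.steady if self.n_steady else 0.0) * self.n_steady) / n)


def state_summary(trials: pd.DataFrame, schedule,
                  acquisition_trials: int = ACQUISITION_TRIALS) -> StateSummary:
    """Mean rich-choice rate in the acquisition (within-block trials 1-20)
    and steady (trial 21 to block end) states.  Blocks shorter than the
    acquisition span truncate it (with a warning); an empty steady state is
    flagged, not fabricated."""
    merged = _chose_rich(trials, schedule)
    acq = merged["trial_in_block"] < acquisition_trials
    block_lengths = [b.length for b in schedule.blocks]
    if min(block_lengths) < acquisition_trials:
        warnings.warn("some blocks are shorter than the acquisition span; truncated")
    n_acq, n_steady = int(acq.sum()), int((~acq).sum())
    if n_steady == 0:
        warnings.warn("no steady-state trials (all blocks within the acquisition span)")
    return StateSummary(
        acquisition=float(merged.loc[acq, "chose_rich"].mean()) if n_acq else float("nan"),
        steady=float(merged.loc[~acq, "chose_rich"].mean()) if n_steady else float("nan"),
        n_acquisition=n_acq, n_steady=n_steady)


def game_score(trials: pd.DataFrame) -> int:
    """Total points: the sum of 0/1 rewards (paid out 1:1)."""
    rewards = trials["reward"].to_numpy()
    if not np.isin(rewards, (0, 1)).all():
        raise ValueError("rewards must be 0/1")
    return int(rewards.sum())


@dataclass
class RunStats:
    """Lengths of consecutive-non-reward runs and their mean (0 if none)."""

    lengths: list[int]

    @property
    def n(self) -> int:
        return len(self.lengths)

    @property
    def mean(self) -> float:
        return float(np.mean(self.lengths)) if self.lengths else 0.0


def nonreward_runs(trials: pd.DataFrame, require_shift: bool = True) -> RunStats:
    """Consecutive non-reward trials on a stuck choice, per deck pair.

    A run is a maximal streak of reward = 0 trials on the same chosen deck.
    With ``require_shift`` (default) only streaks terminated by switching
    to the other deck of the pair are counted ("non-reward trials prior to
    shifting"); without it every maximal streak is counted, including ones
    ended by a reward or by the end of the log.
    """
    lengths: list[int] = []
    for _, sub in trials.sort_values("trial").groupby("pair", observed=True):
        streak = 0
        prev_choice = None
        for choice, reward in zip(sub["choice"], sub["reward"]):
            if prev_choice is not None and choice != prev_choice:
                if streak > 0:
                    lengths.append(streak)   # run ended by a shift
                streak = 0
            if reward == 0:
                streak += 1
            else:
                if streak > 0 and not require_shift:
                    lengths.append(streak)   # streak broken by a reward
                streak = 0
            prev_choice = choice
        if streak > 0 and not require_shift:
            lengths.append(streak)           # streak open at end of log
    return RunStats(lengths=lengths)
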