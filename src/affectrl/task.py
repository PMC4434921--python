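"""Dynamic reward task: probabilistic schedules and reward realizations.

The task presents two deck pairs ("Up" = decks A/B, "Down" = decks C/D),
one pair per prime condition, randomly interleaved trial by trial.  Each
condition runs through a sequence of blocks; within a block one deck of
the pair is "rich" (higher reward probability) and the other "poor", with
the two probabilities in a fixed ratio (e.g. 6:1) summing to a fixed total
(default 60%).  Block transitions are un-signaled and always swap which
deck of the pair is rich.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "Block",
    "TaskSchedule",
    "RewardRealization",
    "ScheduleConstraintError",
    "InvalidScheduleError",
    "generate_schedule",
    "realize_rewards",
    "label_rich_deck",
    "pair_probabilities",
]

#: deck labels belonging to each on-screen pair
PAIR_DECKS: dict[str, tuple[str, str]] = {"Up": ("A", "B"), "Down": ("C", "D")}

#: the two prime conditions present on every trial sequence
CONDITIONS: tuple[str, str] = ("affective", "neutral")


class ScheduleConstraintError(ValueError):
    """Raised when a task configuration cannot produce a valid schedule."""


class InvalidScheduleError(ValueError):
    """Raised when a schedule violates a structural invariant (e.g. a
    probability tie that leaves the rich deck undefined)."""


def pair_probabilities(ratio: tuple[int, int], total: Fraction) -> tuple[Fraction, Fraction]:
    """Exact per-deck reward probabilities for a ``rich:poor`` ratio.

    For ratio ``a:b`` and total probability ``p`` the two decks receive
    ``p*a/(a+b)`` and ``p*b/(a+b)``; e.g. 6:1 at 60% gives 36/70 and 6/70.
    """
    a, b = ratio
    total = Fraction(total)
    return total * Fraction(a, a + b), total * Fraction(b, a + b)


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the dynamic reward task.

    Defaults reproduce the experimental phase: six 70-90 trial blocks per
    prime condition (480 trials/condition, 960 total), reward ratios drawn
    from {6:1, 3:1, 1:3, 1:6} with the pair total fixed at 60%.
    """

    n_blocks_per_condition: int = 6
    trials_per_condition: int = 480
    block_length_range: tuple[int, int] = (70, 90)
    ratio_set: tuple[tuple[int, int], ...] = ((6, 1), (3, 1), (1, 3), (1, 6))
    total_reward_prob: Fraction = Fraction(3, 5)
    training_ratio_set: tuple[tuple[int, int], ...] = ((6, 1), (1, 6))
    training_min_trials: int = 40

    def __post_init__(self) -> None:
        lo, hi = self.block_length_range
        n, t = self.n_blocks_per_condition, self.trials_per_condition
        if not (0 < lo <= hi):
            raise ScheduleConstraintError(f"block_length_range must satisfy 0 < lo <= hi, got {lo, hi}")
        if n * lo > t:
            raise ScheduleConstraintError(
                f"minimum total {n}x{lo}={n * lo} exceeds trials_per_condition={t}")
        if n * hi < t:
            raise ScheduleConstraintError(
                f"maximum total {n}x{hi}={n * hi} is below trials_per_condition={t}")
        if not self.ratio_set:
            raise ScheduleConstraintError("ratio_set must be nonempty")
        if any(a == b for a, b in self.ratio_set):
            raise ScheduleConstraintError("ratios must define a strict rich deck (a != b)")
        p = Fraction(self.total_reward_prob)
        if not (0 < p <= 1):
            raise ScheduleConstraintError(f"total_reward_prob must lie in (0, 1], got {p}")
        # alternating rich sides requires ratios on both sides of the pair
        sides = {a > b for a, b in self.ratio_set}
        if self.n_blocks_per_condition > 1 and len(sides) < 2:
            raise ScheduleConstraintError(
                "ratio_set needs ratios with both rich sides so the rich deck can swap at transitions")


@dataclass(frozen=True)
class Block:
    """One constant-probability stretch of trials for a single condition."""

    condition: str
    index: int
    length: int
    ratio: tuple[int, int]          # (first deck : second deck) multipliers
    p_decks: tuple[Fraction, Fraction]  # exact probabilities for (deck1, deck2)

    @property
    def rich_index(self) -> int:
        return 0 if self.p_decks[0] > self.p_decks[1] else 1


@dataclass
class TaskSchedule:
    """Realized block structure plus its per-trial expansion.

    ``trials`` has one row per trial with columns: ``trial``, ``condition``,
    ``pair``, ``deck1``, ``deck2``, ``p1``, ``p2``, ``rich_deck``, ``block``,
    ``trial_in_block``, ``trial_in_condition``.
    """

    config: TaskConfig
    seed: int
    pair_assignment: dict[str, str]
    blocks: list[Block]
    trials: pd.DataFrame

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def rich_deck(self, trial: int) -> str:
        """Deck label with the strictly higher scheduled probability."""
        row = self.trials.iloc[trial]
        if row.p1 == row.p2:
            raise InvalidScheduleError(f"trial {trial}: tied probabilities {row.p1}")
        return row.deck1 if row.p1 > row.p2 else row.deck2

    def to_tsv(self, path: str | Path, realization: "RewardRealization | None" = None) -> None:
        """One row per trial; optional drawn outcomes; JSON sidecar with config."""
        path = Path(path)
        df = self.trials.copy()
        if realization is not None:
            df["outcome1"] = realization.outcomes[:, 0]
            df["outcome2"] = realization.outcomes[:, 1]
        df.to_csv(path, sep="\t", index=False)
        sidecar = {
            "seed": self.seed,
            "pair_assignment": self.pair_assignment,
            "config": {k: str(v) if isinstance(v, Fraction) else v
                       for k, v in asdict(self.config).items()},
        }
        if realization is not None:
            sidecar["reward_seed"] = realization.seed
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


@dataclass
class RewardRealization:
    """Pre-drawn Bernoulli outcomes, one per deck of the active pair per trial.

    ``outcomes[t, k]`` is the 0/1 reward that trial ``t`` pays if the agent
    picks deck ``k`` (deck1/deck2 of that trial's pair).  Draws are
    independent across trials and decks; nothing is baited or carried over.
    """

    outcomes: np.ndarray  # (n_trials, 2) int8
    seed: int


def _sample_block_lengths(rng: np.random.Generator, n: int, total: int,
                          lo: int, hi: int, max_tries: int = 10_000) -> np.ndarray:
    """Uniform composition of `total` into `n` parts within [lo, hi].

    Rejection sampling; falls back to a randomized constructive fill when
    the feasible set is too thin to hit by rejection.
    """
    for _ in range(max_tries):
        lengths = rng.integers(lo, hi + 1, size=n)
        if lengths.sum() == total:
            return lengths
    lengths = np.full(n, lo, dtype=np.int64)
    deficit = total - n * lo
    while deficit > 0:
        room = np.flatnonzero(lengths < hi)
        i = rng.choice(room)
        lengths[i] += 1
        deficit -= 1
    return lengths


def _sample_ratio_sequence(rng: np.random.Generator, config: TaskConfig) -> list[tuple[int, int]]:
    """Ratio per block, uniform given that the rich side swaps every transition."""
    ratios = list(config.ratio_set)
    seq = [ratios[rng.integers(len(ratios))]]
    for _ in range(config.n_blocks_per_condition - 1):
        prev_rich_first = seq[-1][0] > seq[-1][1]
        candidates = [r for r in ratios if (r[0] > r[1]) != prev_rich_first]
        seq.append(candidates[rng.integers(len(candidates))])
    return seq


def generate_schedule(config: TaskConfig, seed: int,
                      pair_assignment: dict[str, str] | None = None) -> TaskSchedule:
    """Draw a full task schedule: blocks per condition plus the random
    trial-by-trial interleaving of the two conditions.

    Parameters
    ----------
    config
        Task parameters; validated on construction.
    seed
        Seed for all schedule randomness; same seed => identical schedule.
    pair_assignment
        Mapping from condition to deck pair ("Up"/"Down").  Defaults to
        affective->Up, neutral->Down; flip it to counterbalance across
        simulated subjects.
    """
    if pair_assignment is None:
        pair_assignment = {"affective": "Up", "neutral": "Down"}
    if set(pair_assignment) != set(CONDITIONS) or set(pair_assignment.values()) != set(PAIR_DECKS):
        raise ScheduleConstraintError(f"pair_assignment must map {CONDITIONS} onto Up/Down")

    rng = np.random.default_rng(seed)
    total = Fraction(config.total_reward_prob)

    blocks: list[Block] = []
    per_cond_rows: dict[str, dict[str, list]] = {}
    for cond in CONDITIONS:
        lengths = _sample_block_lengths(
            rng, config.n_blocks_per_condition, config.trials_per_condition,
            *config.block_length_range)
        ratios = _sample_ratio_sequence(rng, config)
        cols: dict[str, list] = {k: [] for k in ("p1", "p2", "block", "trial_in_block")}
        for b, (length, ratio) in enumerate(zip(lengths, ratios)):
            p1, p2 = pair_probabilities(ratio, total)
            blocks.append(Block(cond, b, int(length), ratio, (p1, p2)))
            cols["p1"].extend([p1] * length)
            cols["p2"].extend([p2] * length)
            cols["block"].extend([b] * length)
            cols["trial_in_block"].extend(range(length))
        per_cond_rows[cond] = cols

    # random interleaving: each condition occupies half of the trials
    cond_seq = np.repeat(np.arange(2), config.trials_per_condition)
    rng.shuffle(cond_seq)

    pos = {c: 0 for c in CONDITIONS}
    rows = []
    for t, ci in enumerate(cond_seq):
        cond = CONDITIONS[ci]
        pair = pair_assignment[cond]
        deck1, deck2 = PAIR_DECKS[pair]
        i = pos[cond]
        cols = per_cond_rows[cond]
        p1, p2 = cols["p1"][i], cols["p2"][i]
        rows.append((t, cond, pair, deck1, deck2, float(p1), float(p2),
                     deck1 if p1 > p2 else deck2,
                     cols["block"][i], cols["trial_in_block"][i], i))
        pos[cond] = i + 1

    trials = pd.DataFrame(rows, columns=[
        "trial", "condition", "pair", "deck1", "deck2", "p1", "p2",
        "rich_deck", "block", "trial_in_block", "trial_in_condition"])
    return TaskSchedule(config=config, seed=int(seed),
                        pair_assignment=dict(pair_assignment),
                        blocks=blocks, trials=trials)


def realize_rewards(schedule: TaskSchedule, seed: int) -> RewardRealization:
    """Draw one independent Bernoulli outcome per deck of the active pair
    per trial, under the scheduled probabilities."""
    rng = np.random.default_rng(seed)
    p = schedule.trials[["p1", "p2"]].to_numpy()
    outcomes = (rng.random(p.shape) < p).astype(np.int8)
    return RewardRealization(outcomes=outcomes, seed=int(seed))


def label_rich_deck(schedule: TaskSchedule, trial: int) -> str:
    """Deck label of the strictly richer deck on ``trial`` (errors on ties)."""
    return schedule.rich_deck(trial)
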