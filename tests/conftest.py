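import numpy as np
import pandas as pd
import pytest

from affectrl.rl import AgentParams, simulate_agent
from affectrl.task import TaskConfig, generate_schedule, realize_rewards


@pytest.fixture(scope="session")
def small_task_config() -> TaskConfig:
    """Two 40-80-trial blocks per condition, 120 trials/condition."""
    return TaskConfig(n_blocks_per_condition=2, trials_per_condition=120,
                      block_length_range=(40, 80))


@pytest.fixture(scope="session")
def small_schedule(small_task_config):
    return generate_schedule(small_task_config, seed=11)


@pytest.fixture(scope="session")
def small_rewards(small_schedule):
    return realize_rewards(small_schedule, seed=12)


@pytest.fixture(scope="session")
def learner_log(small_schedule, small_rewards) -> pd.DataFrame:
    """One simulated learner (alpha=0.3, beta=4) on the small task."""
    return simulate_agent(AgentParams(0.3, 4.0), small_schedule, small_rewards, seed=13)


def replay_likelihood(params: AgentParams, trials: pd.DataFrame) -> float:
    """Independent brute-force likelihood: per-trial softmax product via a
    plain dict-of-values replay (no shared code with the kernel path)."""
    q = {}
    total = 0.0
    for row in trials.sort_values("trial").itertuples(index=False):
        if row.pair not in q:
            q[row.pair] = {d: 0.5 for d in _pair_decks(row.pair)}
        decks = _pair_decks(row.pair)
        num = np.exp(params.beta * q[row.pair][row.choice])
        den = sum(np.exp(params.beta * q[row.pair][d]) for d in decks)
        total += np.log(num / den)
        q[row.pair][row.choice] += params.alpha * (row.reward - q[row.pair][row.choice])
    return total


def _pair_decks(pair: str):
    return ("A", "B") if pair == "Up" else ("C", "D")
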