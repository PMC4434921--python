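"""Q-learning / softmax choice model.

Value updating follows the delta rule Q <- Q + alpha * (R - Q) where the
reward prediction error (RPE) delta = R - Q is the discrepancy between the
obtained (0/1) and expected reward of the chosen deck.  Choices follow
Boltzmann exploration: P(A) = exp(beta*Q_A) / (exp(beta*Q_A) + exp(beta*Q_B)).
alpha in [0,1] is the learning rate; beta >= 0 the choice perseveration
(inverse-temperature-like) parameter -- beta = 0 is fully random choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .task import PAIR_DECKS, RewardRealization, TaskSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "AgentParams",
    "q_update",
    "choice_prob",
    "simulate_agent",
    "log_likelihood",
    "trials_to_arrays",
]

try:  # numba accelerates the likelihood replay used heavily by the MCMC fitter
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class AgentParams:
    """Subject-level model parameters.

    alpha : learning rate in [0, 1].
    beta : choice perseveration, >= 0; 0 means choices ignore value.
    q_init : initial expected value of every deck (rewards are 0/1, so the
        midpoint 0.5 is the default).
    """

    alpha: float
    beta: float
    q_init: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not (0.0 <= self.q_init <= 1.0):
            raise ValueError(f"q_init must lie in [0, 1], got {self.q_init}")


def q_update(q_values: np.ndarray, chosen: int, reward: int | float,
             alpha: float) -> tuple[np.ndarray, float]:
    """Delta-rule update of the chosen deck's value.

    Returns the updated value array (a copy; unchosen decks untouched) and
    the RPE delta = reward - Q_chosen.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward}")
    q = np.asarray(q_values, dtype=float).copy()
    delta = float(reward) - q[chosen]
    q[chosen] += alpha * delta
    return q, float(delta)


def choice_prob(q_values: np.ndarray, beta: float) -> float:
    """Boltzmann probability of choosing the first deck of the pair.

    Computed through the logistic of beta*(Q_1 - Q_2), which is stable for
    arbitrarily large beta*Q.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    q = np.asarray(q_values, dtype=float)
    return float(expit(beta * (q[0] - q[1])))


def simulate_agent(params: AgentParams, schedule: TaskSchedule,
                   rewards: RewardRealization, seed: int,
                   subject: int = 0) -> pd.DataFrame:
    """Forward-simulate one agent through a realized schedule.

    Each trial: sample a choice from the softmax over the active pair's
    current values, read that deck's pre-drawn outcome, apply the delta-rule
    update.  Values are kept separately per deck pair and carried across
    block transitions without reset (transitions are un-signaled).

    Returns the canonical trial-log frame with columns: subject, trial,
    condition, pair, choice, reward, q_a, q_b, p_choice, delta (q_a/q_b are
    the pre-choice values of deck1/deck2; p_choice the probability of the
    deck actually chosen).
    """
    n = schedule.n_trials
    if len(rewards.outcomes) != n:
        raise ValueError(
            f"schedule has {n} trials but realization has {len(rewards.outcomes)}")
    rng = np.random.default_rng(seed)
    q_state = {pair: np.full(2, params.q_init, dtype=float) for pair in PAIR_DECKS}
    records = []
    for row in schedule.trials.itertuples(index=False):
        q = q_state[row.pair]
        p1 = choice_prob(q, params.beta)
        idx = 0 if rng.random() < p1 else 1
        reward = int(rewards.outcomes[row.trial, idx])
        delta = reward - q[idx]
        records.append((subject, row.trial, row.condition, row.pair,
                        (row.deck1, row.deck2)[idx], reward, q[0], q[1],
                        p1 if idx == 0 else 1.0 - p1, delta))
        q[idx] += params.alpha * delta
    return pd.DataFrame(records, columns=[
        "subject", "trial", "condition", "pair", "choice", "reward",
        "q_a", "q_b", "p_choice", "delta"])


def trials_to_arrays(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compress a trial log into (pair_idx, choice_idx, reward) int arrays
    ordered by trial, as consumed by the likelihood kernels."""
    trials = trials.sort_values("trial")
    pair_names = sorted(PAIR_DECKS)  # ["Down", "Up"] - fixed ordering
    pair_idx = trials["pair"].map({p: i for i, p in enumerate(pair_names)}).to_numpy(np.int64)
    first_deck = trials["pair"].map({p: PAIR_DECKS[p][0] for p in pair_names})
    choice_idx = (trials["choice"].to_numpy() != first_deck.to_numpy()).astype(np.int64)
    reward = trials["reward"].to_numpy(np.float64)
    if not np.isin(reward, (0.0, 1.0)).all():
        raise ValueError("rewards must be 0/1")
    return pair_idx, choice_idx, reward


@njit(cache=True)
def _loglik_single(pair_idx, choice_idx, reward, alpha, beta, q_init):
    q = np.full((2, 2), q_init)
    ll = 0.0
    for t in range(pair_idx.shape[0]):
        p = pair_idx[t]
        c = choice_idx[t]
        # log softmax of the chosen deck, stabilized by the max
        a = beta * q[p, 0]
        b = beta * q[p, 1]
        m = a if a > b else b
        ll += (a if c == 0 else b) - (m + np.log(np.exp(a - m) + np.exp(b - m)))
        q[p, c] += alpha * (reward[t] - q[p, c])
    return ll


@njit(cache=True)
def _loglik_batch(offsets, pair_idx, choice_idx, reward, alphas, betas, q_init):
    """Per-subject log-likelihoods for concatenated trial arrays."""
    n = alphas.shape[0]
    out = np.empty(n)
    for i in range(n):
        s, e = offsets[i], offsets[i + 1]
        out[i] = _loglik_single(pair_idx[s:e], choice_idx[s:e], reward[s:e],
                                alphas[i], betas[i], q_init)
    return out


def log_likelihood(params: AgentParams, trials: pd.DataFrame) -> float:
    """Log-probability of the observed choices under (alpha, beta).

    The value trajectory is replayed from q_init using the observed choices
    and rewards; stored q columns in the log are ignored.  An empty log is
    defined as 0 (with a warning).
    """
    if len(trials) == 0:
        logger.warning("log_likelihood called with an empty trial list; returning 0.0")
        return 0.0
    pair_idx, choice_idx, reward = trials_to_arrays(trials)
    return float(_loglik_single(pair_idx, choice_idx, reward,
                                params.alpha, params.beta, params.q_init))
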