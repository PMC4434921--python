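"""Synthetic studies: choice logs from known group-level parameters and
feedback- or prime-locked EEG with embedded ERP components.

Cohorts draw subject-level (alpha, beta) from truncated group-level
normals and simulate each subject through an independent schedule
realization.  EEG epochs are additive: channel noise (white or 1/f) plus
an outcome-dependent Gaussian-shaped fronto-central negativity whose
noise-free difference-wave peak equals a target amplitude, so every
pipeline stage can be scored against known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .erp import EpochSet, classify_outcomes
from .rl import AgentParams, simulate_agent
from .task import TaskConfig, generate_schedule, realize_rewards

__all__ = [
    "GroupSpec",
    "EegNoiseSpec",
    "desk_task_config",
    "synth_cohort",
    "synth_epochs",
    "synth_feedback_epochs",
    "synth_feedback_recording",
    "gaussian_bump",
]

#: relative FRN topography: targets refer to gain-1.0 channels
FRN_CHANNEL_GAINS = {"Fz": 0.9, "FCz": 1.0, "Cz": 1.0, "Pz": 0.4, "P7": 0.1, "P8": 0.1}
N170_CHANNEL_GAINS = {"P7": 0.9, "P8": 1.0}   # right-lateralized
EEP_CHANNEL_GAINS = {"Fz": 1.0, "Cz": 1.0, "Pz": 0.6}


@dataclass(frozen=True)
class GroupSpec:
    """Generating truth for one subject group.

    ERP amplitude defaults are the reference group-mean General FRN values
    (NN -6.50, AN -7.33, HN -7.23 uV); per-class (expected/unexpected)
    amplitudes fall back to the general value when not given.
    """

    label: str = "NN"
    mu_alpha: float = 0.3
    sigma_alpha: float = 0.1
    mu_beta: float = 3.0
    sigma_beta: float = 1.0
    n_subjects: int = 12
    frn_general: float = -6.50
    frn_expected: float | None = None
    frn_unexpected: float | None = None
    n170: float = -6.0
    eep: float = 4.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for a in (self.frn_general, self.n170, self.eep):
            if not np.isfinite(a):
                raise ValueError("component amplitudes must be finite")

    @property
    def expected_amplitude(self) -> float:
        return self.frn_general if self.frn_expected is None else self.frn_expected

    @property
    def unexpected_amplitude(self) -> float:
        return self.frn_general if self.frn_unexpected is None else self.frn_unexpected


@dataclass(frozen=True)
class EegNoiseSpec:
    """Additive channel-noise model for synthetic EEG."""

    model: str = "white"            # "white" or "one-over-f"
    sd: float = 5.0                 # uV
    channels: tuple[str, ...] = ("Fz", "FCz", "Cz", "Pz", "P7", "P8")
    sfreq: float = 1000.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("noise SD must be positive")
        if not self.channels:
            raise ValueError("montage must be nonempty")
        if self.model not in ("white", "one-over-f"):
            raise ValueError(f"unknown noise model {self.model!r}")


#: the three prime groups at their reported group-mean General FRN amplitudes
REFERENCE_GROUPS = (
    GroupSpec(label="NN", frn_general=-6.50),
    GroupSpec(label="AN", frn_general=-7.33),
    GroupSpec(label="HN", frn_general=-7.23),
)


def desk_task_config() -> TaskConfig:
    """Reduced task for fast simulation studies: 2 blocks of 40-80 trials
    per condition, 120 trials/condition (240 total), same ratios/total."""
    return TaskConfig(n_blocks_per_condition=2, trials_per_condition=120,
                      block_length_range=(40, 80))


def _truncnorm_rvs(rng, mu, sigma, lo, hi, size):
    if sigma <= 0:
        warnings.warn("degenerate sigma <= 0; using a point mass at mu")
        return np.full(size, float(np.clip(mu, lo, min(hi, np.inf))))
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size, random_state=rng)


def synth_cohort(spec: GroupSpec, task: TaskConfig | None = None,
                 seed: int = 0) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Simulate one group: per-subject trial logs plus the ground-truth
    parameter table.

    alpha_i ~ TruncNormal(mu_alpha, sigma_alpha, [0, 1]); beta_i ~
    TruncNormal(mu_beta, sigma_beta, [0, inf)).  Each subject gets an
    independent schedule and reward realization; deck-pair assignment to
    the prime conditions is counterbalanced across subjects.
    """
    task = task or TaskConfig()
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    alphas = _truncnorm_rvs(param_rng, spec.mu_alpha, spec.sigma_alpha, 0.0, 1.0,
                            spec.n_subjects)
    betas = _truncnorm_rvs(param_rng, spec.mu_beta, spec.sigma_beta, 0.0, np.inf,
                           spec.n_subjects)
    logs = []
    subj_seeds = ss.spawn(spec.n_subjects)
    for i in range(spec.n_subjects):
        s = subj_seeds[i].generate_state(3) % (2 ** 31)
        assignment = ({"affective": "Up", "neutral": "Down"} if i % 2 == 0
                      else {"affective": "Down", "neutral": "Up"})
        schedule = generate_schedule(task, int(s[0]), pair_assignment=assignment)
        rewards = realize_rewards(schedule, int(s[1]))
        params = AgentParams(alpha=float(alphas[i]), beta=float(betas[i]))
        log = simulate_agent(params, schedule, rewards, int(s[2]), subject=i)
        log.attrs["schedule"] = schedule
        logs.append(log)
    truth = pd.DataFrame({"subject": np.arange(spec.n_subjects),
                          "alpha": alphas, "beta": betas,
                          "group": spec.label})
    return logs, truth


def gaussian_bump(times_ms: np.ndarray, center_ms: float = 280.0,
                  width_ms: float = 40.0) -> np.ndarray:
    """Unit-peak Gaussian component shape over an epoch time axis."""
    return np.exp(-0.5 * ((times_ms - center_ms) / width_ms) ** 2)


def _noise(rng, noise: EegNoiseSpec, shape):
    if noise.model == "white":
        return rng.normal(0.0, noise.sd, shape)
    # 1/f: shape a white spectrum, rescale to the requested SD
    white = rng.normal(0.0, 1.0, shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], 1.0 / noise.sfreq)
    weight = 1.0 / np.sqrt(np.maximum(freqs, freqs[1] if len(freqs) > 1 else 1.0))
    pink = np.fft.irfft(spec * weight, n=shape[-1], axis=-1)
    return pink * (noise.sd / pink.std())


def synth_feedback_epochs(n_reward: int, n_nonreward: int, amplitude: float,
                          noise: EegNoiseSpec = EegNoiseSpec(), seed: int = 0,
                          window_ms: tuple[float, float] = (-100.0, 700.0),
                          center_ms: float = 280.0, width_ms: float = 40.0,
                          expectation: str = "expected",
                          channel_gains: dict[str, float] | None = None) -> EpochSet:
    """Feedback-locked epochs with a controlled difference-wave negativity.

    Non-reward epochs receive ``amplitude`` x channel gain x Gaussian bump
    (center 280 ms, SD 40 ms by default), so the noise-free difference
    wave's windowed peak at a gain-1.0 channel equals ``amplitude``.
    ``expectation`` labels both sides as expectation-consistent
    ("expected") or expectation-violating ("unexpected") outcome classes.
    """
    if expectation not in ("expected", "unexpected"):
        raise ValueError("expectation must be 'expected' or 'unexpected'")
    gains = channel_gains or FRN_CHANNEL_GAINS
    missing = [c for c in noise.channels if c not in gains]
    if missing:
        raise ValueError(f"no FRN gain defined for channel(s) {missing}")
    rng = np.random.default_rng(seed)
    n_samp = int(round((window_ms[1] - window_ms[0]) * noise.sfreq / 1000.0)) + 1
    times = window_ms[0] + np.arange(n_samp) * 1000.0 / noise.sfreq
    n_total = n_reward + n_nonreward
    data = _noise(rng, noise, (n_total, len(noise.channels), n_samp))
    bump = gaussian_bump(times, center_ms, width_ms)
    gain_vec = np.array([gains[c] for c in noise.channels])
    data[n_reward:] += amplitude * gain_vec[:, None] * bump[None, :]
    labels = pd.DataFrame({
        "outcome": ["reward"] * n_reward + ["nonreward"] * n_nonreward,
        "outcome_class": ([f"{expectation}-delivery"] * n_reward
                          + [f"{expectation}-omission"] * n_nonreward),
    })
    return EpochSet(data=data, channels=list(noise.channels), sfreq=noise.sfreq,
                    tmin_ms=window_ms[0], labels=labels)


def synth_feedback_recording(n_reward: int, n_nonreward: int, amplitude: float,
                             noise: EegNoiseSpec = EegNoiseSpec(), seed: int = 0,
                             isi_ms: float = 1000.0,
                             center_ms: float = 280.0, width_ms: float = 40.0,
                             expectation: str = "expected",
                             channel_gains: dict[str, float] | None = None
                             ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Continuous synthetic recording with feedback events, for the
    filter-then-epoch path (a 0.1 Hz highpass is only meaningful on
    continuous data, so round trips use this form).

    Returns ``(continuous, events, labels)``: a (n_channels, n_samples)
    signal in uV, event times in samples, and per-event labels.  Reward /
    non-reward events are randomly interleaved; each non-reward event adds
    ``amplitude`` x channel gain x Gaussian bump, so the noise-free
    difference wave's windowed peak at a gain-1.0 channel equals
    ``amplitude``.
    """
    if expectation not in ("expected", "unexpected"):
        raise ValueError("expectation must be 'expected' or 'unexpected'")
    gains = channel_gains or FRN_CHANNEL_GAINS
    missing = [c for c in noise.channels if c not in gains]
    if missing:
        raise ValueError(f"no FRN gain defined for channel(s) {missing}")
    rng = np.random.default_rng(seed)
    n_total = n_reward + n_nonreward
    isi = int(round(isi_ms * noise.sfreq / 1000.0))
    n_samp = (n_total + 1) * isi
    events = isi + np.arange(n_total) * isi
    outcome = np.array(["reward"] * n_reward + ["nonreward"] * n_nonreward)
    rng.shuffle(outcome)
    data = _noise(rng, noise, (len(noise.channels), n_samp))
    # component support: +-5 SD around the bump center
    half = int(round(5 * width_ms * noise.sfreq / 1000.0))
    c_samp = int(round(center_ms * noise.sfreq / 1000.0))
    offs = np.arange(c_samp - half, c_samp + half + 1)
    bump = gaussian_bump(offs * 1000.0 / noise.sfreq, center_ms, width_ms)
    gain_vec = np.array([gains[c] for c in noise.channels])
    for e in events[outcome == "nonreward"]:
        data[:, e + offs[0]:e + offs[-1] + 1] += amplitude * gain_vec[:, None] * bump[None, :]
    labels = pd.DataFrame({
        "outcome": outcome,
        "outcome_class": np.where(outcome == "reward",
                                  f"{expectation}-delivery", f"{expectation}-omission"),
    })
    return data, events, labels


def synth_epochs(trials: pd.DataFrame, spec: GroupSpec,
                 noise: EegNoiseSpec = EegNoiseSpec(), seed: int = 0,
                 schedule=None, lock: str = "feedback",
                 center_ms: float = 280.0, width_ms: float = 40.0) -> EpochSet:
    """One epoch per trial of a classified trial log.

    ``lock="feedback"`` (window -100..700 ms): non-reward epochs carry the
    group's FRN negativity, with per-class amplitude (expected-omission ->
    expected target, unexpected-omission -> unexpected target) scaled by
    the fronto-central channel topography.  ``lock="prime"`` (window
    -100..500 ms): every epoch carries the N170 (negative, 150 ms, P7/P8,
    right-lateralized) and the EEP (positive, 150 ms, Fz/Cz/Pz).
    """
    if schedule is None:
        schedule = trials.attrs.get("schedule")
    if "outcome_class" in trials.columns:
        classes = trials["outcome_class"]
    else:
        if schedule is None:
            raise ValueError("need a schedule (or precomputed outcome_class) to classify trials")
        classes = classify_outcomes(trials, schedule)

    if lock == "feedback":
        window_ms = (-100.0, 700.0)
        required = [c for c in noise.channels if c not in FRN_CHANNEL_GAINS]
    elif lock == "prime":
        window_ms = (-100.0, 500.0)
        required = []
        for need in ("P7", "P8", "Fz", "Cz", "Pz"):
            if need not in noise.channels:
                required.append(need)
    else:
        raise ValueError("lock must be 'feedback' or 'prime'")
    if required:
        raise ValueError(f"montage incompatible with lock={lock!r}: {required}")

    rng = np.random.default_rng(seed)
    n_samp = int(round((window_ms[1] - window_ms[0]) * noise.sfreq / 1000.0)) + 1
    times = window_ms[0] + np.arange(n_samp) * 1000.0 / noise.sfreq
    n = len(trials)
    data = _noise(rng, noise, (n, len(noise.channels), n_samp))

    state = np.where(trials["trial"].map(
        schedule.trials.set_index("trial")["trial_in_block"]) < 20,
        "acquisition", "steady") if schedule is not None else np.full(n, "unknown")

    if lock == "feedback":
        bump = gaussian_bump(times, center_ms, width_ms)
        gain = np.array([FRN_CHANNEL_GAINS[c] for c in noise.channels])
        amp = np.zeros(n)
        amp[classes.to_numpy() == "expected-omission"] = spec.expected_amplitude
        amp[classes.to_numpy() == "unexpected-omission"] = spec.unexpected_amplitude
        data += amp[:, None, None] * gain[None, :, None] * bump[None, None, :]
    else:
        bump = gaussian_bump(times, 150.0, 25.0)
        for ch_gains, amp in ((N170_CHANNEL_GAINS, spec.n170),
                              (EEP_CHANNEL_GAINS, spec.eep)):
            gain = np.array([ch_gains.get(c, 0.0) for c in noise.channels])
            data += amp * gain[None, :, None] * bump[None, None, :]

    labels = pd.DataFrame({
        "trial": trials["trial"].to_numpy(),
        "condition": trials["condition"].to_numpy(),
        "outcome": np.where(trials["reward"].to_numpy() == 1, "reward", "nonreward"),
        "outcome_class": classes.to_numpy(),
        "state": state,
    })
    return EpochSet(data=data, channels=list(noise.channels), sfreq=noise.sfreq,
                    tmin_ms=window_ms[0], labels=labels)
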