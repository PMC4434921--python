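"""Hierarchical Bayesian estimation of Q-learning parameters by MCMC.

Model.  For subject i with choice data D_i:

    alpha_i ~ TruncNormal(mu_alpha, sigma_alpha, [0, 1])
    beta_i  ~ TruncNormal(mu_beta,  sigma_beta,  [0, inf))
    D_i     ~ Q-learning/softmax likelihood(alpha_i, beta_i)

with non-informative uniform hyperpriors mu_alpha, sigma_alpha ~ U(0, 1),
mu_beta ~ U(0, 10), sigma_beta ~ U(0, 5).  Group-level distributions are
truncated to the parameter supports so the density is well defined at the
bounds.

Sampler.  Random-walk Metropolis within Gibbs: one vectorized sweep over
all subjects' alphas, one over betas (subjects are conditionally
independent given the hypers, so elementwise accept/reject is exact), then
scalar updates of the four group-level parameters.  Proposal scales adapt
toward ~30% acceptance during burn-in and are frozen afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .rl import AgentParams, _loglik_batch, trials_to_arrays

__all__ = [
    "HyperPriors",
    "McmcSettings",
    "PosteriorSamples",
    "InitializationError",
    "log_posterior",
    "fit_hierarchical",
    "gelman_rubin",
    "wald_compare",
    "paper_settings",
    "truncnorm_logpdf",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

GROUP_PARAMS = ("mu_alpha", "sigma_alpha", "mu_beta", "sigma_beta")


class InitializationError(RuntimeError):
    """Raised when the sampler cannot find a finite starting density."""


@dataclass(frozen=True)
class HyperPriors:
    """Uniform hyperprior bounds for the four group-level parameters."""

    mu_alpha: tuple[float, float] = (0.0, 1.0)
    sigma_alpha: tuple[float, float] = (0.0, 1.0)
    mu_beta: tuple[float, float] = (0.0, 10.0)
    sigma_beta: tuple[float, float] = (0.0, 5.0)

    def __post_init__(self) -> None:
        for name in GROUP_PARAMS:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} prior bounds must be strictly ordered, got {lo, hi}")

    def bounds(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


@dataclass(frozen=True)
class McmcSettings:
    """Chain bookkeeping.  Defaults follow the reference analysis:
    3 chains x 16,000 iterations, 6,000 burn-in, thinning interval 5,
    hence 30,000 post-burn-in points thinned to 6,000 retained draws."""

    n_chains: int = 3
    n_iterations: int = 16_000
    n_burnin: int = 6_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("burn-in must be smaller than the iteration count")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def pre_thin_total(self) -> int:
        """Post-burn-in points across chains, before thinning."""
        return self.n_chains * (self.n_iterations - self.n_burnin)

    @property
    def retained_per_chain(self) -> int:
        return len(range(self.n_burnin, self.n_iterations, self.thin))

    @property
    def retained_total(self) -> int:
        return self.n_chains * self.retained_per_chain


def paper_settings(seed: int = 0) -> McmcSettings:
    """The reference MCMC settings (3 x 16,000, burn-in 6,000, thin 5)."""
    return McmcSettings(n_chains=3, n_iterations=16_000, n_burnin=6_000, thin=5, seed=seed)


def truncnorm_logpdf(x, mu, sigma, lo, hi):
    """Log-density of Normal(mu, sigma) truncated to [lo, hi].

    Vectorized over ``x``; returns -inf outside the support.  ``hi`` may be
    ``np.inf``.
    """
    x = np.asarray(x, dtype=float)
    if sigma <= 0:
        return np.full_like(x, -np.inf)
    z = (x - mu) / sigma
    with np.errstate(divide="ignore"):
        log_z = np.log(ndtr((hi - mu) / sigma) - ndtr((lo - mu) / sigma))
    out = -0.5 * z * z - _LOG_SQRT_2PI - math.log(sigma) - log_z
    return np.where((x < lo) | (x > hi), -np.inf, out)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws with chain structure preserved.

    Subject-level arrays have shape (n_chains, n_draws, n_subjects);
    group-level arrays (n_chains, n_draws).  Parameter names accepted by
    :meth:`get` are ``mu_alpha``/``sigma_alpha``/``mu_beta``/``sigma_beta``
    and ``alpha[i]``/``beta[i]``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    mu_alpha: np.ndarray
    sigma_alpha: np.ndarray
    mu_beta: np.ndarray
    sigma_beta: np.ndarray
    acceptance: dict[str, float]
    settings: McmcSettings
    seed: int

    @property
    def n_subjects(self) -> int:
        return self.alpha.shape[2]

    @property
    def n_retained(self) -> int:
        return self.mu_alpha.shape[0] * self.mu_alpha.shape[1]

    def get(self, parameter: str) -> np.ndarray:
        """(n_chains, n_draws) array of one scalar parameter's draws."""
        if parameter in GROUP_PARAMS:
            return getattr(self, parameter)
        if parameter.endswith("]") and "[" in parameter:
            base, idx = parameter[:-1].split("[")
            if base in ("alpha", "beta"):
                return getattr(self, base)[:, :, int(idx)]
        raise KeyError(f"unknown parameter {parameter!r}")

    def parameter_names(self) -> list[str]:
        names = list(GROUP_PARAMS)
        names += [f"alpha[{i}]" for i in range(self.n_subjects)]
        names += [f"beta[{i}]" for i in range(self.n_subjects)]
        return names

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.parameter_names():
            draws = self.get(name)
            rows.append((name, draws.mean(), draws.std(ddof=1),
                         gelman_rubin(self, name)))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "rhat"]
                            ).set_index("parameter")

    def to_tsv(self, path) -> None:
        """Long-format export: chain, draw, parameter, value."""
        frames = []
        for name in self.parameter_names():
            draws = self.get(name)
            n_chains, n_draws = draws.shape
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(n_chains), n_draws),
                "draw": np.tile(np.arange(n_draws), n_chains),
                "parameter": name,
                "value": draws.ravel(),
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def _as_arrays(data) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = []
    for d in data:
        out.append(d if isinstance(d, tuple) else trials_to_arrays(d))
    return out


def _concat(datasets):
    offsets = np.zeros(len(datasets) + 1, dtype=np.int64)
    for i, (p, _, _) in enumerate(datasets):
        offsets[i + 1] = offsets[i] + len(p)
    pair = np.concatenate([d[0] for d in datasets])
    choice = np.concatenate([d[1] for d in datasets])
    reward = np.concatenate([d[2] for d in datasets])
    return offsets, pair, choice, reward


def log_posterior(subject_params, hypers: dict, data,
                  priors: HyperPriors = HyperPriors(), q_init: float = 0.5) -> float:
    """Joint log-density of subject parameters, group parameters and data.

    ``subject_params`` is a list of :class:`AgentParams` (or (alpha, beta)
    pairs); ``hypers`` a mapping with keys mu_alpha, sigma_alpha, mu_beta,
    sigma_beta.  Returns -inf anywhere outside the prior support.
    """
    for name in GROUP_PARAMS:
        lo, hi = priors.bounds(name)
        v = hypers[name]
        if not (lo < v < hi) if name.startswith("sigma") else not (lo <= v <= hi):
            return -np.inf
    alphas = np.array([p.alpha if isinstance(p, AgentParams) else p[0] for p in subject_params])
    betas = np.array([p.beta if isinstance(p, AgentParams) else p[1] for p in subject_params])
    if np.any((alphas < 0) | (alphas > 1)) or np.any(betas < 0):
        return -np.inf

    datasets = _as_arrays(data)
    if len(datasets) != len(alphas):
        raise ValueError("one trial list per subject is required")
    offsets, pair, choice, reward = _concat(datasets)
    ll = _loglik_batch(offsets, pair, choice, reward, alphas, betas, q_init).sum()

    lp = truncnorm_logpdf(alphas, hypers["mu_alpha"], hypers["sigma_alpha"], 0.0, 1.0).sum()
    lp += truncnorm_logpdf(betas, hypers["mu_beta"], hypers["sigma_beta"], 0.0, np.inf).sum()
    for name in GROUP_PARAMS:  # uniform hyperprior log-densities
        lo, hi = priors.bounds(name)
        lp += -math.log(hi - lo)
    total = ll + lp
    return float(total) if np.isfinite(total) else -np.inf


def _grid_mle(datasets, q_init):
    """Coarse per-subject (alpha, beta) maximum-likelihood estimates."""
    alpha_grid = np.linspace(0.02, 0.98, 25)
    beta_grid = np.linspace(0.05, 9.0, 25)
    offsets, pair, choice, reward = _concat(datasets)
    n = len(datasets)
    best_ll = np.full(n, -np.inf)
    best = np.zeros((n, 2))
    for a in alpha_grid:
        for b in beta_grid:
            ll = _loglik_batch(offsets, pair, choice, reward,
                               np.full(n, a), np.full(n, b), q_init)
            better = ll > best_ll
            best_ll[better] = ll[better]
            best[better] = (a, b)
    return best[:, 0], best[:, 1]


def fit_hierarchical(data, hypers: HyperPriors = HyperPriors(),
                     settings: McmcSettings = McmcSettings(),
                     q_init: float = 0.5) -> PosteriorSamples:
    """Sample the hierarchical posterior by adaptive random-walk
    Metropolis within Gibbs.

    ``data`` is a list with one trial log (DataFrame or pre-compressed
    arrays) per subject.  Subject parameters are initialized at coarse
    grid-search ML estimates (jittered per chain); group-level parameters
    at the sample mean/SD of those estimates.  Burn-in is discarded and
    thinning applied per :class:`McmcSettings`.
    """
    datasets = _as_arrays(data)
    if not datasets or any(len(d[0]) == 0 for d in datasets):
        raise ValueError("need at least one subject, each with at least one trial")
    offsets, pair, choice, reward = _concat(datasets)
    n_subj = len(datasets)

    mle_a, mle_b = _grid_mle(datasets, q_init)
    bounds = {name: np.array(getattr(hypers, name)) for name in GROUP_PARAMS}

    n_keep = settings.retained_per_chain
    keep_iters = range(settings.n_burnin, settings.n_iterations, settings.thin)
    out = {
        "alpha": np.empty((settings.n_chains, n_keep, n_subj)),
        "beta": np.empty((settings.n_chains, n_keep, n_subj)),
        **{g: np.empty((settings.n_chains, n_keep)) for g in GROUP_PARAMS},
    }
    acc_totals: dict[str, list] = {k: [] for k in ("alpha", "beta", *GROUP_PARAMS)}

    ss = np.random.SeedSequence(settings.seed)
    chain_seeds = ss.spawn(settings.n_chains)

    for c in range(settings.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        alpha = np.clip(mle_a + rng.normal(0, 0.05, n_subj), 1e-3, 1 - 1e-3)
        beta = np.clip(mle_b + rng.normal(0, 0.3, n_subj), 1e-3, None)
        hyp = {
            "mu_alpha": float(np.clip(alpha.mean() + rng.normal(0, 0.02),
                                      *(bounds["mu_alpha"] + [0.01, -0.01]))),
            "sigma_alpha": float(np.clip(alpha.std() + rng.normal(0, 0.02),
                                         0.02, bounds["sigma_alpha"][1] - 0.01)),
            "mu_beta": float(np.clip(beta.mean() + rng.normal(0, 0.1),
                                     *(bounds["mu_beta"] + [0.05, -0.05]))),
            "sigma_beta": float(np.clip(beta.std() + rng.normal(0, 0.1),
                                        0.05, bounds["sigma_beta"][1] - 0.05)),
        }

        ll = _loglik_batch(offsets, pair, choice, reward, alpha, beta, q_init)
        pa = truncnorm_logpdf(alpha, hyp["mu_alpha"], hyp["sigma_alpha"], 0.0, 1.0)
        pb = truncnorm_logpdf(beta, hyp["mu_beta"], hyp["sigma_beta"], 0.0, np.inf)
        if not (np.isfinite(ll).all() and np.isfinite(pa).all() and np.isfinite(pb).all()):
            raise InitializationError(
                f"chain {c}: non-finite initial posterior "
                f"(ll finite: {np.isfinite(ll).all()}, hypers: {hyp})")

        s_alpha = np.full(n_subj, 0.08)
        s_beta = np.full(n_subj, 0.5)
        s_hyp = {"mu_alpha": 0.05, "sigma_alpha": 0.05, "mu_beta": 0.3, "sigma_beta": 0.3}
        acc_post = {k: 0.0 for k in acc_totals}
        acc_window = {k: np.zeros(n_subj) if k in ("alpha", "beta") else 0.0
                      for k in acc_totals}
        window = 50
        keep_set = set(keep_iters)
        k_out = 0

        for t in range(settings.n_iterations):
            # --- subject-level alpha sweep (vectorized across subjects) ---
            prop = alpha + rng.normal(0, s_alpha)
            ll_p = _loglik_batch(offsets, pair, choice, reward, prop, beta, q_init)
            pa_p = truncnorm_logpdf(prop, hyp["mu_alpha"], hyp["sigma_alpha"], 0.0, 1.0)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random(n_subj)) < (ll_p + pa_p) - (ll + pa)
            alpha = np.where(accept, prop, alpha)
            ll = np.where(accept, ll_p, ll)
            pa = np.where(accept, pa_p, pa)
            acc_window["alpha"] += accept
            if t >= settings.n_burnin:
                acc_post["alpha"] += accept.mean()

            # --- subject-level beta sweep ---
            prop = beta + rng.normal(0, s_beta)
            ll_p = _loglik_batch(offsets, pair, choice, reward, alpha, prop, q_init)
            pb_p = truncnorm_logpdf(prop, hyp["mu_beta"], hyp["sigma_beta"], 0.0, np.inf)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random(n_subj)) < (ll_p + pb_p) - (ll + pb)
            beta = np.where(accept, prop, beta)
            ll = np.where(accept, ll_p, ll)
            pb = np.where(accept, pb_p, pb)
            acc_window["beta"] += accept
            if t >= settings.n_burnin:
                acc_post["beta"] += accept.mean()

            # --- group-level scalar updates ---
            for name in GROUP_PARAMS:
                lo, hi = bounds[name]
                prop_h = hyp[name] + rng.normal(0, s_hyp[name])
                if lo < prop_h < hi:
                    if name.endswith("alpha"):
                        mu = prop_h if name == "mu_alpha" else hyp["mu_alpha"]
                        sd = prop_h if name == "sigma_alpha" else hyp["sigma_alpha"]
                        new_prior = truncnorm_logpdf(alpha, mu, sd, 0.0, 1.0)
                        cur = pa
                    else:
                        mu = prop_h if name == "mu_beta" else hyp["mu_beta"]
                        sd = prop_h if name == "sigma_beta" else hyp["sigma_beta"]
                        new_prior = truncnorm_logpdf(beta, mu, sd, 0.0, np.inf)
                        cur = pb
                    if math.log(rng.random()) < new_prior.sum() - cur.sum():
                        hyp[name] = float(prop_h)
                        if name.endswith("alpha"):
                            pa = new_prior
                        else:
                            pb = new_prior
                        acc_window[name] += 1.0
                        if t >= settings.n_burnin:
                            acc_post[name] += 1.0

            # --- proposal adaptation, burn-in only ---
            if t < settings.n_burnin and (t + 1) % window == 0:
                rate_a = acc_window["alpha"] / window
                rate_b = acc_window["beta"] / window
                s_alpha = np.clip(s_alpha * np.exp(rate_a - 0.3), 1e-3, 0.5)
                s_beta = np.clip(s_beta * np.exp(rate_b - 0.3), 1e-3, 3.0)
                for name in GROUP_PARAMS:
                    rate = acc_window[name] / window
                    s_hyp[name] = float(np.clip(s_hyp[name] * math.exp(rate - 0.3),
                                                1e-4, 2.0))
                for k in acc_window:
                    acc_window[k] = np.zeros(n_subj) if k in ("alpha", "beta") else 0.0

            if t in keep_set:
                out["alpha"][c, k_out] = alpha
                out["beta"][c, k_out] = beta
                for g in GROUP_PARAMS:
                    out[g][c, k_out] = hyp[g]
                k_out += 1

        n_post = settings.n_iterations - settings.n_burnin
        for k in acc_totals:
            acc_totals[k].append(acc_post[k] / n_post)

    acceptance = {k: float(np.mean(v)) for k, v in acc_totals.items()}
    return PosteriorSamples(
        alpha=out["alpha"], beta=out["beta"],
        mu_alpha=out["mu_alpha"], sigma_alpha=out["sigma_alpha"],
        mu_beta=out["mu_beta"], sigma_beta=out["sigma_beta"],
        acceptance=acceptance, settings=settings, seed=settings.seed)


def gelman_rubin(samples, parameter: str | None = None) -> float:
    """Potential scale reduction factor (between/within-chain variance form).

    Accepts a :class:`PosteriorSamples` plus a parameter name, or a raw
    (n_chains, n_draws) array.  Constant chains return 1.0 with a warning.
    """
    x = samples.get(parameter) if isinstance(samples, PosteriorSamples) else np.asarray(samples)
    if x.ndim != 2:
        raise ValueError("expected an (n_chains, n_draws) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("R-hat needs >= 2 chains; split each chain in half "
                         "to diagnose a single-chain run")
    if n < 10:
        raise ValueError("R-hat needs >= 10 draws per chain")
    w = x.var(axis=1, ddof=1).mean()
    b_over_n = x.mean(axis=1).var(ddof=1)
    if w == 0 and b_over_n == 0:
        warnings.warn("all chains constant; R-hat defined as 1.0")
        return 1.0
    if w == 0:
        return np.inf
    var_hat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(var_hat / w))


def wald_compare(samples_g1, samples_g2, parameter: str) -> tuple[float, float]:
    """Wald z-test between two groups' posterior draws of one parameter.

    z = (mean1 - mean2) / sqrt(sd1^2 + sd2^2) over retained draws, with a
    two-sided normal p-value.
    """
    x1 = samples_g1.get(parameter).ravel() if isinstance(samples_g1, PosteriorSamples) \
        else np.ravel(samples_g1)
    x2 = samples_g2.get(parameter).ravel() if isinstance(samples_g2, PosteriorSamples) \
        else np.ravel(samples_g2)
    pooled = x1.var(ddof=1) + x2.var(ddof=1)
    if pooled == 0:
        if x1.mean() == x2.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    z = (x1.mean() - x2.mean()) / math.sqrt(pooled)
    p = 2.0 * ndtr(-abs(z))
    return float(z), float(p)
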