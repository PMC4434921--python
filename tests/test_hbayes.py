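"""Hierarchical model: density, sampler, convergence and Wald diagnostics."""

import math

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import truncnorm as sp_truncnorm

from affectrl.hbayes import (
    GROUP_PARAMS,
    HyperPriors,
    McmcSettings,
    fit_hierarchical,
    gelman_rubin,
    log_posterior,
    paper_settings,
    truncnorm_logpdf,
    wald_compare,
)
from affectrl.rl import AgentParams, simulate_agent
from affectrl.synth import synth_cohort, GroupSpec
from affectrl.task import TaskConfig, generate_schedule, realize_rewards
from conftest import replay_likelihood

HYPERS = {"mu_alpha": 0.4, "sigma_alpha": 0.2, "mu_beta": 3.0, "sigma_beta": 1.0}


def _tiny_data(n_subjects=2, n_trials=10, seed=0):
    cfg = TaskConfig(n_blocks_per_condition=1, trials_per_condition=max(n_trials, 5),
                     block_length_range=(max(n_trials, 5), max(n_trials, 5)),
                     ratio_set=((6, 1),))
    data = []
    for i in range(n_subjects):
        sch = generate_schedule(cfg, seed=seed + i)
        rw = realize_rewards(sch, seed=seed + 50 + i)
        data.append(simulate_agent(AgentParams(0.3, 2.0), sch, rw, seed + 100 + i)
                    .iloc[:n_trials])
    return data


def test_retained_draw_identity_defaults():
    s = McmcSettings()
    assert (s.n_chains, s.n_iterations, s.n_burnin, s.thin) == (3, 16_000, 6_000, 5)
    assert s.pre_thin_total == 30_000
    assert s.retained_total == 6_000


@pytest.mark.parametrize("chains,iters,burn,thin", [(2, 1000, 200, 4), (4, 333, 33, 7)])
def test_retained_draw_identity_general(chains, iters, burn, thin):
    s = McmcSettings(n_chains=chains, n_iterations=iters, n_burnin=burn, thin=thin)
    assert s.retained_per_chain == len(range(burn, iters, thin))
    assert s.retained_total == chains * s.retained_per_chain


def test_truncnorm_logpdf_matches_scipy():
    x = np.linspace(0.01, 0.99, 17)
    mine = truncnorm_logpdf(x, 0.3, 0.15, 0.0, 1.0)
    ref = sp_truncnorm.logpdf(x, (0 - 0.3) / 0.15, (1 - 0.3) / 0.15, loc=0.3, scale=0.15)
    np.testing.assert_allclose(mine, ref, atol=1e-12)
    assert truncnorm_logpdf(np.array([-0.1, 1.1]), 0.3, 0.15, 0.0, 1.0).tolist() == \
        [-np.inf, -np.inf]


def test_log_posterior_support():
    data = _tiny_data(1, 5)
    params = [AgentParams(0.3, 2.0)]
    bad = dict(HYPERS, mu_beta=11.0)
    assert log_posterior(params, bad, data) == -np.inf
    assert np.isfinite(log_posterior(params, HYPERS, data))


def test_log_posterior_flat_subject():
    """With beta_i = 0 the data term is n*log(0.5) plus the prior terms."""
    data = _tiny_data(1, 10)
    params = [AgentParams(0.3, 0.0)]
    got = log_posterior(params, HYPERS, data)
    prior = (sp_truncnorm.logpdf(0.3, -0.4 / 0.2, 0.6 / 0.2, loc=0.4, scale=0.2)
             + sp_truncnorm.logpdf(0.0, -3.0, np.inf, loc=3.0, scale=1.0)
             - math.log(1) - math.log(1) - math.log(10) - math.log(5))
    assert got == pytest.approx(10 * math.log(0.5) + prior, abs=1e-10)


def test_log_posterior_term_by_term_oracle():
    """Joint density equals the independently computed sum of likelihoods,
    truncated-normal subject priors and uniform hyperpriors."""
    data = _tiny_data(2, 10)
    params = [AgentParams(0.25, 1.5), AgentParams(0.6, 3.5)]
    expected = 0.0
    for p, d in zip(params, data):
        expected += replay_likelihood(p, d)
        expected += sp_truncnorm.logpdf(
            p.alpha, (0 - HYPERS["mu_alpha"]) / HYPERS["sigma_alpha"],
            (1 - HYPERS["mu_alpha"]) / HYPERS["sigma_alpha"],
            loc=HYPERS["mu_alpha"], scale=HYPERS["sigma_alpha"])
        expected += sp_truncnorm.logpdf(
            p.beta, (0 - HYPERS["mu_beta"]) / HYPERS["sigma_beta"], np.inf,
            loc=HYPERS["mu_beta"], scale=HYPERS["sigma_beta"])
    expected += -math.log(10) - math.log(5)  # uniform hyperprior densities
    assert log_posterior(params, HYPERS, data) == pytest.approx(expected, abs=1e-10)


def test_fit_bookkeeping_and_truncation():
    data = _tiny_data(2, 20)
    settings = McmcSettings(n_chains=3, n_iterations=600, n_burnin=200, thin=4, seed=1)
    post = fit_hierarchical(data, settings=settings)
    assert post.n_retained == settings.retained_total
    assert post.alpha.shape == (3, settings.retained_per_chain, 2)
    assert (post.alpha >= 0).all() and (post.alpha <= 1).all()
    assert (post.beta >= 0).all()
    assert (post.sigma_alpha > 0).all() and (post.sigma_beta > 0).all()


def test_fit_reproducible():
    data = _tiny_data(2, 20)
    s = McmcSettings(n_chains=2, n_iterations=400, n_burnin=100, thin=2, seed=5)
    a, b = fit_hierarchical(data, settings=s), fit_hierarchical(data, settings=s)
    np.testing.assert_array_equal(a.mu_alpha, b.mu_alpha)
    np.testing.assert_array_equal(a.beta, b.beta)


def test_posterior_mean_matches_grid_oracle():
    """One subject, five trials: the MCMC marginal posterior mean of alpha
    agrees with dense grid integration (hypers marginalized numerically)."""
    data = _tiny_data(1, 5, seed=3)

    a_grid = np.linspace(0.0025, 0.9975, 200)
    b_grid = np.linspace(0.0125, 12.4875, 500)
    mu_a = np.linspace(0.0025, 0.9975, 200)
    sd_a = np.linspace(0.0025, 0.9975, 200)
    mu_b = np.linspace(0.025, 9.975, 200)
    sd_b = np.linspace(0.0125, 4.9875, 200)

    # marginal subject-level prior: integrate truncated normals over the
    # uniform hyper grids
    def marginal(grid, mus, sds, hi):
        out = np.zeros_like(grid)
        for s in sds:
            lp = truncnorm_logpdf(grid[:, None], mus[None, :], s, 0.0, hi)
            out += np.exp(logsumexp(lp, axis=1) - math.log(lp.shape[1]))
        return out / len(sds)

    prior_a = marginal(a_grid, mu_a, sd_a, 1.0)
    prior_b = marginal(b_grid, mu_b, sd_b, np.inf)

    # the value trajectory depends on alpha only, so replay once per alpha
    # and evaluate the softmax term over the whole beta grid in numpy
    def ll_row(alpha):
        q = {}
        qc, qo = [], []   # chosen / other deck values per trial
        for row in data[0].sort_values("trial").itertuples(index=False):
            decks = ("A", "B") if row.pair == "Up" else ("C", "D")
            if row.pair not in q:
                q[row.pair] = {d: 0.5 for d in decks}
            other = decks[0] if row.choice == decks[1] else decks[1]
            qc.append(q[row.pair][row.choice])
            qo.append(q[row.pair][other])
            q[row.pair][row.choice] += alpha * (row.reward - q[row.pair][row.choice])
        qc, qo = np.array(qc), np.array(qo)
        bg = b_grid[:, None]
        return (bg * qc - np.logaddexp(bg * qc, bg * qo)).sum(axis=1)

    ll = np.array([ll_row(a) for a in a_grid])
    post = np.exp(ll) * prior_a[:, None] * prior_b[None, :]
    oracle_mean = (post.sum(axis=1) * a_grid).sum() / post.sum()

    settings = McmcSettings(n_chains=3, n_iterations=6000, n_burnin=2000, thin=2, seed=9)
    samples = fit_hierarchical(data, settings=settings)
    assert samples.alpha.mean() == pytest.approx(oracle_mean, abs=0.02)


def test_posterior_sd_shrinks_with_more_data():
    """Doubling subjects and trials tightens the posterior on mu_alpha."""
    sds = []
    for n_subj, trials in [(5, 60), (10, 120)]:
        cfg = TaskConfig(n_blocks_per_condition=1, trials_per_condition=trials,
                         block_length_range=(trials, trials), ratio_set=((6, 1),))
        sd_runs = []
        for seed in (0, 1):
            logs, _ = synth_cohort(GroupSpec(n_subjects=n_subj), cfg, seed=seed)
            post = fit_hierarchical(logs, settings=McmcSettings(
                n_chains=2, n_iterations=1500, n_burnin=500, thin=2, seed=seed))
            sd_runs.append(post.mu_alpha.std())
        sds.append(np.mean(sd_runs))
    assert sds[1] < sds[0]


def test_gelman_rubin_cases():
    rng = np.random.default_rng(0)
    iid = rng.normal(0, 1, (4, 2000))
    assert 0.99 <= gelman_rubin(iid) <= 1.05
    shifted = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    assert gelman_rubin(shifted) > 1.5
    with pytest.warns(UserWarning):
        assert gelman_rubin(np.ones((3, 100))) == 1.0
    with pytest.raises(ValueError, match="chains"):
        gelman_rubin(np.ones((1, 100)))


def test_wald_compare_closed_form():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 4000)
    z, p = wald_compare(x, x.copy(), parameter="")
    assert z == 0.0 and p == 1.0
    # groups standardized to mean 0 vs 1, sd 0.5 each: z = -1/sqrt(0.5)
    g1 = rng.normal(0, 1, 100)
    g1 = (g1 - g1.mean()) / g1.std(ddof=1) * 0.5 + 0.0
    g2 = rng.normal(0, 1, 100)
    g2 = (g2 - g2.mean()) / g2.std(ddof=1) * 0.5 + 1.0
    z, p = wald_compare(g1, g2, parameter="")
    assert z == pytest.approx(-1 / math.sqrt(0.5), abs=1e-9)
    assert 0 < p < 0.2
    z2, _ = wald_compare(g2, g1, parameter="")
    assert z2 == pytest.approx(-z)
    with pytest.raises(ValueError):
        wald_compare(np.zeros(10), np.ones(10), parameter="")


def test_paper_settings_helper():
    s = paper_settings(seed=3)
    assert s.retained_total == 6000 and s.seed == 3
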