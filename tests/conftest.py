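"""Shared fixtures: small task objects, independent oracles, participant factories.

The oracle implementations here are deliberately written from scratch with
scalar math (no reuse of the package's vectorised code paths) so they can
serve as independent references for the grid-Bayes learner and the rank-sum
test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from moral_inference.inference import AgentBlock, ParticipantData
from moral_inference.learner import LearnerParams, run_learner
from moral_inference.task import (
    Trial,
    TrialOption,
    TrialSet,
    default_agents,
    generate_trial_set,
    simulate_agent,
)


@pytest.fixture
def small_trial_set() -> TrialSet:
    return generate_trial_set(10, variant_seed=7)


@pytest.fixture
def agents():
    return default_agents()


def _brute_force_learner(mu0, sigma0, beta, lam, grid, trials, choices, money_scale, shock_scale):
    """Scalar re-implementation of the Bayes loop: lists, math.exp, explicit sums."""
    mass = []
    for g in grid:
        mass.append(math.exp(-0.5 * ((g - mu0) / sigma0) ** 2))
    total = sum(mass)
    mass = [m / total for m in mass]

    def moments(m):
        mean = sum(mi * gi for mi, gi in zip(m, grid))
        var = sum(mi * (gi - mean) ** 2 for mi, gi in zip(m, grid))
        return mean, math.sqrt(max(var, 0.0))

    records = []
    for trial, observed in zip(trials, choices):
        dm = (trial.harmful.money - trial.helpful.money) / money_scale
        ds = (trial.harmful.shocks - trial.helpful.shocks) / shock_scale
        lik_harm = [1.0 / (1.0 + math.exp(-beta * ((1 - g) * dm - g * ds))) for g in grid]
        p_pred = sum(mi * li for mi, li in zip(mass, lik_harm))
        mu_pre, sd_pre = moments(mass)
        lik = lik_harm if observed else [1.0 - li for li in lik_harm]
        post = [mi * li for mi, li in zip(mass, lik)]
        z = sum(post)
        post = [pi / z for pi in post]
        if lam > 0:
            post = [(1 - lam) * pi + lam / len(grid) for pi in post]
        mu_post, sd_post = moments(post)
        delta = (1.0 if observed else 0.0) - p_pred
        alpha = 0.0 if abs(delta) < 1e-12 else abs(mu_post - mu_pre) / abs(delta)
        records.append(
            {
                "p_pred": p_pred,
                "mu_pre": mu_pre,
                "sigma_pre": sd_pre,
                "mu_post": mu_post,
                "sigma_post": sd_post,
                "delta": delta,
                "alpha": alpha,
            }
        )
        mass = post
    return records, mass


@pytest.fixture(scope="session")
def brute_force_learner():
    return _brute_force_learner


def _exact_ranksum_p(a, b):
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Uses midranks; two-sided as P(|W - EW| >= |w_obs - EW|).
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = rankdata(pooled)
    n, n_a = len(pooled), len(a)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    target = abs(w_obs - mu) - 1e-12
    hits = total = 0
    for combo in itertools.combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= target:
            hits += 1
    return hits / total


@pytest.fixture(scope="session")
def exact_ranksum_p():
    return _exact_ranksum_p


def _make_synthetic_participant(
    i: int,
    mu: tuple[float, float],
    sigma: tuple[float, float],
    beta_learner: float,
    lam: float,
    n_trials: int,
    agent_beta: float = 6.0,
    seed0: int = 0,
    lapse: float = 0.02,
    leak_to_prior: bool = False,
) -> ParticipantData:
    """Simulate one two-agent participant directly from the dynamic learner."""
    rng = np.random.default_rng(seed0 + 7919 * i)
    ag = default_agents(beta=agent_beta)
    blocks = {}
    gen = {}
    for k, lab in enumerate(["bad", "good"]):
        ts = generate_trial_set(n_trials, variant_seed=seed0 + 4 * i + k)
        ch = simulate_agent(ag[lab], ts, seed=seed0 + 4 * i + 2 + k)
        params = LearnerParams(mu0=mu[k], sigma0=sigma[k], beta=beta_learner, lam=lam)
        traces, _ = run_learner(params, ts, ch, leak_to_prior=leak_to_prior)
        q = lapse + (1 - 2 * lapse) * np.array([t.p_pred for t in traces])
        preds = rng.random(n_trials) < q
        blocks[lab] = AgentBlock(ts, np.array([c.chose_harmful for c in ch]), preds)
        gen[f"mu0_{lab}"], gen[f"sigma0_{lab}"] = mu[k], sigma[k]
    return ParticipantData(
        participant_id=f"sim-{i:03d}", group="sim", blocks=blocks, generative_params=gen
    )


@pytest.fixture(scope="session")
def make_synthetic_participant():
    return _make_synthetic_participant


def two_point_trial() -> Trial:
    return Trial(index=1, harmful=TrialOption(8.0, 10), helpful=TrialOption(2.0, 2))
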