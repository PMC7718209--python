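"""Dynamic Bayesian learner: prior construction, prediction, update, learning rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from moral_inference.inference import prediction_nll
from moral_inference.learner import (
    BeliefState,
    LearnerParamError,
    LearnerParams,
    init_belief,
    learning_rate,
    predict,
    run_learner,
    update,
)
from moral_inference.task import Trial, TrialOption, TrialSet, generate_trial_set, simulate_agent, default_agents

TRIAL = Trial(1, TrialOption(8.0, 10), TrialOption(2.0, 2))


class TestInitBelief:
    def test_flat_prior_limit(self):
        b = init_belief(LearnerParams(0.5, 50.0, 1.0), grid_size=41)
        assert b.mass.max() - b.mass.min() < 1e-3
        assert b.mean == pytest.approx(0.5, abs=1e-6)

    def test_symmetry_about_half(self):
        b = init_belief(LearnerParams(0.5, 0.2, 1.0), grid_size=51)
        assert np.allclose(b.mass, b.mass[::-1])

    def test_three_point_hand_computation(self):
        b = init_belief(LearnerParams(0.5, 0.25, 1.0), grid_size=3)
        lo = math.exp(-0.5 * (0.5 / 0.25) ** 2)  # density at 0 and 1, relative to centre
        expected = np.array([lo, 1.0, lo]) / (1.0 + 2 * lo)
        assert np.allclose(b.mass, expected, atol=1e-15)

    def test_mean_close_to_mu0_for_moderate_priors(self):
        # truncation at [0, 1] shifts the mean inward; the shift stays small
        # while the prior keeps ~1.5 SDs of clearance from the boundary
        for mu0, sigma0 in ((0.2, 0.13), (0.3, 0.2), (0.5, 0.2), (0.7, 0.2), (0.8, 0.13)):
            b = init_belief(LearnerParams(mu0, sigma0, 1.0))
            assert abs(b.mean - mu0) < 0.05

    def test_parameter_validation(self):
        with pytest.raises(LearnerParamError):
            LearnerParams(0.5, 0.0, 1.0)
        with pytest.raises(LearnerParamError):
            init_belief(LearnerParams(0.5, 0.2, 1.0), grid_size=2)


class TestPredict:
    def test_point_mass_equals_choice_rule(self):
        from moral_inference.task import AgentSpec, choice_prob

        b = BeliefState(grid=np.array([0.2, 0.6, 0.9]), mass=np.array([0.0, 1.0, 0.0]))
        expected = choice_prob(AgentSpec("x", 0.6, 4.0), TRIAL)
        assert predict(b, TRIAL, beta=4.0) == pytest.approx(expected, abs=1e-14)

    def test_zero_beta_is_chance(self):
        b = init_belief(LearnerParams(0.3, 0.1, 1.0))
        assert predict(b, TRIAL, beta=0.0) == pytest.approx(0.5)

    def test_two_point_mixture_is_average(self):
        from moral_inference.task import AgentSpec, choice_prob

        b = BeliefState(grid=np.array([0.3, 0.7]), mass=np.array([0.5, 0.5]))
        expected = 0.5 * (
            choice_prob(AgentSpec("x", 0.3, 2.0), TRIAL)
            + choice_prob(AgentSpec("x", 0.7, 2.0), TRIAL)
        )
        assert predict(b, TRIAL, beta=2.0) == pytest.approx(expected, abs=1e-14)


class TestUpdate:
    def test_flat_likelihood_leaves_prior(self):
        b = init_belief(LearnerParams(0.4, 0.15, 1.0), grid_size=21)
        post = update(b, TRIAL, observed=True, beta=0.0, lam=0.0)
        assert np.allclose(post.mass, b.mass, atol=1e-15)

    def test_full_forgetting_gives_uniform(self):
        b = init_belief(LearnerParams(0.4, 0.15, 1.0), grid_size=21)
        post = update(b, TRIAL, observed=True, beta=3.0, lam=1.0)
        assert np.allclose(post.mass, 1.0 / 21, atol=1e-15)

    def test_two_point_bayes_by_hand(self):
        grid = np.array([0.3, 0.7])
        b = BeliefState(grid=grid, mass=np.array([0.5, 0.5]))
        beta, dm, ds = 2.0, TRIAL.delta_money, TRIAL.delta_shocks
        lik = 1.0 / (1.0 + np.exp(-beta * ((1 - grid) * dm - grid * ds)))
        expected = (0.5 * lik) / (0.5 * lik).sum()
        post = update(b, TRIAL, observed=True, beta=beta, lam=0.0)
        assert np.allclose(post.mass, expected, atol=1e-14)

    def test_harmful_observation_never_raises_mean(self):
        b = init_belief(LearnerParams(0.5, 0.2, 1.0))
        post = update(b, TRIAL, observed=True, beta=4.0, lam=0.0)
        assert post.mean <= b.mean
        post2 = update(b, TRIAL, observed=False, beta=4.0, lam=0.0)
        assert post2.mean >= b.mean


class TestLearningRate:
    def test_null_update_gives_zero(self):
        assert learning_rate(0.5, 0.5, 0.3) == 0.0
        assert learning_rate(0.5, 0.6, 1e-15) == 0.0

    def test_hand_computed_from_two_point_example(self):
        grid = np.array([0.3, 0.7])
        b = BeliefState(grid=grid, mass=np.array([0.5, 0.5]))
        p = predict(b, TRIAL, beta=2.0)
        post = update(b, TRIAL, observed=True, beta=2.0, lam=0.0)
        expected = abs(post.mean - b.mean) / abs(1.0 - p)
        assert learning_rate(b.mean, post.mean, 1.0 - p) == pytest.approx(expected)

    def test_alpha_strictly_increases_with_prior_spread(self):
        # the uncertainty-gating mechanism: wider priors update more per unit error
        sigmas = np.arange(0.05, 0.41, 0.05)
        alphas = []
        for s in sigmas:
            b = init_belief(LearnerParams(0.5, float(s), 1.0), grid_size=101)
            p = predict(b, TRIAL, beta=4.0)
            post = update(b, TRIAL, observed=True, beta=4.0, lam=0.0)
            alphas.append(learning_rate(b.mean, post.mean, 1.0 - p))
        assert all(a < b for a, b in zip(alphas, alphas[1:]))


class TestRunLearner:
    def test_zero_trials(self):
        params = LearnerParams(0.5, 0.2, 2.0)
        empty = TrialSet(trials=[], money_scale=6.0, shock_scale=8.0)
        traces, final = run_learner(params, empty, [])
        assert traces == []
        assert np.allclose(final.mass, init_belief(params).mass)

    def test_length_mismatch_rejected(self, small_trial_set):
        with pytest.raises(ValueError):
            run_learner(LearnerParams(0.5, 0.2, 2.0), small_trial_set, [True])

    def test_monotone_mean_under_uniform_harmful_evidence(self, small_trial_set):
        params = LearnerParams(0.5, 0.25, 3.0, lam=0.0)
        traces, _ = run_learner(params, small_trial_set, [True] * len(small_trial_set))
        mus = [t.mu_pre for t in traces] + [traces[-1].mu_post]
        assert all(a >= b - 1e-12 for a, b in zip(mus, mus[1:]))

    @pytest.mark.parametrize("grid_size,n_trials", [(3, 5), (5, 10)])
    def test_matches_brute_force_oracle(self, brute_force_learner, grid_size, n_trials):
        ts = generate_trial_set(n_trials, variant_seed=13)
        choices = simulate_agent(default_agents()["bad"], ts, seed=5)
        params = LearnerParams(0.45, 0.22, 3.5, lam=0.07)
        traces, final = run_learner(params, ts, choices, grid_size=grid_size)
        grid = list(np.linspace(0, 1, grid_size))
        recs, brute_mass = brute_force_learner(
            params.mu0, params.sigma0, params.beta, params.lam, grid,
            ts.trials, [c.chose_harmful for c in choices], ts.money_scale, ts.shock_scale,
        )
        for t, r in zip(traces, recs):
            for key in ("p_pred", "mu_pre", "sigma_pre", "mu_post", "sigma_post", "delta", "alpha"):
                assert getattr(t, key) == pytest.approx(r[key], abs=1e-12)
        assert np.allclose(final.mass, brute_mass, atol=1e-12)

    def test_leak_bounds_uncertainty_away_from_zero(self):
        ts = generate_trial_set(300, variant_seed=21)
        choices = simulate_agent(default_agents()["bad"], ts, seed=2)
        _, final = run_learner(LearnerParams(0.5, 0.3, 6.0, lam=0.1), ts, choices)
        assert final.sd > 0.02

    def test_prediction_nll_consistent_with_traces(self, make_synthetic_participant):
        p = make_synthetic_participant(0, (0.4, 0.6), (0.3, 0.15), 2.0, 0.02, 15, seed0=44)
        params = {"mu0_bad": 0.4, "sigma0_bad": 0.3, "mu0_good": 0.6, "sigma0_good": 0.15, "beta": 2.0}
        nll = prediction_nll("dynamic", params, p, lapse=0.02, grid_size=101, lam=0.02)
        manual = 0.0
        for lab in ("bad", "good"):
            block = p.blocks[lab]
            traces, _ = run_learner(
                LearnerParams(params[f"mu0_{lab}"], params[f"sigma0_{lab}"], 2.0, 0.02),
                block.trial_set, list(block.agent_choices), grid_size=101,
            )
            for t, pred in zip(traces, block.predictions):
                q = 0.02 + 0.96 * t.p_pred
                manual -= math.log(q) if pred else math.log(1 - q)
        assert nll == pytest.approx(manual, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    mu0=st_h.floats(0.1, 0.9),
    sigma0=st_h.floats(0.05, 0.5),
    beta=st_h.floats(0.0, 10.0),
    lam=st_h.floats(0.0, 1.0),
    observed=st_h.booleans(),
)
def test_update_preserves_belief_invariants(mu0, sigma0, beta, lam, observed):
    """Any single update keeps the mass normalized, nonnegative, mean in [0, 1]."""
    b = init_belief(LearnerParams(mu0, sigma0, beta, lam), grid_size=31)
    post = update(b, TRIAL, observed=observed, beta=beta, lam=lam)
    assert abs(post.mass.sum() - 1.0) < 1e-10
    assert (post.mass >= -1e-15).all()
    assert 0.0 <= post.mean <= 1.0
    assert post.sd >= 0.0
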