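"""Grid-based Bayesian learner over an agent's harm aversion, with dynamic learning rates.

The learner maintains a discretised probability distribution (a "belief") over
the agent's exchange rate kappa on a regular grid in [0, 1]. Before each trial
it predicts the agent's choice by averaging the logistic choice rule over the
belief; after observing the choice it applies Bayes' rule on the grid and then
leaks a fraction ``lam`` of mass toward a target distribution — the uniform
by default, or the learner's own prior — a forgetting term that keeps
uncertainty from collapsing over long runs.

The trialwise effective learning rate is defined in Rescorla–Wagner terms:

    alpha_t = |mu_post - mu_pre| / |delta_t|,   delta_t = observed - p_pred

i.e. the amount the belief mean moved per unit of prediction error. Because
Bayesian updates are precision-weighted, alpha_t grows with the spread of the
prior belief: when beliefs are less precise, new information is weighted more
heavily. That uncertainty-gating is the phenomenon of interest downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import AgentChoice, Trial, TrialSet, harmful_choice_prob

DEFAULT_GRID_SIZE = 101
#: Tolerance for belief-mass normalisation checks.
MASS_TOL = 1e-10


class LearnerParamError(ValueError):
    pass


@dataclass(frozen=True)
class LearnerParams:
    """Free parameters of the dynamic learner.

    mu0, sigma0
        Mean and spread of the truncated-Gaussian prior belief over kappa.
    beta
        Choice consistency the learner attributes to the agent.
    lam
        Leak weight in [0, 1]: after each Bayes step the belief is mixed with
        the uniform distribution, ``(1-lam)*posterior + lam*uniform``.
    """

    mu0: float
    sigma0: float
    beta: float
    lam: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu0 <= 1.0:
            raise LearnerParamError(f"mu0 must lie in [0, 1], got {self.mu0}")
        if not self.sigma0 > 0:
            raise LearnerParamError(f"sigma0 must be > 0, got {self.sigma0}")
        if self.beta < 0:
            raise LearnerParamError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 <= self.lam <= 1.0:
            raise LearnerParamError(f"lam must lie in [0, 1], got {self.lam}")


@dataclass
class BeliefState:
    """Discretised belief over kappa: grid locations and probability masses."""

    grid: np.ndarray
    mass: np.ndarray

    def validate(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.mass < -MASS_TOL):
            raise ValueError("belief masses must be nonnegative")
        if abs(float(self.mass.sum()) - 1.0) > MASS_TOL:
            raise ValueError("belief masses must sum to 1")

    @property
    def mean(self) -> float:
        return float(self.mass @ self.grid)

    @property
    def sd(self) -> float:
        m = self.mean
        var = float(self.mass @ (self.grid - m) ** 2)
        return float(np.sqrt(max(var, 0.0)))


@dataclass(frozen=True)
class TrialTrace:
    """Per-trial record of the predict -> observe -> update cycle."""

    trial_index: int
    p_pred: float
    observed: bool
    delta: float
    mu_pre: float
    sigma_pre: float
    mu_post: float
    sigma_post: float
    alpha: float


def gaussian_mass(grid: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Truncated-Gaussian density evaluated on the grid, renormalised to sum 1."""
    w = np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
    return w / w.sum()


def init_belief(params: LearnerParams, grid_size: int = DEFAULT_GRID_SIZE) -> BeliefState:
    """Prior belief: truncated Gaussian N(mu0, sigma0^2) on a regular kappa grid."""
    if grid_size < 3:
        raise LearnerParamError(f"grid_size must be >= 3, got {grid_size}")
    grid = np.linspace(0.0, 1.0, grid_size)
    return BeliefState(grid=grid, mass=gaussian_mass(grid, params.mu0, params.sigma0))


def predict(
    belief: BeliefState,
    trial: Trial,
    beta: float,
    money_scale: float = 1.0,
    shock_scale: float = 1.0,
) -> float:
    """Predicted P(agent chooses harmful): the choice rule averaged over the belief."""
    dm = trial.delta_money / money_scale
    ds = trial.delta_shocks / shock_scale
    p = harmful_choice_prob(belief.grid, beta, dm, ds)
    return float(belief.mass @ p)


def update(
    belief: BeliefState,
    trial: Trial,
    observed: bool,
    beta: float,
    lam: float = 0.0,
    money_scale: float = 1.0,
    shock_scale: float = 1.0,
    leak_target: np.ndarray | None = None,
) -> BeliefState:
    """One Bayes step on the grid followed by a leak.

    The likelihood of a harmful choice is the logistic choice rule at each
    grid point; a helpful choice uses its complement. The leak mixes the
    renormalised posterior with ``leak_target`` (a probability vector on the
    same grid) with weight ``lam``; by default the target is the uniform
    distribution. Anchoring the leak to the learner's own prior instead keeps
    belief spread — and with it the dynamic learning rate — tied to the prior
    throughout long runs rather than converging to a prior-independent floor.
    """
    dm = trial.delta_money / money_scale
    ds = trial.delta_shocks / shock_scale
    p = harmful_choice_prob(belief.grid, beta, dm, ds)
    lik = p if observed else 1.0 - p
    post = belief.mass * lik
    total = float(post.sum())
    if total <= 0.0 or not np.isfinite(total):
        raise ArithmeticError("likelihood vanished over the entire grid")
    post = post / total
    if lam > 0.0:
        target = leak_target if leak_target is not None else 1.0 / len(post)
        post = (1.0 - lam) * post + lam * target
    return BeliefState(grid=belief.grid, mass=post)


def learning_rate(mu_pre: float, mu_post: float, delta: float) -> float:
    """Effective learning rate |d mu| / |delta|; zero when the trial carried no information."""
    if abs(delta) < 1e-12:
        return 0.0
    return abs(mu_post - mu_pre) / abs(delta)


def run_learner(
    params: LearnerParams,
    trial_set: TrialSet,
    choices: list[AgentChoice],
    grid_size: int = DEFAULT_GRID_SIZE,
    leak_to_prior: bool = False,
) -> tuple[list[TrialTrace], BeliefState]:
    """Run the full predict -> observe -> update loop over a trial sequence.

    With ``leak_to_prior`` the forgetting term pulls the belief back toward
    the learner's own prior rather than the uniform distribution, so
    prior-driven differences in belief spread persist across the session.
    Returns the per-trial traces (in trial order) and the final belief.
    """
    if len(choices) != len(trial_set):
        raise ValueError(
            f"{len(choices)} choices provided for {len(trial_set)} trials"
        )
    belief = init_belief(params, grid_size)
    target = belief.mass.copy() if leak_to_prior else None
    ms, ss = trial_set.money_scale, trial_set.shock_scale
    traces: list[TrialTrace] = []
    for trial, choice in zip(trial_set.trials, choices):
        observed = bool(
            choice.chose_harmful if isinstance(choice, AgentChoice) else choice
        )
        p_pred = predict(belief, trial, params.beta, ms, ss)
        delta = float(observed) - p_pred
        mu_pre, sigma_pre = belief.mean, belief.sd
        belief = update(
            belief, trial, observed, params.beta, params.lam, ms, ss, leak_target=target
        )
        mu_post, sigma_post = belief.mean, belief.sd
        traces.append(
            TrialTrace(
                trial_index=trial.index,
                p_pred=p_pred,
                observed=observed,
                delta=delta,
                mu_pre=mu_pre,
                sigma_pre=sigma_pre,
                mu_post=mu_post,
                sigma_post=sigma_post,
                alpha=learning_rate(mu_pre, mu_post, delta),
            )
        )
    return traces, belief


def traces_to_frame(traces: list[TrialTrace], participant_id: str = "", agent_label: str = ""):
    """Serialise traces to the long CSV schema shared by all three models."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in traces],
            "p_pred": [t.p_pred for t in traces],
            "observed": [t.observed for t in traces],
            "delta": [t.delta for t in traces],
            "mu_pre": [t.mu_pre for t in traces],
            "sigma_pre": [t.sigma_pre for t in traces],
            "mu_post": [t.mu_post for t in traces],
            "sigma_post": [t.sigma_post for t in traces],
            "alpha": [t.alpha for t in traces],
        }
    )
    if participant_id:
        frame.insert(0, "participant_id", participant_id)
    if agent_label:
        frame.insert(1 if participant_id else 0, "agent_label", agent_label)
    return frame
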