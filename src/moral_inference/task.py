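"""Moral inference task: trial structure, agent preference model, choice simulation.

The task presents an observer with a sequence of binary choices faced by
another person (the "agent"): a *harmful* option (more money, more painful
electric shocks delivered to a victim) versus a *helpful* option (less money,
fewer shocks). An agent is characterised by a harm-aversion exchange rate
``kappa`` in [0, 1] — how much money the agent requires per shock inflicted —
and a choice-consistency (inverse temperature) ``beta`` >= 0. The probability
that the agent takes the harmful option follows a logistic choice rule on the
money/shock trade-off:

    P(harmful) = logistic(beta * [(1 - kappa) * dm - kappa * ds])

where ``dm`` and ``ds`` are the money and shock differences between the two
options, each rescaled by its task-wide maximum so that kappa is a unitless
exchange rate (kappa = 0.5 is indifferent when dm = ds after rescaling).

A two-agent task instance pairs a "good" agent (high kappa, needs a lot of
money to harm) with a "bad" agent (low kappa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

GOOD = "good"
BAD = "bad"
AGENT_LABELS = (BAD, GOOD)


class TaskConfigError(ValueError):
    """Raised when a task cannot be constructed from the given settings."""


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class TrialOption:
    """One side of a trial: money gained and shocks inflicted."""

    money: float
    shocks: int

    def __post_init__(self) -> None:
        _require_finite("money", self.money)
        if self.money < 0:
            raise ValueError(f"money must be >= 0, got {self.money}")
        if int(self.shocks) != self.shocks or self.shocks < 0:
            raise ValueError(f"shocks must be a nonnegative integer, got {self.shocks}")


@dataclass(frozen=True)
class Trial:
    """A single choice problem: harmful option strictly dominates on money and shocks."""

    index: int
    harmful: TrialOption
    helpful: TrialOption

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"trial index must be >= 1, got {self.index}")
        if not self.harmful.money > self.helpful.money:
            raise ValueError("harmful option must offer strictly more money")
        if not self.harmful.shocks > self.helpful.shocks:
            raise ValueError("harmful option must inflict strictly more shocks")

    @property
    def delta_money(self) -> float:
        return self.harmful.money - self.helpful.money

    @property
    def delta_shocks(self) -> int:
        return self.harmful.shocks - self.helpful.shocks


@dataclass(frozen=True)
class AgentSpec:
    """An agent's moral preference: exchange rate kappa and consistency beta."""

    label: str
    kappa: float
    beta: float

    def __post_init__(self) -> None:
        _require_finite("kappa", self.kappa)
        _require_finite("beta", self.beta)
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


@dataclass(frozen=True)
class AgentChoice:
    """The agent's observed decision on one trial."""

    trial_index: int
    chose_harmful: bool


@dataclass
class TrialSet:
    """A sequence of trials together with the rescaling constants.

    ``money_scale`` and ``shock_scale`` are the task-wide maxima of the money
    and shock differences; dividing by them puts both attribute differences on
    [0, 1] so kappa acts as a unitless exchange rate.
    """

    trials: list[Trial]
    money_scale: float = field(default=0.0)
    shock_scale: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.money_scale <= 0:
            self.money_scale = max(t.delta_money for t in self.trials)
        if self.shock_scale <= 0:
            self.shock_scale = float(max(t.delta_shocks for t in self.trials))

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def dm(self) -> np.ndarray:
        """Rescaled money differences, one per trial."""
        return np.array([t.delta_money for t in self.trials]) / self.money_scale

    @property
    def ds(self) -> np.ndarray:
        """Rescaled shock differences, one per trial."""
        return np.array([float(t.delta_shocks) for t in self.trials]) / self.shock_scale

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial_index": [t.index for t in self.trials],
                "harmful_money": [t.harmful.money for t in self.trials],
                "harmful_shocks": [t.harmful.shocks for t in self.trials],
                "helpful_money": [t.helpful.money for t in self.trials],
                "helpful_shocks": [t.helpful.shocks for t in self.trials],
            }
        )

    @classmethod
    def from_frame(cls, frame) -> "TrialSet":
        trials = [
            Trial(
                index=int(row.trial_index),
                harmful=TrialOption(float(row.harmful_money), int(row.harmful_shocks)),
                helpful=TrialOption(float(row.helpful_money), int(row.helpful_shocks)),
            )
            for row in frame.itertuples()
        ]
        return cls(trials=trials)


def harmful_choice_prob(kappa, beta: float, dm, ds):
    """Vectorised logistic choice rule on rescaled attribute differences.

    Accepts scalars or arrays for ``kappa``, ``dm`` and ``ds`` (numpy
    broadcasting applies). Returns P(choose harmful).
    """
    dv = (1.0 - np.asarray(kappa)) * dm - np.asarray(kappa) * ds
    return expit(beta * dv)


def choice_prob(
    agent: AgentSpec,
    trial: Trial,
    money_scale: float = 1.0,
    shock_scale: float = 1.0,
) -> float:
    """Probability that ``agent`` picks the harmful option on ``trial``."""
    if money_scale <= 0 or shock_scale <= 0:
        raise ValueError("rescaling constants must be positive")
    dm = trial.delta_money / money_scale
    ds = trial.delta_shocks / shock_scale
    return float(harmful_choice_prob(agent.kappa, agent.beta, dm, ds))


def generate_trial_set(
    n_trials: int,
    money_range: tuple[float, float] = (0.5, 20.0),
    shock_range: tuple[int, int] = (1, 20),
    variant_seed: int = 0,
) -> TrialSet:
    """Build a reproducible trial sequence spanning the given difference ranges.

    ``money_range`` and ``shock_range`` bound the money and shock *differences*
    between the harmful and helpful options. Differences are stratified across
    the range (then shuffled) so every variant exercises both easy and hard
    trade-offs for both agents. Deterministic given ``variant_seed``.
    """
    if n_trials < 1:
        raise TaskConfigError(f"n_trials must be >= 1, got {n_trials}")
    m_lo, m_hi = float(money_range[0]), float(money_range[1])
    s_lo, s_hi = int(shock_range[0]), int(shock_range[1])
    if not (0 < m_lo < m_hi):
        raise TaskConfigError(f"money_range must satisfy 0 < lo < hi, got {money_range}")
    if not (1 <= s_lo <= s_hi):
        raise TaskConfigError(f"shock_range must satisfy 1 <= lo <= hi, got {shock_range}")

    rng = np.random.default_rng(variant_seed)
    # Stratified draws: one difference per equal-width bin, then shuffled.
    u = (np.arange(n_trials) + rng.uniform(0.0, 1.0, n_trials)) / n_trials
    dm = m_lo + (m_hi - m_lo) * rng.permutation(u)
    v = (np.arange(n_trials) + rng.uniform(0.0, 1.0, n_trials)) / n_trials
    ds = s_lo + np.floor((s_hi - s_lo + 1) * rng.permutation(v) * 0.999999).astype(int)

    base_money = rng.uniform(0.0, m_hi, n_trials)
    base_shocks = rng.integers(0, 4, n_trials)
    trials = [
        Trial(
            index=i + 1,
            harmful=TrialOption(float(base_money[i] + dm[i]), int(base_shocks[i] + ds[i])),
            helpful=TrialOption(float(base_money[i]), int(base_shocks[i])),
        )
        for i in range(n_trials)
    ]
    return TrialSet(trials=trials)


def simulate_agent(agent: AgentSpec, trial_set: TrialSet, seed: int) -> list[AgentChoice]:
    """Sample the agent's choice on every trial, independently across trials."""
    rng = np.random.default_rng(seed)
    p = harmful_choice_prob(agent.kappa, agent.beta, trial_set.dm, trial_set.ds)
    draws = rng.random(len(trial_set)) < p
    return [
        AgentChoice(trial_index=t.index, chose_harmful=bool(d))
        for t, d in zip(trial_set.trials, draws)
    ]


def default_agents(
    kappa_good: float = 0.7, kappa_bad: float = 0.3, beta: float = 6.0
) -> dict[str, AgentSpec]:
    """The canonical good/bad agent pair. kappa(good) > kappa(bad) is enforced."""
    if not kappa_good > kappa_bad:
        raise TaskConfigError("kappa(good) must exceed kappa(bad)")
    return {
        BAD: AgentSpec(label=BAD, kappa=kappa_bad, beta=beta),
        GOOD: AgentSpec(label=GOOD, kappa=kappa_good, beta=beta),
    }
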