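"""Fixed-learning-rate comparison models.

Two alternatives to the dynamic Bayesian learner, used in model comparison:

* single-rate — a point estimate kappa-hat updated by a constant fraction of
  the prediction error on every trial;
* valenced — the same, but with separate rates for harmful observations
  (``alpha_neg``) and helpful observations (``alpha_pos``).

Both models track a point estimate rather than a distribution, so their
traces carry NaN in the sigma columns. Setting alpha_pos = alpha_neg makes
the valenced model reproduce the single-rate model exactly (the models nest).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .learner import TrialTrace
from .task import AgentChoice, TrialSet, harmful_choice_prob


@dataclass(frozen=True)
class FixedLRParams:
    """Parameters of the fixed-rate learners.

    For the single-rate model set ``alpha_fixed``; for the valenced model set
    ``alpha_neg`` (rate after harmful observations) and ``alpha_pos`` (after
    helpful observations).
    """

    kappa_hat0: float
    beta: float
    alpha_fixed: float | None = None
    alpha_neg: float | None = None
    alpha_pos: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa_hat0 <= 1.0:
            raise ValueError(f"kappa_hat0 must lie in [0, 1], got {self.kappa_hat0}")
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        for name in ("alpha_fixed", "alpha_neg", "alpha_pos"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


def run_fixed_lr(
    params: FixedLRParams,
    trial_set: TrialSet,
    choices: list[AgentChoice],
    valenced: bool = False,
) -> list[TrialTrace]:
    """Run a fixed-rate learner over a trial sequence.

    Each trial: predict P(harmful) from the current kappa-hat via the logistic
    choice rule; compute the prediction error delta = observed - p_pred; move
    kappa-hat *against* delta (harmful evidence lowers the inferred harm
    aversion) by the applicable rate, clipping to [0, 1].
    """
    if len(choices) != len(trial_set):
        raise ValueError(f"{len(choices)} choices provided for {len(trial_set)} trials")
    if valenced:
        if params.alpha_neg is None or params.alpha_pos is None:
            raise ValueError("valenced model requires alpha_neg and alpha_pos")
    elif params.alpha_fixed is None:
        raise ValueError("single-rate model requires alpha_fixed")

    ms, ss = trial_set.money_scale, trial_set.shock_scale
    kappa_hat = params.kappa_hat0
    traces: list[TrialTrace] = []
    for trial, choice in zip(trial_set.trials, choices):
        observed = bool(choice.chose_harmful if isinstance(choice, AgentChoice) else choice)
        dm = trial.delta_money / ms
        ds = trial.delta_shocks / ss
        p_pred = float(harmful_choice_prob(kappa_hat, params.beta, dm, ds))
        delta = float(observed) - p_pred
        if valenced:
            rate = params.alpha_neg if observed else params.alpha_pos
        else:
            rate = params.alpha_fixed
        new_kappa = min(1.0, max(0.0, kappa_hat - rate * delta))
        traces.append(
            TrialTrace(
                trial_index=trial.index,
                p_pred=p_pred,
                observed=observed,
                delta=delta,
                mu_pre=kappa_hat,
                sigma_pre=math.nan,
                mu_post=new_kappa,
                sigma_post=math.nan,
                alpha=rate,
            )
        )
        kappa_hat = new_kappa
    return traces
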