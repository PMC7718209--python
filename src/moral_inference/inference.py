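"""Per-participant likelihood and maximum-likelihood fitting for all three models.

A participant's data consist of one *block* per agent: the trial sequence,
the agent's observed choices, and the participant's binary predictions. All
three models produce a trialwise predicted probability ``p_t`` that the agent
takes the harmful option; the participant is assumed to predict "harmful"
with probability

    q_t = lapse + (1 - 2 * lapse) * p_t

where a small fixed symmetric lapse keeps the Bernoulli log likelihood finite. Fits are
bounded multi-start local optimisations of the negative log likelihood; model
evidence is approximated by -BIC/2 for downstream random-effects selection.

Default fit layout (two agents, joint fit):

* dynamic   — mu0 and sigma0 per agent + shared beta (5 free parameters);
* fixed     — shared kappa_hat0, one rate alpha, beta (3);
* valenced  — shared kappa_hat0, alpha_neg, alpha_pos, beta (4).

The leak lam of the dynamic learner is fixed, not fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .comparison_models import FixedLRParams, run_fixed_lr
from .learner import DEFAULT_GRID_SIZE, gaussian_mass
from .task import TrialSet

MODELS = ("dynamic", "fixed", "valenced")

DEFAULT_LAPSE = 0.02
DEFAULT_LAM = 0.1
DEFAULT_RESTARTS = 10

#: Default box bounds for each named parameter.
DEFAULT_BOUNDS = {
    "mu0": (0.01, 0.99),
    "sigma0": (0.01, 1.0),
    "kappa_hat0": (0.01, 0.99),
    "rate": (0.0, 1.0),
    "beta": (0.1, 20.0),
}


class FitError(RuntimeError):
    pass


@dataclass
class AgentBlock:
    """One agent's worth of data for a participant."""

    trial_set: TrialSet
    agent_choices: np.ndarray  # bool, agent chose harmful
    predictions: np.ndarray  # bool, participant predicted harmful

    def __post_init__(self) -> None:
        self.agent_choices = np.asarray(self.agent_choices, dtype=bool)
        self.predictions = np.asarray(self.predictions, dtype=bool)
        n = len(self.trial_set)
        if len(self.agent_choices) != n or len(self.predictions) != n:
            raise ValueError("choices/predictions must align with the trial list")


@dataclass
class ParticipantData:
    """Behavioral data plus covariates for one participant."""

    participant_id: str
    group: str
    blocks: dict[str, AgentBlock]
    ratings: pd.DataFrame | None = None
    covariates: dict = field(default_factory=dict)
    variant_seed: int = 0
    generative_params: dict | None = None

    @property
    def n_obs(self) -> int:
        return sum(len(b.trial_set) for b in self.blocks.values())

    @property
    def labels(self) -> list[str]:
        return sorted(self.blocks)


@dataclass
class FitResult:
    """Best fit of one model to one participant."""

    participant_id: str
    model_id: str
    params: dict[str, float]
    nll: float
    n_params: int
    n_obs: int
    n_restarts: int
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.nll + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return 2.0 * self.nll + self.n_params * math.log(self.n_obs)

    @property
    def log_evidence(self) -> float:
        return -0.5 * self.bic


def bernoulli_nll(p_pred: np.ndarray, predictions: np.ndarray, lapse: float) -> float:
    """Negative log likelihood of binary predictions under lapse-mixed probabilities.

    q = lapse + (1 - 2*lapse) * p: the participant lapses toward either
    response with probability ``lapse`` each, so lapse = 0.5 is pure chance
    and any lapse > 0 keeps the likelihood finite.
    """
    if not 0.0 <= lapse <= 0.5:
        raise ValueError(f"lapse must lie in [0, 0.5], got {lapse}")
    p_pred = np.asarray(p_pred, dtype=float)
    y = np.asarray(predictions, dtype=bool)
    q = lapse + (1.0 - 2.0 * lapse) * p_pred
    q_obs = np.where(y, q, 1.0 - q)
    with np.errstate(divide="ignore"):
        return float(-np.log(q_obs).sum())


def _block_dv(block: AgentBlock, grid: np.ndarray) -> np.ndarray:
    """Decision-value matrix (trials x grid), precomputed once per fit."""
    dm = block.trial_set.dm[:, None]
    ds = block.trial_set.ds[:, None]
    return (1.0 - grid[None, :]) * dm - grid[None, :] * ds


def _dynamic_probs(
    theta: np.ndarray,
    prepped: list[tuple[np.ndarray, np.ndarray]],
    grid: np.ndarray,
    lam: float,
    leak_to_prior: bool = False,
) -> np.ndarray:
    """Trialwise predicted probabilities of the dynamic learner, all blocks concatenated.

    theta = (mu0_1, sigma0_1, ..., mu0_B, sigma0_B, beta), blocks in sorted
    label order. The sequential loop mirrors learner.run_learner exactly,
    including the choice of leak target (uniform or the block's own prior).
    """
    beta = theta[-1]
    uniform = 1.0 / len(grid)
    out: list[float] = []
    for j, (dv, obs) in enumerate(prepped):
        mass = gaussian_mass(grid, theta[2 * j], theta[2 * j + 1])
        target = mass.copy() if leak_to_prior else uniform
        like = expit(beta * dv)  # trials x grid
        for t in range(dv.shape[0]):
            row = like[t]
            out.append(float(mass @ row))
            lik = row if obs[t] else 1.0 - row
            mass = mass * lik
            mass = mass / mass.sum()
            if lam > 0.0:
                mass = (1.0 - lam) * mass + lam * target
    return np.array(out)


def _fixed_probs(theta: np.ndarray, blocks: list[AgentBlock], valenced: bool) -> np.ndarray:
    """Trialwise predicted probabilities of the fixed-rate learners."""
    if valenced:
        kappa0, a_neg, a_pos, beta = theta
        params = FixedLRParams(kappa_hat0=kappa0, beta=beta, alpha_neg=a_neg, alpha_pos=a_pos)
    else:
        kappa0, a_fix, beta = theta
        params = FixedLRParams(kappa_hat0=kappa0, beta=beta, alpha_fixed=a_fix)
    out: list[float] = []
    for block in blocks:
        traces = run_fixed_lr(params, block.trial_set, list(block.agent_choices), valenced)
        out.extend(t.p_pred for t in traces)
    return np.array(out)


def _theta_layout(
    model_id: str, labels: list[str], shared_prior: bool = False
) -> tuple[list[str], list[tuple[float, float]]]:
    b = DEFAULT_BOUNDS
    if model_id == "dynamic":
        if shared_prior:
            return ["mu0", "sigma0", "beta"], [b["mu0"], b["sigma0"], b["beta"]]
        names: list[str] = []
        bounds: list[tuple[float, float]] = []
        for lab in labels:
            names += [f"mu0_{lab}", f"sigma0_{lab}"]
            bounds += [b["mu0"], b["sigma0"]]
        return names + ["beta"], bounds + [b["beta"]]
    if model_id == "fixed":
        return ["kappa_hat0", "alpha_fixed", "beta"], [b["kappa_hat0"], b["rate"], b["beta"]]
    if model_id == "valenced":
        return (
            ["kappa_hat0", "alpha_neg", "alpha_pos", "beta"],
            [b["kappa_hat0"], b["rate"], b["rate"], b["beta"]],
        )
    raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODELS}")


def _theta_from_params(model_id: str, params: dict, labels: list[str]) -> np.ndarray:
    names, _ = _theta_layout(model_id, labels)
    theta = []
    for name in names:
        if name in params:
            theta.append(params[name])
        elif "_" in name and name.split("_", 1)[0] in params:
            # allow shared mu0/sigma0 across agents
            theta.append(params[name.split("_", 1)[0]])
        else:
            raise KeyError(f"missing parameter {name!r} for model {model_id!r}")
    return np.array(theta, dtype=float)


def _expand_shared(theta: np.ndarray, n_blocks: int) -> np.ndarray:
    """(mu0, sigma0, beta) -> per-block-layout theta for _dynamic_probs."""
    return np.concatenate([np.tile(theta[:2], n_blocks), theta[2:]])


def predicted_probs(
    model_id: str,
    params: dict,
    data: ParticipantData,
    grid_size: int = DEFAULT_GRID_SIZE,
    lam: float = DEFAULT_LAM,
    leak_to_prior: bool = False,
) -> np.ndarray:
    """Trialwise model probabilities of a harmful choice, blocks in sorted label order."""
    labels = data.labels
    blocks = [data.blocks[lab] for lab in labels]
    theta = _theta_from_params(model_id, params, labels)
    if model_id == "dynamic":
        grid = np.linspace(0.0, 1.0, grid_size)
        prepped = [(_block_dv(b, grid), b.agent_choices) for b in blocks]
        return _dynamic_probs(theta, prepped, grid, lam, leak_to_prior)
    return _fixed_probs(theta, blocks, model_id == "valenced")


def prediction_nll(
    model_id: str,
    params: dict,
    data: ParticipantData,
    lapse: float = DEFAULT_LAPSE,
    grid_size: int = DEFAULT_GRID_SIZE,
    lam: float = DEFAULT_LAM,
    leak_to_prior: bool = False,
) -> float:
    """Negative log likelihood of the participant's predictions under one model."""
    p = predicted_probs(
        model_id, params, data, grid_size=grid_size, lam=lam, leak_to_prior=leak_to_prior
    )
    preds = np.concatenate([data.blocks[lab].predictions for lab in data.labels])
    return bernoulli_nll(p, preds, lapse)


_DEFAULT_START = {
    "mu0": 0.5,
    "sigma0": 0.25,
    "kappa_hat0": 0.5,
    "alpha_fixed": 0.3,
    "alpha_neg": 0.3,
    "alpha_pos": 0.3,
    "beta": 5.0,
}


def fit_participant(
    model_id: str,
    data: ParticipantData,
    n_restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    bounds: dict[str, tuple[float, float]] | None = None,
    grid_size: int = DEFAULT_GRID_SIZE,
    lam: float = DEFAULT_LAM,
    lapse: float = DEFAULT_LAPSE,
    shared_prior: bool = False,
    leak_to_prior: bool = False,
) -> FitResult:
    """Multi-start bounded maximum-likelihood fit of one model to one participant.

    The first start is a fixed mid-range point; the remaining ``n_restarts-1``
    starts are drawn uniformly within the bounds from a generator seeded with
    ``seed``, so the fit is deterministic given (data, seed). With
    ``shared_prior`` the dynamic model fits one (mu0, sigma0) pair for all
    agents instead of one per agent.
    """
    labels = data.labels
    names, box = _theta_layout(model_id, labels, shared_prior)
    if bounds:
        merged = dict(DEFAULT_BOUNDS)
        merged.update(bounds)
        box = []
        for name in names:
            key = name
            if key not in merged:
                key = name.split("_", 1)[0] if "_" in name else name
            if key not in merged and name.startswith("alpha"):
                key = "rate"
            box.append(merged[key])

    labels_blocks = [data.blocks[lab] for lab in labels]
    preds = np.concatenate([b.predictions for b in labels_blocks])

    if model_id == "dynamic":
        grid = np.linspace(0.0, 1.0, grid_size)
        prepped = [(_block_dv(b, grid), b.agent_choices) for b in labels_blocks]
        n_blocks = len(labels_blocks)

        def objective(theta: np.ndarray) -> float:
            full = _expand_shared(theta, n_blocks) if shared_prior else theta
            return bernoulli_nll(
                _dynamic_probs(full, prepped, grid, lam, leak_to_prior), preds, lapse
            )

    else:

        def objective(theta: np.ndarray) -> float:
            return bernoulli_nll(
                _fixed_probs(theta, labels_blocks, model_id == "valenced"), preds, lapse
            )

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    starts = [
        np.array([_DEFAULT_START.get(n, _DEFAULT_START.get(n.split("_", 1)[0], 0.5)) for n in names])
    ]
    starts[0] = np.clip(starts[0], lo, hi)
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.uniform(lo, hi))

    best = None
    any_success = False
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=box)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"all {n_restarts} restarts failed for {model_id} fit")

    params = {name: float(v) for name, v in zip(names, best.x)}
    n_free = int(sum(1 for (b_lo, b_hi) in box if b_hi > b_lo))
    return FitResult(
        participant_id=data.participant_id,
        model_id=model_id,
        params=params,
        nll=float(best.fun),
        n_params=n_free,
        n_obs=data.n_obs,
        n_restarts=n_restarts,
        converged=any_success,
    )


def evidence_matrix(fits: dict[str, dict[str, FitResult]], models=MODELS) -> pd.DataFrame:
    """Participants x models matrix of approximate log evidences (-BIC/2).

    ``fits`` maps participant_id -> model_id -> FitResult; every participant
    must have a fit for every requested model. Row order follows insertion
    order of ``fits`` (stable).
    """
    rows = {}
    for pid, per_model in fits.items():
        missing = [m for m in models if m not in per_model]
        if missing:
            raise ValueError(f"participant {pid!r} is missing fits for {missing}")
        rows[pid] = [per_model[m].log_evidence for m in models]
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(models))
    frame.index.name = "participant_id"
    return frame
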