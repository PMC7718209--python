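"""Synthetic cohort generator: three groups with distinct belief-updating profiles.

Produces complete datasets with the structure the analysis pipeline assumes —
an untreated borderline personality disorder (BPD) group, a matched non-BPD
control group, and a group treated in a democratic therapeutic community
(DTC) — with no real data required. Each group is described by a
:class:`GroupProfile` of generative learner parameters:

* controls hold a wider prior over the bad agent's harm aversion than the
  good agent's (sigma0 bad > good), the asymmetry that yields faster updating
  and more uncertain impressions of bad agents;
* the untreated BPD profile reverses that asymmetry (tight beliefs about the
  bad agent, looser about the good one) and is more pessimistic a priori
  (lower prior mean over kappa);
* the DTC profile matches BPD's pessimism but restores the wide bad-agent
  prior.

Participants' trialwise predictions are sampled from their own generative
learner (probability matching), impressions/certainty are rated every third
trial plus once before any observation, and controls are matched five-to-one
to BPD patients on task variant (same trial and agent-choice sequences).
Covariates (screening score, symptom severity, medication flag) are drawn per
group. Everything is reproducible from (variant_seed, participant_seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .inference import AgentBlock, ParticipantData
from .learner import BeliefState, LearnerParams, run_learner
from .task import BAD, GOOD, TrialSet, default_agents, generate_trial_set, simulate_agent

GROUP_BPD = "BPD"
GROUP_CONTROL = "non-BPD"
GROUP_DTC = "DTC"
GROUPS = (GROUP_BPD, GROUP_CONTROL, GROUP_DTC)

#: Maximal SD of a distribution supported on [0, 1]; scales model spread to [0, 1].
SIGMA_MAX = 0.5
#: Screening cutoff: scores strictly greater are excluded from the control group.
MSI_CUTOFF = 6
RATING_EVERY = 3


@dataclass(frozen=True)
class TaskSettings:
    """Task-level generation settings shared by all participants."""

    n_trials: int = 50
    kappa_good: float = 0.7
    kappa_bad: float = 0.3
    agent_beta: float = 6.0
    money_range: tuple[float, float] = (0.5, 20.0)
    shock_range: tuple[int, int] = (1, 20)


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameter distributions for one participant group."""

    name: str
    n: int
    prior_mean: float  # mean of mu0 for both agents (pre-task expectation)
    sigma0_mean: dict[str, float]  # per agent-label prior spread means
    param_sd: float = 0.05  # between-participant SD of mu0 and sigma0 draws
    beta: float = 3.0  # participants' assumed agent consistency
    lam: float = 0.1
    leak_to_prior: bool = True  # forgetting pulls back toward the prior impression
    lapse: float = 0.02
    rating_noise_sd: float = 5.0  # impression points; certainty noise = /100
    msi_mean: float | None = None  # Poisson mean of screening scores (controls)
    severity_mean: float | None = None
    severity_sd: float | None = None
    medication_p: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group size must be >= 1, got {self.n}")
        if not 0.0 <= self.prior_mean <= 1.0:
            raise ValueError("prior_mean must lie in [0, 1]")
        if self.param_sd < 0 or self.rating_noise_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if not 0.0 <= self.medication_p <= 1.0:
            raise ValueError("medication_p must lie in [0, 1]")


def default_profiles() -> dict[str, GroupProfile]:
    """The three study groups with their generative parameter profiles.

    Group sizes are the final analysed samples (20 untreated BPD, 106 matched
    controls, 23 DTC-treated). Severity scores follow the reported group
    means/SDs on the Borderline Evaluation of Severity over Time scale, and
    medication prevalence the reported 9/20 and 11/23 rates.
    """
    return {
        GROUP_BPD: GroupProfile(
            name=GROUP_BPD,
            n=20,
            prior_mean=0.40,
            sigma0_mean={BAD: 0.18, GOOD: 0.22},
            severity_mean=41.444,
            severity_sd=8.832,
            medication_p=9 / 20,
        ),
        GROUP_CONTROL: GroupProfile(
            name=GROUP_CONTROL,
            n=106,
            prior_mean=0.50,
            sigma0_mean={BAD: 0.33, GOOD: 0.12},
            msi_mean=2.0,
        ),
        GROUP_DTC: GroupProfile(
            name=GROUP_DTC,
            n=23,
            prior_mean=0.40,
            sigma0_mean={BAD: 0.28, GOOD: 0.18},
            severity_mean=26.867,
            severity_sd=9.381,
            medication_p=11 / 23,
        ),
    }


def _rate_from_moments(
    mu: float, sd: float, noise_sd: float, rng: np.random.Generator
) -> tuple[float, float]:
    impression = 100.0 * mu + rng.normal(0.0, noise_sd) if noise_sd > 0 else 100.0 * mu
    certainty = 1.0 - sd / SIGMA_MAX
    if noise_sd > 0:
        certainty += rng.normal(0.0, noise_sd / 100.0)
    return float(np.clip(impression, 0.0, 100.0)), float(np.clip(certainty, 0.0, 1.0))


def rate_beliefs(
    belief: BeliefState, noise_sd: float, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Map a belief to an impression (0-100) and a certainty (0-1) rating.

    Impression is the belief mean on the nasty->nice scale; certainty is one
    minus the belief spread relative to the widest possible spread on [0, 1]
    (SIGMA_MAX = 0.5). Gaussian noise of SD ``noise_sd`` (impression points)
    is added to the impression, and ``noise_sd / 100`` to the certainty; both
    are clipped to their scales.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _rate_from_moments(belief.mean, belief.sd, noise_sd, rng)


def simulate_participant(
    profile: GroupProfile,
    variant_seed: int,
    participant_seed: int,
    task: TaskSettings = TaskSettings(),
    participant_id: str = "",
    grid_size: int = 101,
) -> ParticipantData:
    """Simulate one participant's full session.

    The task variant (trial sequences and agent choice sequences for both
    agents) is a pure function of ``variant_seed``, so matched participants
    sharing a variant_seed observe identical evidence. Everything
    participant-specific (generative parameters, prediction sampling, rating
    noise, covariates) derives from ``participant_seed``.
    """
    rng = np.random.default_rng(participant_seed)
    agents = default_agents(task.kappa_good, task.kappa_bad, task.agent_beta)
    labels = sorted(agents)

    # Participant-level generative parameters, one (mu0, sigma0) pair per agent.
    gen: dict[str, float] = {"beta": profile.beta, "lam": profile.lam}
    for lab in labels:
        gen[f"mu0_{lab}"] = float(
            np.clip(rng.normal(profile.prior_mean, profile.param_sd), 0.05, 0.95)
        )
        gen[f"sigma0_{lab}"] = float(
            np.clip(rng.normal(profile.sigma0_mean[lab], profile.param_sd), 0.03, 0.6)
        )

    blocks: dict[str, AgentBlock] = {}
    rating_rows: list[dict] = []
    for i, lab in enumerate(labels):
        trial_set = generate_trial_set(
            task.n_trials, task.money_range, task.shock_range,
            variant_seed=int(variant_seed) * 4 + i,
        )
        choices = simulate_agent(agents[lab], trial_set, seed=int(variant_seed) * 4 + 2 + i)
        params = LearnerParams(
            mu0=gen[f"mu0_{lab}"], sigma0=gen[f"sigma0_{lab}"],
            beta=profile.beta, lam=profile.lam,
        )
        traces, _ = run_learner(
            params, trial_set, choices, grid_size=grid_size,
            leak_to_prior=profile.leak_to_prior,
        )

        # Probability-matched predictions with a small symmetric lapse.
        q = profile.lapse + (1.0 - 2.0 * profile.lapse) * np.array([t.p_pred for t in traces])
        predictions = rng.random(len(q)) < q
        blocks[lab] = AgentBlock(
            trial_set=trial_set,
            agent_choices=np.array([c.chose_harmful for c in choices]),
            predictions=predictions,
        )

        # Pre-task rating from the prior, then one rating every third trial.
        imp, cert = _rate_from_moments(
            traces[0].mu_pre, traces[0].sigma_pre, profile.rating_noise_sd, rng
        )
        rating_rows.append(
            {"agent_label": lab, "trial_index": 0, "impression": imp, "certainty": cert}
        )
        for t in traces:
            if t.trial_index % RATING_EVERY == 0:
                imp, cert = _rate_from_moments(
                    t.mu_post, t.sigma_post, profile.rating_noise_sd, rng
                )
                rating_rows.append(
                    {
                        "agent_label": lab,
                        "trial_index": t.trial_index,
                        "impression": imp,
                        "certainty": cert,
                    }
                )

    covariates = {
        "msi": (
            float(min(rng.poisson(profile.msi_mean), MSI_CUTOFF))
            if profile.msi_mean is not None
            else float("nan")
        ),
        "severity": (
            float(np.clip(rng.normal(profile.severity_mean, profile.severity_sd), 12.0, 72.0))
            if profile.severity_mean is not None
            else float("nan")
        ),
        "medication": int(rng.random() < profile.medication_p),
    }

    return ParticipantData(
        participant_id=participant_id or f"{profile.name}-x",
        group=profile.name,
        blocks=blocks,
        ratings=pd.DataFrame(rating_rows),
        covariates=covariates,
        variant_seed=int(variant_seed),
        generative_params=gen,
    )


@dataclass
class CohortDataset:
    """Long-format behavioral tables plus the participant covariate table."""

    participants: pd.DataFrame
    behavior: pd.DataFrame
    ratings: pd.DataFrame

    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants["participant_id"])

    def __len__(self) -> int:
        return len(self.participants)

    def groups(self) -> dict[str, str]:
        return dict(zip(self.participants["participant_id"], self.participants["group"]))

    def participant_data(self, participant_id: str) -> ParticipantData:
        row = self.participants[self.participants["participant_id"] == participant_id]
        if row.empty:
            raise KeyError(f"unknown participant {participant_id!r}")
        row = row.iloc[0]
        beh = self.behavior[self.behavior["participant_id"] == participant_id]
        blocks = {}
        for lab, sub in beh.groupby("agent_label"):
            sub = sub.sort_values("trial_index")
            blocks[str(lab)] = AgentBlock(
                trial_set=TrialSet.from_frame(sub),
                agent_choices=sub["agent_chose_harmful"].to_numpy(dtype=bool),
                predictions=sub["predicted_harmful"].to_numpy(dtype=bool),
            )
        ratings = self.ratings[self.ratings["participant_id"] == participant_id].drop(
            columns="participant_id"
        )
        return ParticipantData(
            participant_id=participant_id,
            group=str(row["group"]),
            blocks=blocks,
            ratings=ratings.reset_index(drop=True),
            covariates={
                "msi": float(row["msi"]),
                "severity": float(row["severity"]),
                "medication": int(row["medication"]),
            },
            variant_seed=int(row["variant_seed"]),
        )

    def iter_participants(self):
        for pid in self.participant_ids:
            yield self.participant_data(pid)

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        # %.17g guarantees binary round-trip of doubles through the CSV
        self.participants.to_csv(path / "participants.csv", index=False, float_format="%.17g")
        self.behavior.to_csv(path / "behavior.csv", index=False, float_format="%.17g")
        self.ratings.to_csv(path / "ratings.csv", index=False, float_format="%.17g")

    @classmethod
    def from_dir(cls, path) -> "CohortDataset":
        path = Path(path)
        for name in ("participants.csv", "behavior.csv", "ratings.csv"):
            if not (path / name).exists():
                raise FileNotFoundError(f"cohort file missing: {path / name}")
        read = lambda name: pd.read_csv(path / name, float_precision="round_trip")
        return cls(
            participants=read("participants.csv"),
            behavior=read("behavior.csv"),
            ratings=read("ratings.csv"),
        )


def _variant_seeds(
    profiles: dict[str, GroupProfile], rng: np.random.Generator, matching: bool
) -> dict[str, np.ndarray]:
    """Assign variant seeds; with matching, 5 controls share each BPD patient's seed."""

    def fresh(n: int) -> np.ndarray:
        return rng.integers(0, 2**28, size=n)

    seeds: dict[str, np.ndarray] = {}
    bpd = profiles.get(GROUP_BPD)
    control = profiles.get(GROUP_CONTROL)
    for name, prof in profiles.items():
        seeds[name] = fresh(prof.n)
    if matching and bpd is not None and control is not None:
        matched = np.repeat(seeds[GROUP_BPD], 5)
        n_matched = min(len(matched), control.n)
        seeds[GROUP_CONTROL][:n_matched] = matched[:n_matched]
    return seeds


def generate_cohort(
    profiles: dict[str, GroupProfile] | None = None,
    seed: int = 0,
    task: TaskSettings = TaskSettings(),
    matching: bool = True,
    grid_size: int = 101,
) -> CohortDataset:
    """Generate a full synthetic cohort as long-format tables.

    Deterministic given ``seed``. With ``matching`` enabled each untreated-BPD
    participant's task variant is reused by five consecutive controls.
    """
    profiles = profiles if profiles is not None else default_profiles()
    rng = np.random.default_rng(seed)
    seeds = _variant_seeds(profiles, rng, matching)

    part_rows, beh_frames, rating_frames = [], [], []
    for name, prof in profiles.items():
        for i in range(prof.n):
            pid = f"{name}-{i:03d}"
            pdata = simulate_participant(
                prof,
                variant_seed=int(seeds[name][i]),
                participant_seed=int(rng.integers(2**31 - 1)),
                task=task,
                participant_id=pid,
                grid_size=grid_size,
            )
            part_rows.append(
                {
                    "participant_id": pid,
                    "group": name,
                    "variant_seed": pdata.variant_seed,
                    **pdata.covariates,
                    **{f"true_{k}": v for k, v in pdata.generative_params.items()},
                }
            )
            for lab in pdata.labels:
                block = pdata.blocks[lab]
                frame = block.trial_set.to_frame()
                frame.insert(0, "participant_id", pid)
                frame.insert(1, "agent_label", lab)
                frame["agent_chose_harmful"] = block.agent_choices.astype(int)
                frame["predicted_harmful"] = block.predictions.astype(int)
                beh_frames.append(frame)
            ratings = pdata.ratings.copy()
            ratings.insert(0, "participant_id", pid)
            rating_frames.append(ratings)

    return CohortDataset(
        participants=pd.DataFrame(part_rows),
        behavior=pd.concat(beh_frames, ignore_index=True),
        ratings=pd.concat(rating_frames, ignore_index=True),
    )


def msi_screen(
    cohort: CohortDataset, scores: dict[str, float] | pd.Series | None = None
) -> tuple[CohortDataset, list[str]]:
    """Apply the control-group screening rule: drop non-BPD participants with score > 6.

    ``scores`` optionally overrides the cohort's recorded screening scores
    (participant_id -> score). Patient groups are never removed. Returns the
    filtered cohort and the list of removed participant ids.
    """
    parts = cohort.participants
    score_map = dict(zip(parts["participant_id"], parts["msi"]))
    if scores is not None:
        score_map.update(dict(scores))

    removed: list[str] = []
    for pid, group in zip(parts["participant_id"], parts["group"]):
        if group != GROUP_CONTROL:
            continue
        s = score_map.get(pid, float("nan"))
        if not np.isfinite(s):
            raise ValueError(f"missing screening score for control participant {pid!r}")
        if s > MSI_CUTOFF:
            removed.append(pid)

    keep = ~parts["participant_id"].isin(removed)
    filtered = CohortDataset(
        participants=parts[keep].reset_index(drop=True),
        behavior=cohort.behavior[~cohort.behavior["participant_id"].isin(removed)].reset_index(
            drop=True
        ),
        ratings=cohort.ratings[~cohort.ratings["participant_id"].isin(removed)].reset_index(
            drop=True
        ),
    )
    return filtered, removed
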