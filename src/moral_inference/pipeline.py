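"""End-to-end orchestration: cohort -> fits -> model selection -> group statistics.

Thin functional layer gluing the modules together so that the command-line
interface, the test suite and the reproduction script all run the identical
code path. The trialwise measures entering the group analysis come from the
*fitted* dynamic learner replayed over each participant's observed trial
sequence: the effective learning rate alpha_t and the model-side belief
uncertainty sigma_t, alongside the participant's own impression and
(reverse-scored) certainty ratings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bms as bms_mod
from . import stats as stats_mod
from .inference import MODELS, FitResult, ParticipantData, evidence_matrix, fit_participant
from .learner import LearnerParams, run_learner
from .synthetic_cohort import (
    GROUP_BPD,
    GROUP_CONTROL,
    GROUP_DTC,
    CohortDataset,
    default_profiles,
    generate_cohort,
)


def fit_cohort(
    participants: list[ParticipantData],
    models: tuple[str, ...] = MODELS,
    seed: int = 0,
    n_restarts: int = 3,
    grid_size: int = 61,
    lam: float = 0.1,
    lapse: float = 0.02,
    bounds: dict | None = None,
    leak_to_prior: bool = False,
    progress: bool = False,
) -> dict[str, dict[str, FitResult]]:
    """Fit the requested models to every participant; deterministic given seed."""
    fits: dict[str, dict[str, FitResult]] = {}
    for i, pdata in enumerate(participants):
        per_model: dict[str, FitResult] = {}
        for j, model in enumerate(models):
            per_model[model] = fit_participant(
                model,
                pdata,
                n_restarts=n_restarts,
                seed=(seed * 1_000_003 + i * 31 + j) % (2**31 - 1),
                grid_size=grid_size,
                lam=lam,
                lapse=lapse,
                bounds=bounds,
                leak_to_prior=(leak_to_prior and model == "dynamic"),
            )
        fits[pdata.participant_id] = per_model
        if progress and (i + 1) % 10 == 0:
            print(f"  fitted {i + 1}/{len(participants)} participants")
    return fits


def dynamic_trace_table(
    participants: list[ParticipantData],
    fits: dict[str, dict[str, FitResult]],
    grid_size: int = 101,
    lam: float = 0.1,
    leak_to_prior: bool = False,
) -> pd.DataFrame:
    """Replay each participant's fitted dynamic learner to get trialwise traces."""
    rows = []
    for pdata in participants:
        fit = fits[pdata.participant_id]["dynamic"]
        for lab in pdata.labels:
            block = pdata.blocks[lab]
            params = LearnerParams(
                mu0=fit.params[f"mu0_{lab}"],
                sigma0=fit.params[f"sigma0_{lab}"],
                beta=fit.params["beta"],
                lam=lam,
            )
            traces, _ = run_learner(
                params, block.trial_set, list(block.agent_choices),
                grid_size=grid_size, leak_to_prior=leak_to_prior,
            )
            for t in traces:
                rows.append(
                    {
                        "participant_id": pdata.participant_id,
                        "group": pdata.group,
                        "agent": lab,
                        "trial_index": t.trial_index,
                        "alpha": t.alpha,
                        "sigma_pre": t.sigma_pre,
                    }
                )
    return pd.DataFrame(rows)


def analysis_table(
    cohort: CohortDataset,
    trace_df: pd.DataFrame | None = None,
    aggregate: bool = False,
) -> pd.DataFrame:
    """Build the long analysis table of all measures.

    Measures: ``learning_rate`` (standardized fitted alpha_t),
    ``model_uncertainty`` (standardized fitted sigma_t), ``impression``
    (ratings rescaled to 0-1) and ``uncertainty`` (reverse-scored certainty
    ratings). Pre-task ratings (trial 0) are excluded — they are prior
    expectations, analysed separately. With ``aggregate`` the trialwise rows
    are averaged per participant x agent before standardization.
    """
    groups = cohort.groups()
    covs = cohort.participants.set_index("participant_id")
    frames = []

    ratings = cohort.ratings[cohort.ratings["trial_index"] > 0].copy()
    for measure, values in (
        ("impression", ratings["impression"] / 100.0),
        ("uncertainty", stats_mod.reverse_uncertainty(ratings["certainty"].to_numpy())),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": ratings["participant_id"],
                    "agent": ratings["agent_label"],
                    "trial_index": ratings["trial_index"],
                    "measure": measure,
                    "value": np.asarray(values, dtype=float),
                }
            )
        )

    if trace_df is not None and not trace_df.empty:
        for measure, col in (("learning_rate", "alpha"), ("model_uncertainty", "sigma_pre")):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": trace_df["participant_id"],
                        "agent": trace_df["agent"],
                        "trial_index": trace_df["trial_index"],
                        "measure": measure,
                        "value": stats_mod.standardize(trace_df[col].to_numpy()),
                    }
                )
            )

    table = pd.concat(frames, ignore_index=True)
    if aggregate:
        table = (
            table.groupby(["participant_id", "agent", "measure"], as_index=False)
            .agg(value=("value", "mean"), trial_index=("trial_index", "mean"))
        )
    table["group"] = table["participant_id"].map(groups)
    for cov in ("severity", "medication"):
        if cov in covs.columns:
            table[cov] = table["participant_id"].map(covs[cov])
    return table


def prior_expectation_tests(cohort: CohortDataset) -> dict[str, dict]:
    """Rank-sum comparisons of pre-task expectation and certainty ratings.

    Each participant contributes the mean of their two pre-task ratings.
    Compares BPD vs non-BPD and BPD vs DTC, for both the expectation
    (impression) and its certainty.
    """
    pre = cohort.ratings[cohort.ratings["trial_index"] == 0]
    per_part = pre.groupby("participant_id")[["impression", "certainty"]].mean()
    groups = cohort.groups()
    per_part["group"] = [groups[p] for p in per_part.index]

    out: dict[str, dict] = {}
    for name, other in (("bpd_vs_control", GROUP_CONTROL), ("bpd_vs_dtc", GROUP_DTC)):
        a = per_part[per_part["group"] == GROUP_BPD]
        b = per_part[per_part["group"] == other]
        if a.empty or b.empty:
            continue
        for col, label in (("impression", "expectation"), ("certainty", "certainty")):
            z, p = stats_mod.ranksum_test(a[col].to_numpy(), b[col].to_numpy())
            out[f"{name}_{label}"] = {"z": z, "p": p, "n_a": len(a), "n_b": len(b)}
    return out


def phenotype_run(
    seed: int,
    n_restarts: int = 3,
    fit_grid_size: int = 51,
    models: tuple[str, ...] = ("dynamic",),
    aggregate: bool = True,
) -> dict:
    """Generate the default cohort, fit it, and build the analysis table.

    This is the canonical end-to-end phenotype analysis: the dynamic learner
    is fitted per participant with the assumed agent consistency fixed by
    configuration at the cohort's generative value (it is common to all
    participants), and the group regressions run on the fitted trialwise
    traces plus the rating streams. Fitting uses a reduced grid and restart
    count; these are the analysis problem sizes, exposed as arguments.
    """
    profile = default_profiles()[GROUP_CONTROL]
    cohort = generate_cohort(seed=seed)
    participants = list(cohort.iter_participants())
    fits = fit_cohort(
        participants,
        models=models,
        seed=seed,
        n_restarts=n_restarts,
        grid_size=fit_grid_size,
        lam=profile.lam,
        bounds={"beta": (profile.beta, profile.beta)},
        leak_to_prior=profile.leak_to_prior,
    )
    trace_df = dynamic_trace_table(
        participants, fits, grid_size=101, lam=profile.lam,
        leak_to_prior=profile.leak_to_prior,
    )
    table = analysis_table(cohort, trace_df, aggregate=aggregate)
    return {
        "cohort": cohort,
        "participants": participants,
        "fits": fits,
        "trace_df": trace_df,
        "table": table,
    }


def run_analysis(
    cohort: CohortDataset,
    fits: dict[str, dict[str, FitResult]],
    seed: int = 0,
    reference_group: str = GROUP_BPD,
    bms_n_samples: int = bms_mod.DEFAULT_N_SAMPLES,
    grid_size: int = 101,
    aggregate: bool = False,
    leak_to_prior: bool = False,
    lam: float = 0.1,
) -> dict:
    """Model selection, best-model group comparison, regressions, and report."""
    participants = list(cohort.iter_participants())
    models = sorted(next(iter(fits.values())).keys(), key=lambda m: MODELS.index(m))
    result: dict = {}

    if len(models) >= 2:
        ev = evidence_matrix(fits, models=models)
        bms_res = bms_mod.rfx_bms(ev, n_samples=bms_n_samples, seed=seed)
        counts = bms_mod.best_model_counts(bms_res, cohort.groups())
        result["bms"] = bms_res
        result["best_model_counts"] = counts
        if (counts.sum(axis=0) > 0).all() and (counts.sum(axis=1) > 0).all():
            chi2, dof, p = bms_mod.chi_square_independence(counts)
            result["chi2_best_model"] = {"statistic": chi2, "df": dof, "p": p}
        else:
            # every participant best fit by the same model: no association to test
            result["chi2_best_model"] = {
                "statistic": float("nan"), "df": (counts.shape[0] - 1), "p": float("nan"),
                "degenerate": True,
            }

    trace_df = dynamic_trace_table(
        participants, fits, grid_size=grid_size, lam=lam, leak_to_prior=leak_to_prior
    )
    table = analysis_table(cohort, trace_df, aggregate=aggregate)
    measure_fits = stats_mod.fit_all_measures(
        table, reference_group=reference_group, include_trial=not aggregate
    )
    result["analysis_table"] = table
    result["measure_fits"] = measure_fits
    result["report"] = stats_mod.phenotype_report(measure_fits, reference_group)
    result["prior_expectations"] = prior_expectation_tests(cohort)
    return result
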