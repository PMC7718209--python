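"""Group-level statistics: robust regression, rank-sum tests, phenotype summary.

The measures analysed are standardized trialwise learning rates, subjective
impression ratings, and certainty ratings reverse-scored into *uncertainty*
(higher = less certain). The workhorse is an iteratively reweighted
least-squares regression with Tukey bisquare weights (tuning constant 4.685,
scale estimated by the median absolute deviation), the standard
95%-efficiency robust alternative to ordinary least squares. The omnibus
model for each measure includes agent (bad vs. good), group (dummy-coded
against a configurable reference, untreated BPD by default), their
interaction, and trial number as a nuisance covariate; severity moderation
and a medication covariate are supported by adding terms.

Nonparametric two-sample comparisons use the Wilcoxon rank-sum test with
midranks; for small samples (combined n <= 12) the two-sided p-value comes
from exact enumeration of rank assignments, otherwise from the tie- and
continuity-corrected normal approximation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

BISQUARE_C = 4.685
MEASURES = ("learning_rate", "impression", "uncertainty", "model_uncertainty")
#: Combined sample size up to which the rank-sum p-value is computed exactly.
EXACT_RANKSUM_N = 12


def standardize(values) -> np.ndarray:
    """z-score with sample (ddof=1) SD, computed over the full analysis sample."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardize requires at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("standardize requires non-constant input")
    return (x - x.mean()) / sd


def reverse_uncertainty(certainty):
    """Reverse-score certainty (0-1) so that higher values mean greater uncertainty."""
    c = np.asarray(certainty, dtype=float)
    if np.any((c < 0) | (c > 1)):
        raise ValueError("certainty ratings must lie in [0, 1]")
    out = 1.0 - c
    return float(out) if np.isscalar(certainty) else out


def _check_full_rank(design: pd.DataFrame) -> None:
    x = np.asarray(design, dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    # Identify columns that do not increase rank when added left to right.
    bad = []
    r = 0
    for j in range(x.shape[1]):
        rj = np.linalg.matrix_rank(x[:, : j + 1])
        if rj == r:
            bad.append(design.columns[j])
        r = rj
    raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")


def _coef_table(params, bse, tvals, pvals, n_obs: int, cov=None) -> pd.DataFrame:
    table = pd.DataFrame(
        {
            "term": list(params.index),
            "estimate": np.asarray(params, dtype=float),
            "se": np.asarray(bse, dtype=float),
            "t": np.asarray(tvals, dtype=float),
            "p": np.asarray(pvals, dtype=float),
            "n_obs": n_obs,
        }
    )
    if cov is not None:
        table.attrs["cov_params"] = pd.DataFrame(
            np.asarray(cov), index=params.index, columns=params.index
        )
    return table


def robust_fit(
    table: pd.DataFrame,
    measure: str,
    reference_group: str = "BPD",
    include_agent: bool = True,
    include_group: bool = True,
    include_interaction: bool = True,
    include_trial: bool = True,
    covariates: tuple[str, ...] = (),
    extra_terms: tuple[str, ...] = (),
    group_var: str = "group",
) -> pd.DataFrame:
    """Robust (bisquare) regression of one measure on agent x group (+ covariates).

    ``table`` is a long analysis table with columns participant_id, group,
    agent, trial_index, measure, value (plus any covariates). Returns a
    coefficient table (term, estimate, se, t, p, n_obs) with the robust
    covariance matrix attached in ``.attrs['cov_params']``.

    Perfect fits (all residuals zero, e.g. noise-free cell-mean designs) fall
    back to ordinary least squares, which is the exact bisquare solution when
    every residual weight is 1.
    """
    data = table[table["measure"] == measure].copy()
    if data.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    if include_group and reference_group not in set(data[group_var]):
        raise ValueError(f"reference group {reference_group!r} not present")

    data["agent_bad"] = (data["agent"] == "bad").astype(float)
    terms = []
    if include_agent and include_group and not include_interaction:
        terms.append(f"agent_bad + C({group_var}, Treatment(reference='{reference_group}'))")
    elif include_agent and include_group:
        terms.append(f"agent_bad * C({group_var}, Treatment(reference='{reference_group}'))")
    elif include_agent:
        terms.append("agent_bad")
    elif include_group:
        terms.append(f"C({group_var}, Treatment(reference='{reference_group}'))")
    if include_trial:
        terms.append("trial_index")
    terms.extend(covariates)
    terms.extend(extra_terms)
    if not terms:
        raise ValueError("no model terms requested")
    formula = "value ~ " + " + ".join(terms)

    from patsy import dmatrices

    y, x = dmatrices(formula, data=data, return_type="dataframe")
    _check_full_rank(x)
    n_obs = len(y)

    ols = sm.OLS(np.asarray(y).ravel(), x).fit()
    resid_scale = sm.robust.scale.mad(ols.resid, center=0)
    y_scale = float(np.std(np.asarray(y))) + 1.0
    if resid_scale < 1e-12 * y_scale:
        # Degenerate perfect fit: bisquare weights are all exactly 1.
        return _coef_table(
            ols.params, ols.bse, ols.tvalues, ols.pvalues, n_obs, ols.cov_params()
        )

    rlm = sm.RLM(np.asarray(y).ravel(), x, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = rlm.fit(scale_est="mad")
    return _coef_table(res.params, res.bse, res.tvalues, res.pvalues, n_obs, res.cov_params())


def wald_interaction_test(coef_table: pd.DataFrame, term_substring: str = "agent_bad:") -> tuple[float, int, float]:
    """Joint Wald chi-square test of all coefficients whose term contains a substring.

    Used for the omnibus group x agent interaction (2 df with three groups).
    """
    cov = coef_table.attrs.get("cov_params")
    if cov is None:
        raise ValueError("coefficient table lacks a covariance matrix")
    mask = coef_table["term"].str.contains(term_substring, regex=False)
    idx = list(coef_table.loc[mask, "term"])
    if not idx:
        raise ValueError(f"no terms match {term_substring!r}")
    beta = coef_table.loc[mask, "estimate"].to_numpy()
    v = cov.loc[idx, idx].to_numpy()
    stat = float(beta @ np.linalg.solve(v, beta))
    df = len(idx)
    from scipy.stats import chi2

    return stat, df, float(chi2.sf(stat, df))


class RankSumResult(NamedTuple):
    z: float
    p: float


def _ranksum_moments(ranks: np.ndarray, n_a: int) -> tuple[float, float]:
    n = len(ranks)
    n_b = n - n_a
    mu = n_a * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    return mu, var


def ranksum_test(sample_a, sample_b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test (midranks).

    The z statistic uses the tie-corrected normal approximation with a
    continuity correction. The p-value is exact (enumeration over rank
    assignments, two-sided as P(|W - E W| >= |w - E W|)) when the combined
    sample size is at most 12, and the normal approximation otherwise.
    Identical constant samples give z = 0, p = 1.
    """
    from scipy.stats import norm, rankdata

    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = float(ranks[: a.size].sum())
    mu, var = _ranksum_moments(ranks, a.size)
    if var <= 0:
        return RankSumResult(z=0.0, p=1.0)

    dev = w - mu
    cc = 0.5 * np.sign(dev)
    z = (dev - cc) / math.sqrt(var) if dev != 0 else 0.0

    n = pooled.size
    if n <= EXACT_RANKSUM_N:
        target = abs(dev) - 1e-12
        hits = total = 0
        for combo in itertools.combinations(range(n), a.size):
            w_perm = ranks[list(combo)].sum()
            total += 1
            if abs(w_perm - mu) >= target:
                hits += 1
        p = hits / total
    else:
        p = 2.0 * float(norm.sf(abs(z)))
    return RankSumResult(z=float(z), p=float(min(p, 1.0)))


def _term_summary(row: pd.Series) -> dict:
    p = float(row["p"])
    est = float(row["estimate"])
    return {
        "estimate": est,
        "se": float(row["se"]),
        "t": float(row["t"]),
        "p": p,
        "significant": bool(p < 0.05),
        "sign": int(np.sign(est)),
    }


def _find_term(table: pd.DataFrame, substring: str) -> pd.Series | None:
    mask = table["term"].str.contains(substring, regex=False)
    if not mask.any():
        return None
    return table[mask].iloc[0]


def fit_all_measures(
    table: pd.DataFrame,
    reference_group: str = "BPD",
    measures: tuple[str, ...] = MEASURES,
    covariates: tuple[str, ...] = (),
    include_trial: bool = True,
) -> dict[str, dict]:
    """Omnibus agent x group fit plus per-agent simple-effect fits, per measure."""
    out: dict[str, dict] = {}
    for measure in measures:
        if not (table["measure"] == measure).any():
            continue
        entry: dict = {
            "omnibus": robust_fit(
                table,
                measure,
                reference_group=reference_group,
                covariates=covariates,
                include_trial=include_trial,
            ),
            "simple": {},
        }
        for agent in ("bad", "good"):
            sub = table[(table["measure"] == measure) & (table["agent"] == agent)]
            entry["simple"][agent] = robust_fit(
                sub.assign(measure=measure),
                measure,
                reference_group=reference_group,
                include_agent=False,
                include_trial=include_trial,
                covariates=covariates,
            )
        out[measure] = entry
    return out


def phenotype_report(fits: dict[str, dict], reference_group: str = "BPD") -> dict:
    """Structured summary of the phenotype pattern across measures.

    For every fitted measure: the agent main effect, each group x agent
    interaction against the reference group, and per-agent simple-effect
    group contrasts, each with estimate/SE/t/p, a significance flag at 0.05,
    and the sign. Measures without fits are listed as absent.
    """
    report: dict = {"reference_group": reference_group, "measures": {}, "absent": []}
    for measure in MEASURES:
        entry = fits.get(measure)
        if entry is None:
            report["absent"].append(measure)
            continue
        omnibus = entry["omnibus"]
        # Exclude interaction rows when picking the main effect.
        main_mask = (omnibus["term"] == "agent_bad")
        agent_main = _term_summary(omnibus[main_mask].iloc[0]) if main_mask.any() else None

        interactions = {}
        for _, row in omnibus.iterrows():
            term = row["term"]
            if ":agent_bad" in term or term.endswith(":agent_bad") or (
                "agent_bad:" in term
            ):
                # patsy names interactions like "agent_bad:C(group, ...)[T.non-BPD]"
                label = term.split("[T.")[-1].rstrip("]") if "[T." in term else term
                interactions[label] = _term_summary(row)

        simple = {}
        for agent, tab in entry["simple"].items():
            simple[agent] = {}
            for _, row in tab.iterrows():
                if "[T." in row["term"]:
                    label = row["term"].split("[T.")[-1].rstrip("]")
                    simple[agent][label] = _term_summary(row)

        report["measures"][measure] = {
            "agent_main": agent_main,
            "interactions": interactions,
            "simple_effects": simple,
        }
    return report


def render_report(report: dict) -> str:
    """Human-readable rendering of a phenotype report."""
    lines = [f"Phenotype report (reference group: {report['reference_group']})"]
    for measure, entry in report["measures"].items():
        lines.append(f"\n== {measure} ==")
        main = entry["agent_main"]
        if main is not None:
            lines.append(
                "  agent main effect (bad - good): "
                f"beta = {main['estimate']:+.3f} +/- {main['se']:.3f}, "
                f"t = {main['t']:.3f}, p = {main['p']:.3g}"
            )
        for label, s in entry["interactions"].items():
            lines.append(
                f"  {label} x agent interaction: beta = {s['estimate']:+.3f} "
                f"+/- {s['se']:.3f}, t = {s['t']:.3f}, p = {s['p']:.3g}"
            )
        for agent, contrasts in entry["simple_effects"].items():
            for label, s in contrasts.items():
                lines.append(
                    f"  {agent} agent, {label} vs reference: beta = {s['estimate']:+.3f}"
                    f" +/- {s['se']:.3f}, t = {s['t']:.3f}, p = {s['p']:.3g}"
                )
    if report["absent"]:
        lines.append("\nabsent measures: " + ", ".join(report["absent"]))
    return "\n".join(lines)
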