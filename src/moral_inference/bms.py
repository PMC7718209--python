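"""Random-effects Bayesian model selection and the best-model group comparison.

Treats the model generating each participant's data as a random effect and
infers the population frequencies of the candidate models from per-participant
log evidences via the standard variational Dirichlet-multinomial scheme:
per-participant model responsibilities are softmax(log evidence + digamma
terms), the Dirichlet counts are prior counts plus summed responsibilities,
and the two steps iterate to a fixed point. Exceedance probabilities — the
posterior probability that each model is the most frequent in the population —
are estimated by Monte Carlo sampling from the fitted Dirichlet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import chi2_contingency

DEFAULT_ALPHA0 = 1.0
DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000
DEFAULT_N_SAMPLES = 1_000_000


@dataclass
class BmsResult:
    """Posterior over population model frequencies and per-participant assignments."""

    model_ids: list[str]
    participant_ids: list[str]
    dirichlet_alpha: np.ndarray  # (K,)
    expected_frequencies: np.ndarray  # (K,), sums to 1
    exceedance: np.ndarray  # (K,), sums to 1
    responsibilities: np.ndarray  # (N, K), rows sum to 1
    best_model: list[str]  # per participant
    converged: bool
    n_iter: int

    def to_json_dict(self) -> dict:
        return {
            "model_ids": list(self.model_ids),
            "dirichlet_alpha": [float(a) for a in self.dirichlet_alpha],
            "expected_frequencies": [float(f) for f in self.expected_frequencies],
            "exceedance": [float(x) for x in self.exceedance],
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }

    def responsibilities_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.responsibilities, index=self.participant_ids, columns=self.model_ids
        )
        frame.index.name = "participant_id"
        return frame


def _softmax_rows(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def rfx_bms(
    evidence: pd.DataFrame,
    alpha0: float = DEFAULT_ALPHA0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int = 0,
    preferred_model: str = "dynamic",
) -> BmsResult:
    """Variational random-effects model selection over a log-evidence matrix.

    ``evidence`` is participants x models (log scale). ``preferred_model``
    only breaks exact ties in the per-participant best-model assignment.
    """
    lnE = np.asarray(evidence, dtype=float)
    if lnE.ndim != 2 or lnE.shape[1] < 2:
        raise ValueError("evidence must be an N x K matrix with K >= 2")
    if not np.all(np.isfinite(lnE)):
        raise ValueError("evidence matrix contains non-finite entries")
    n, k = lnE.shape
    model_ids = [str(c) for c in evidence.columns]
    participant_ids = [str(i) for i in evidence.index]

    alpha = np.full(k, float(alpha0))
    converged = False
    it = 0
    resp = np.full((n, k), 1.0 / k)
    for it in range(1, max_iter + 1):
        resp = _softmax_rows(lnE + (digamma(alpha) - digamma(alpha.sum())))
        alpha_new = alpha0 + resp.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new
    if not converged:
        warnings.warn(
            f"random-effects model selection did not converge in {max_iter} iterations",
            RuntimeWarning,
        )

    xp = exceedance_prob(alpha, n_samples=n_samples, seed=seed)

    best: list[str] = []
    for row in resp:
        top = row.max()
        tied = [model_ids[j] for j in range(k) if row[j] >= top - 1e-12]
        best.append(preferred_model if preferred_model in tied else sorted(tied)[0])

    return BmsResult(
        model_ids=model_ids,
        participant_ids=participant_ids,
        dirichlet_alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance=xp,
        responsibilities=resp,
        best_model=best,
        converged=converged,
        n_iter=it,
    )


def exceedance_prob(
    dirichlet_alpha, n_samples: int = DEFAULT_N_SAMPLES, seed: int = 0
) -> np.ndarray:
    """Monte Carlo P(model k has the highest population frequency)."""
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("Dirichlet parameters must be positive")
    if n_samples < 1000:
        warnings.warn(
            f"n_samples={n_samples} is small; exceedance estimates will be noisy",
            RuntimeWarning,
        )
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(draws, axis=1)
    counts = np.bincount(winners, minlength=len(alpha))
    return counts / counts.sum()


def best_model_counts(
    bms: BmsResult, groups: dict[str, str], group_order=("BPD", "non-BPD", "DTC"),
    target_model: str = "dynamic",
) -> pd.DataFrame:
    """Group x {target model, other} contingency table of best-model assignments."""
    unknown = sorted({g for g in groups.values()} - set(group_order))
    if unknown:
        raise ValueError(f"unknown group labels: {unknown}")
    missing = [p for p in bms.participant_ids if p not in groups]
    if missing:
        raise ValueError(f"no group label for participants: {missing[:5]}")
    table = pd.DataFrame(0, index=list(group_order), columns=[target_model, "other"])
    for pid, best in zip(bms.participant_ids, bms.best_model):
        col = target_model if best == target_model else "other"
        table.loc[groups[pid], col] += 1
    table.index.name = "group"
    return table


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an R x C count table."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be positive")
    stat, p, dof, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)
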