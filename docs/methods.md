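# Methods

## The inference problem

An observer watches an agent repeatedly choose between a *harmful* option
(more money, more painful shocks delivered to a third party) and a *helpful*
option (less money, fewer shocks), predicts each choice before seeing it, and
periodically reports an impression of the agent's moral character (0 =
nasty … 100 = nice) and the certainty of that impression (0–1). The
computational question is how the observer's belief about the agent's *harm
aversion* — the exchange rate between money and shocks — is formed and
updated, and how that process differs between groups (untreated borderline
personality disorder, matched non-BPD controls, and patients treated in a
democratic therapeutic community, DTC).

## Agent choice model

An agent is described by a harm-aversion parameter κ ∈ [0, 1] and a choice
consistency β ≥ 0. With Δm and Δs the money and shock differences between
the harmful and helpful options — each rescaled by its task-wide maximum so
both lie in (0, 1] — the probability of the harmful choice is

    P(harmful) = logistic( β · [ (1 − κ)·Δm − κ·Δs ] ).

κ = 0.5 is indifferent when the rescaled Δm and Δs are equal; higher κ
requires more money per shock. A task instance pairs a "good" agent
(κ = 0.7 by default) with a "bad" agent (κ = 0.3), both with β = 6, values
chosen to give a clear qualitative separation between the two agents'
choice surfaces while keeping both stochastic.

## The dynamic learner

Beliefs over κ live on a regular grid of G = 101 points in [0, 1]. The prior
is a truncated Gaussian with mean μ₀ (the pre-task expectation) and spread
σ₀ (the pre-task uncertainty), evaluated on the grid and normalised. Each
trial the learner

1. predicts P(harmful) by averaging the choice rule over its belief,
2. observes the agent's actual choice and applies Bayes' rule on the grid,
   with the learner's own assumed consistency β in the likelihood,
3. leaks a fraction λ of probability mass toward a leak target.

The trialwise effective learning rate is the Rescorla–Wagner gain implied by
the belief-mean movement:

    α_t = |μ_post − μ_pre| / |δ_t|,   δ_t = observed − predicted probability,

defined as 0 when |δ_t| < 1e−12. Because Bayesian updating is
precision-weighted, α_t increases with the spread of the current belief:
when beliefs are less precise, new information is weighted more heavily.
This uncertainty-gating is the mechanism of interest, and it is verified as
a strict monotonicity property (α strictly increasing over σ₀ ∈ 0.05…0.4 at
λ = 0).

### The leak and its target

Without forgetting, an ideal grid learner converges within a few tens of
trials: belief spread collapses, learning rates flatten, and any
prior-driven differences between agents or groups become transient. Human
observers do not behave this way — certainty ratings remain differentiated
between agents late into a session. The leak models this. Two targets are
supported:

* **uniform** (the `update` default): mass relaxes toward the uniform
  distribution. This bounds spread away from zero but erases *differences*:
  every learner relaxes toward the same floor, so group asymmetries still
  vanish after ~15 trials.
* **prior-anchored** (`leak_to_prior`, the generator and pipeline default):
  mass relaxes toward the learner's own prior. The stationary belief then
  remains tied to (μ₀, σ₀): observers with a wide prior about an agent stay
  persistently more uncertain and keep updating faster. This matches the
  empirical picture of sustained certainty asymmetries, keeps the prior
  parameters expressed in behaviour throughout the session (which is what
  makes them statistically identifiable), and is psychologically
  interpretable as regression toward a trait-like baseline impression.

λ defaults to 0.1 in the cohort generator. Larger λ anchors more strongly;
the parameter-recovery study (below) uses λ = 0.4 to characterise the
well-identified regime.

## Comparison models

Two fixed-learning-rate alternatives track a point estimate κ̂ rather than a
distribution:

* single rate: κ̂ ← clip₀¹(κ̂ − α·δ_t), with prediction from the same choice
  rule at κ̂ (3 free parameters: κ̂₀, α, β);
* valenced: separate rates α⁻ (after harmful observations) and α⁺ (after
  helpful ones); with α⁻ = α⁺ it reproduces the single-rate model exactly
  (4 free parameters).

Harmful evidence lowers κ̂ (δ > 0 after a harmful choice). κ̂₀ is shared
across the two agents, matching the models' stated parameter counts.

## Fitting and model comparison

A participant contributes one block per agent: trials, the agent's choices,
and the participant's binary predictions. Every model yields a trialwise
predicted probability p_t; the participant is assumed to respond "harmful"
with q_t = lapse + (1 − 2·lapse)·p_t, lapse fixed at 0.02 (symmetric lapse;
lapse = 0.5 is pure chance and any positive lapse keeps the Bernoulli log
likelihood finite). Fits are bounded multi-start L-BFGS-B minimisations of
the negative log likelihood (library default 10 restarts; the pipeline's
batch analyses use 3–4 restarts with a G = 51–61 fitting grid, the problem
sizes used for all results below). Default bounds: μ₀, κ̂₀ ∈ [0.01, 0.99],
σ₀ ∈ [0.01, 1], rates ∈ [0, 1], β ∈ [0.1, 20]. β is shared across agents and
fitted unless fixed by configuration; λ is fixed, never fitted. The dynamic
model fits (μ₀, σ₀) per agent by default (5 free parameters) or one shared
pair (`shared_prior`).

Model evidence is approximated by −BIC/2. Random-effects Bayesian model
selection treats the generating model as varying across participants: a
variational Dirichlet-multinomial scheme iterates participant-level
responsibilities (softmax of log evidence plus digamma terms) against
Dirichlet counts (α₀ = 1 per model, tolerance 1e−6), yielding expected
population model frequencies; exceedance probabilities (the posterior
probability that a model is the most frequent) come from 10⁶ Monte Carlo
Dirichlet draws. Per-participant best models are argmax responsibilities,
ties broken toward the dynamic model; a group × (dynamic vs other)
contingency table is tested with Pearson's χ² (no continuity correction).

## Synthetic cohort

The generator emulates the study's structure: 20 untreated BPD, 106 matched
controls and 23 DTC-treated participants; 50-trial blocks per agent;
impression and certainty ratings every third trial plus a pre-task rating;
five controls matched to each BPD patient's task variant (identical trial
and agent-choice sequences). Screening, severity and medication covariates
are drawn per group (severity follows the reported group means/SDs; the
control screening scores are truncated at the exclusion cutoff because the
default cohort represents the post-screening analysed sample).

Group profiles encode the phenotype generatively via per-agent prior spreads
(means, between-participant SD 0.05):

| group    | n   | μ₀ mean | σ₀ bad | σ₀ good |
|----------|-----|---------|--------|---------|
| non-BPD  | 106 | 0.50    | 0.33   | 0.12    |
| BPD      | 20  | 0.40    | 0.18   | 0.22    |
| DTC      | 23  | 0.40    | 0.28   | 0.18    |

Controls hold wide bad-agent priors (uncertain, fast-updating negative
impressions) and tight good-agent priors; untreated BPD reverses the
asymmetry and is pessimistic a priori (lower μ₀); DTC keeps BPD's pessimism
but restores the wide bad-agent prior. All participants share the
generative learner settings β = 3 (beliefs update gradually over the block
rather than converging within a few trials), λ = 0.1 with the prior-anchored
leak, and lapse 0.02. Predictions are sampled from the learner's own
predictive probability (probability matching), which keeps the likelihood
informative for recovery studies. The σ₀ magnitudes are calibration
constants: they were chosen, together with β and the leak target, so that
the generative trajectories carry the intended group asymmetries at
moderate effect sizes *and* those asymmetries survive per-participant
fitting. They are exposed in `GroupProfile` and are not estimates of any
real population.

## Group-level statistics

Four trialwise measures enter the analysis: standardized fitted learning
rates α_t and model uncertainty σ_t (from the dynamic model re-run with each
participant's fitted parameters), impression ratings (rescaled to 0–1), and
certainty ratings reverse-scored into uncertainty. Standardization is over
the full analysis sample per measure. The workhorse regression is
iteratively reweighted least squares with Tukey bisquare weights (tuning
constant 4.685, MAD scale — the standard 95%-efficiency choice), with agent
(bad vs good), group (dummy-coded, untreated BPD the reference), their
interaction, and trial number as a covariate; severity moderation and a
medication covariate are available as extra terms. Perfect fits fall back
to ordinary least squares (bisquare weights are exactly 1 there). Rows can
enter trialwise (with the trial covariate) or aggregated to participant ×
agent means; the phenotype analyses aggregate, because trialwise rows
pseudo-replicate participants (learning rates are heavily skewed across
trials, and the bisquare bulk-weighting then mutes the early-trial signal
while overstating precision). Rank-sum tests (midranks) compare pre-task
expectation and certainty ratings between groups: exact enumeration
p-values for combined n ≤ 12, tie- and continuity-corrected normal
approximation otherwise.

## Validation studies and problem sizes

* **Exactness.** The grid learner matches an independently coded scalar
  Bayes loop to 1e−12 on small grids; belief mass stays normalised to
  1e−10 across 10⁴ randomised updates.
* **Parameter recovery.** 50 participants, two 100-trial blocks, one shared
  (μ₀, σ₀) per participant drawn broadly (μ₀ ~ U(0.15, 0.85),
  σ₀ ~ U(0.05, 0.45)), learner β = 8 known, λ = 0.4 prior-anchored. This is
  the identifiable regime: the anchored prior stays expressed in
  predictions all session. Recovery degrades substantially at weaker
  anchoring or shorter blocks — per-participant binary predictions carry
  little information about prior parameters once beliefs converge — so
  individual point estimates at the cohort's settings should be read as
  noisy; group-level contrasts remain meaningful because estimator noise
  averages out within groups.
* **Model recovery.** 30 participants, 200-trial blocks, distinct per-agent
  priors, β = 10, uniform leak λ = 0.1: conditions under which the dynamic
  learner's signature (large early, uncertainty-gated updates plus
  sustained rate variability) cannot be mimicked by a fixed rate at the
  BIC's parameter cost.
* **Phenotype reproduction.** The default cohort, dynamic model fitted with
  β fixed by configuration at the generative value (it is common to all
  participants), measures aggregated: the pooled agent effect on learning
  rates and model uncertainty is positive (bad > good), and with BPD as
  reference the non-BPD and DTC group × agent interactions are positive,
  across independent cohort seeds.
* **Null calibration.** With identical profiles in all three groups
  (3 × 15 participants, 30-trial blocks), the 2-df Wald test of the group ×
  agent interaction on aggregated uncertainty ratings rejects at nominal
  0.05 with empirical rate within [0.01, 0.10] over 200 simulated cohorts.

## Numerical choices and degenerate inputs

* Grid G = 101 for simulation/replay, 51–61 for batch fitting (the
  likelihood is smooth in κ; coarser grids change fits negligibly).
* Likelihood-vanishing updates cannot occur with the logistic likelihood;
  the update still guards against a zero-mass posterior.
* `standardize` rejects constant input; `robust_fit` rejects rank-deficient
  designs naming the collinear terms; χ² requires positive margins, and the
  pipeline reports a degenerate (NaN) χ² when every participant is best fit
  by the same model.
* Rank-sum with zero rank variance (all values tied) returns z = 0, p = 1.
* CSV round-trips are bit-exact (`%.17g` on write, round-trip float parsing
  on read).

## What the synthetic data do and do not show

The generator produces data *from the fitted model family itself* with
group differences inserted by construction. Passing tests therefore
demonstrate that the pipeline is internally consistent — it recovers what
was put in, prefers the generating model, and its statistics are calibrated
under the null — not that the model describes real behaviour, and not that
the effect sizes resemble empirical ones. Real data add features the
generator omits: response times, attention lapses beyond a constant rate,
sequential dependencies in predictions, missing ratings, and
individual differences in the leak and consistency parameters that are here
fixed within groups.
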