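# Methods

This note documents the models, estimators and synthetic-data generator in
`itpav`: what is computed, the numerical choices behind it, and what the
synthetic results do and do not establish about real data.

## Task model

A session is 200 trials: four conditions (go/no-go × immediate/delayed
reward) presented 50 times each, split into four contiguous 50-trial
blocks. Pseudorandomization forbids more than `max_run = 2` consecutive
presentations of one condition. Orders are drawn by constrained sequential
sampling — each trial's condition is drawn with probability proportional
to its remaining count among run-feasible conditions, restarting on the
rare dead end. This enforces the count and run constraints exactly and is
close to, though not exactly, uniform over admissible sequences (exact
uniformity via rejection sampling of full shuffles is computationally
prohibitive at 200 trials: the acceptance probability is ~e⁻¹²).

Feedback validity is an independent Bernoulli(0.8) draw per trial; whether
the original task balanced invalid feedback exactly within condition is
not documented, so the simpler independent scheme is used. On valid trials
the displayed outcome matches response correctness; on invalid trials it
is reversed. Rewards are coded r ∈ {0, 1} regardless of timing — the two
rewards are preference-matched per participant, so timing enters the
models only through the cue value V(s) and the learning-bias rule, never
through reward magnitude.

## Choice titration

The Monetary Choice Questionnaire is scored by consistency maximisation:
the 27 items imply 9 discount-rate ranks; candidates are the two extreme
ranks plus geometric means of adjacent ranks (10 values), and the scored k
maximises agreement with the observed choices (ties → geometric mean of
tied candidates). The staircase starts at the hyperbolic present value
28/(1 + 120k) rounded to the nearest even integer (ties down), steps €2
down after an immediate choice and up after a delayed choice within
[0, 28], and stops when the last six offers span ≤ €2; the matched amount
is the rounded arithmetic mean of that window (the summary statistic is
not otherwise specified). Choosing €0 triggers one confirmation trial
(counted toward the 50-trial cap); a repeated €0 preference flags the
`prefers-zero` exclusion, and failing to stabilise within 50 trials flags
`no-stability`. The impatience score is 29 − matched amount, mapping the
1–28 range onto itself with higher = more impatient.

## RL model family and likelihood

Action values Q(s, a) are tracked per cue (4 conditions × 2 actions),
initialised at 0 (no initialisation value is documented for the task; 0
makes the first presentation maximally informative and is the common
choice with 0/1 reward coding). Only the taken action's value for the
presented cue is updated. The go action weight adds the go bias b (M2+)
and π·V(s) (M3, M5) with V fixed at +1/−1 for immediate/delayed cues; the
no-go weight is the plain Q value. Choice probabilities use a softmax with
inverse temperature τ, mixed with a uniform lapse: p = softmax·(1−ξ)+ξ/2,
so p(go) ∈ [ξ/2, 1−ξ/2]. The learning bias (M4, M5) applies α₀ when a go
response obtained an immediate reward or a no-go response obtained a
delayed reward, and α₁ otherwise; no-reward outcomes always fall to α₁
(the literal reading of the rule's "else" branch). M4 retains the go bias,
so the nesting M0 ⊂ M1 ⊂ M2 ⊂ {M3, M4} ⊂ M5 holds exactly, with free
parameter counts 2, 3, 4, 5, 5, 6.

The session log-likelihood evolves the same state equations with the
observed actions and outcomes and sums log p(observed action). Softmax
terms subtract the max weight before exponentiation; log-probabilities are
floored at 1e−12, which only binds for ξ-free models (ξ > 0 already bounds
p away from 0). The likelihood and simulator share one jit-compiled
kernel, and an exhaustive enumeration oracle verifies on ≤ 12-trial
schedules that the per-sequence probabilities sum to 1 for every model.

## MAP fitting

Per participant and model, the posterior log-density (likelihood + priors)
is maximised over the natural box-constrained space: α, α₀, α₁, ξ ∈ [0, 1]
(implicit uniform priors), τ ∈ [0, 50] with a Gamma(shape 3, rate 0.3)
prior (mean 10 — the shape/rate reading is consistent with the τ bound and
with fitted means near 7), b, π ∈ [−3, 3] with standard-normal priors.
Optimisation uses differential evolution (population 10 per dimension, up
to 250 generations, relative tolerance 0.01, latin-hypercube
initialisation, gradient polish), seeded deterministically. Two
independent optimiser runs on the same session agree to ~3e−4 in the
parameters, so optimisation error is negligible against sampling noise.
Boundary points with zero prior density return a large finite penalty so
the polish stage's finite differences stay defined. AIC is computed from
the pure likelihood at the MAP point (2k − 2 log L), and model frequency
is the proportion of participants per model with the lowest AIC, ties
split equally.

## Validation battery

Parameter recovery simulates agents at known parameters, refits, and
reports Pearson correlations, bias and RMSE per parameter. Truths default
to uniform draws over shrunken boxes (α, α₀, α₁ ∈ [0.05, 0.6],
τ ∈ [1, 15], ξ ∈ [0, 0.4], b, π ∈ [−1, 1]) — wide enough to span realistic
behaviour, narrow enough to avoid boundary pile-up and agents whose
sessions carry no information (ξ near 1). Recovery can instead be run
under the cohort hyperdistribution (the generator's defaults), which is
how recovery under study conditions is assessed.

At the task's single-session length (T = 200) the recovery ceiling is an
information limit, not an optimiser artifact. The bias parameters recover
strongly (r ≈ 0.8–0.9 for b and π), ξ and α moderately (≈ 0.55–0.9), and
τ weakly (r ≈ 0.4–0.5) because the realistic between-participant spread of
τ (SD ≈ 3) is comparable to its per-session measurement noise. Doubling
the session length raises all recovery correlations. This ordering is
fortunate for the scientific question: the Pavlovian parameter π is the
best-recovered quantity in the family.

Model recovery simulates from every model, fits all six, assigns winners
by lowest AIC (ties split), and row-normalises the confusion matrix.
Posterior predictive checks re-simulate sessions at fitted parameters and
compare condition-wise go-rate trajectories (by within-condition
presentation number) against the observed data, reporting the fraction of
bins inside a 95% predictive band across replicates, the per-condition
mean absolute discrepancy, and the Monte-Carlo standard error of the
simulated mean (which shrinks as 1/√n_sims).

## Hierarchical statistics

The behavioural models are estimated with a two-stage summary-statistics
approach. Stage 1 fits each participant's own full-factorial regression
(action × reward × block, sum-to-zero codes ±1, block centered at
−1.5…+1.5): a ridge-penalised logistic regression for go responses (the
unit penalty equals a standard-normal prior per coefficient and guards
against separation in near-deterministic responders) and OLS on
log(rt − shift) for go-response RTs. Stage 2 treats the per-participant
coefficients as Gaussian population draws and reports the flat-prior
Student-t posterior of each population mean: posterior mean, 95%
highest-density interval (symmetric, so HDI and equal-tailed coincide),
two-sided tail probability, and a significance flag when the interval
excludes 0. Because every participant contributes every coefficient, the
random-effects structure is maximal by construction. Measured calibration
on null cohorts: 5% false-positive rate and 95% interval coverage of
planted effects at their nominal levels.

The RT shift is estimated per participant with the closed-form
three-quantile lognormal-threshold estimator
s = (q₁₀·q₉₀ − q₅₀²)/(q₁₀ + q₉₀ − 2q₅₀), clamped below the fastest
response. Being a quantile statistic it is exactly equivariant under
global RT offsets, so a constant added to all RTs moves the shift, not the
slopes. Participants with fewer than 16 usable go responses are dropped
from the RT model. Marginal means can be back-transformed to ms as
shift + exp(log-scale value).

Mental-health moderation fits one model per covariate: the stage-1
coefficients are regressed on the mean-centered covariate, so each design
term yields a population mean and a term × covariate interaction; the
primary test is the reward × covariate slope. Benjamini–Hochberg (step-up,
via statsmodels) is applied across covariates to the primary two-sided
tail probabilities, and intervals are re-reported at the matching adjusted
credible level (1 − largest rejected raw p, or 1 − q/m when nothing is
rejected) — one defensible operationalisation of FDR-corrected credible
intervals, which have no unique definition. Pearson correlations of
per-participant quantities (impatience, fitted parameters) with the
covariates are BH-corrected the same way.

## Synthetic cohort generator

The generator emulates the full study at configurable scale (default 389
participants). Per participant: a discount rate k ~ lognormal(log 0.008,
1.0) (median matched amount ≈ €14, spanning €1–28); MCQ answers and
staircase choices from a hyperbolic discounter with a €1-scale logistic
choice noise (a small fraction of agents fail the stability rule, as in
real samples); a fresh pseudorandom schedule; a session simulated from
true cue-response-bias (M3) parameters; shifted-lognormal RTs; and 17
gamma-marginal covariates via a Gaussian copula on the true π scores.

True parameters draw from hyperdistributions centred on the cohort
summaries typical for this task family: means α 0.21, τ 7.33, ξ 0.17,
b 0.09, π 0.05. α and ξ use lognormals matched to both mean and median
(α 0.21/0.13, ξ 0.17/0.06), reflecting the strong floor-skew of fitted
learning-rate and lapse estimates; τ, b and π use truncated normals with
SDs 3.0, 0.30, 0.30 — dispersions consistent with cohort-level standard
errors at n ≈ 389. In both families the location is solved numerically so
the box-truncated mean equals the target, and the generator verifies means
within Monte-Carlo error. RT effects default to the small log-scale values
characteristic of this task (action +0.01, reward −0.001, action × reward
−0.003, block −0.005, shift 150 ms, log-scale SD 0.25, truncated into the
600 ms response window by redraw). Covariate marginals use gamma
distributions with symptom-scale mean/SD pairs; the default correlation
with π is 0 (a null cohort). The π-covariate correlation, effect sizes and
all dispersions are configurable.

What the generator does *not* emulate: item-level questionnaire responses,
attention checks and practice rounds, post-task titration drift,
within-session non-stationarity beyond the RL dynamics, and any dependence
of RTs on the latent decision process (RTs are generated from the design
cells, not from an evidence-accumulation model). Passing tests on
synthetic cohorts therefore establishes the *estimators'* correctness and
calibration — not that real data satisfy the generative assumptions.

## Problem sizes

Desk-scale defaults keep every analysis on one core in minutes: cohorts of
40–120 participants for fitting demonstrations, 50-agent parameter
recovery, 6 agents per model for model recovery, 20-replicate calibration
and power cells. All entry points accept larger sizes; the study-scale
power cell (n = 389) runs in seconds because the two-stage test is cheap.

## Known limitations

- τ recovery at T = 200 sits near r ≈ 0.45 under realistic dispersion;
  conclusions about individual differences in choice stochasticity from
  single sessions are correspondingly weak.
- The two-stage estimator does not partially pool stage-1 coefficients, so
  it is slightly conservative for participants with extreme, noisy
  estimates; with 200 trials per participant the efficiency loss against a
  full mixed model is small, and calibration is exact in the tested
  regimes.
- The BH-adjusted credible level is one of several defensible mappings
  from FDR control to interval widths.
- Exact uniformity over admissible pseudorandom orders is approximated
  (see Task model).
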