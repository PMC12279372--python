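# Methods

## Task model

The simulated task presents `n_stimuli = 3` stimuli in an interleaved
pseudo-random order.  Each stimulus carries a hidden reward contingency
drawn from {0.2, 0.3, 0.5, 0.7, 0.8} that is constant within a block of
30–35 encounters and changes at every block boundary (a reversal);
7 blocks per stimulus give 714 trials and 18 reversals.  Contingencies
are grouped by outcome noise: *low* (20/80%), *high* (30/70%) and
*random* (50%); stimuli with p > 0.5 are *good* (gambling is correct),
p < 0.5 *bad* (passing is correct), p = 0.5 neutral (excluded from
correct-choice analyses).  A *misleading* outcome is a win on a bad
stimulus or a loss on a good one.

Because 21 blocks must average 34 trials, block lengths cannot be drawn
independently; the generator starts from the even partition and applies
seeded ±1 pairwise transfers, which random-walks over the admissible
compositions.  Contingency sequences are rejection-sampled so that
consecutive blocks of a stimulus always differ and (with ≥5 blocks) each
stimulus visits at least two good and two bad contingencies — without
this constraint occasional draws contain almost no good blocks, which
distorts attainable point totals.  The interleaving draws each next
stimulus with probability proportional to its remaining quota and forces
any stimulus absent for 8 trials, bounding absences at 9 trials.
Outcome valences are pre-drawn per trial from Bernoulli(p), independent
of the agent's action: a play shows the outcome as factual feedback
(±10 points), a pass shows the same draw as fictive feedback (0 points).

The package ships one *canonical schedule* (`canonical_schedule()`,
seed 7, regenerated deterministically).  The human task used a single
fixed pseudo-random series for every participant, so benchmarks treat
the schedule as a design constant and randomize only outcomes, agents
and fits.

## The hybrid model family

Value learning per stimulus, reward signal R ∈ {+1, −1}:

    δ_t = R_t − Q_t(X_t)
    Q_{t+1}(X_t) = Q_t(X_t) + α_t δ_t

Choice by softmax with inverse temperature β over the biased gamble
value V_play = B_play + Q against V_pass = 0.  Counterfactual outcomes
update Q exactly like factual ones; feedback modality enters only
through κ (below).  The learning rate is associability-gated:

    α_t = κ_t · A'_t,      κ_t = logistic(w · x_t)
    A'_t = η |δ_t| + (1 − η) A_t(X_t)

with predictors x = (1, confirmatory, modality), binary features coded
±0.5 so the intercept is a grand-mean logit.  Confirmatory feedback is a
factual win or a counterfactual loss.  The nested variants are M1
(constant α = κ with an intercept-only κ; no associability), M2
(+ associability, intercept-only κ), M3 (+ confirmatory predictor), M4
(+ modality predictor).

Conventions, each of which the package documents because the model
family's literature leaves them open:

* **Update order.**  The associability absorbs the *current* trial's
  |δ| before the value update, so a surprising outcome amplifies its own
  influence on Q.  The lagged alternative (α built from the previous
  encounter's surprise) was implemented and rejected: under the lag, a
  surprise boosts learning on the *next*, usually representative,
  outcome, which makes strong surprise weighting strictly beneficial —
  mean points then increase monotonically in η, erasing the η-cost
  phenomena this package exists to study (the inverted-U of points over
  η, the η–accuracy correlation after double misleading feedback, and
  the drug-direction pattern).  The within-trial order reproduces all of
  them.
* **Bounds.**  |δ| enters the associability update uncapped (natural
  range [0, 2], so A ∈ [0, 2]); α is clipped at 1, the delta-rule
  stability bound, keeping Q ∈ [−1, 1].  Capping |δ| at 1 instead
  compresses the win/loss surprise asymmetry and measurably degrades η
  identifiability.
* **Initial values.**  Q₀ = 0 and A₀ = 1 per stimulus, so the first
  update uses α = κ ("κ is the initial learning rate") and M2 with η = 0
  reduces exactly to M1.
* **Reward coding.**  Internal R = ±1; displayed points ±10.

## Fitting and model selection

Per-subject MAP by L-BFGS-B from `n_starts = 10` random in-bounds
starting points; bounds β ∈ [0, 10], B_play ∈ [−3, 3], κ weights
∈ [−10, 10], η ∈ [0, 1].  Priors: Normal(0, 10²) on the unbounded
parameters (effectively flat), uniform on β, and **Beta(2, 2) on η**.
The η likelihood is shallow at 714 trials (a full profile over [0, 1]
spans only a few nats), and with a flat prior estimates pile up on the
0/1 bounds; Beta(2, 2) is nearly flat in the interior, removes the
pileup, and roughly doubles recovery correlations without moving
well-identified estimates.  The likelihood floor is 10⁻¹² per trial.
BIC = k·ln(n) − 2·lnL̂ with the likelihood (not the posterior) at the
MAP.

Group-level comparison uses the standard variational random-effects
scheme on log evidences (−0.5·BIC by default): Dirichlet(α₀ = 1) updates
iterated to 10⁻⁶, exceedance probabilities from 10⁵ seeded Dirichlet
draws, the Bayes omnibus risk from the free-energy comparison with the
equal-frequency null, and protected exceedance
pxp = (1 − BOR)·xp + BOR/K.

η is weakly identified in absolute terms: its fitted-value error SD is
≈0.09–0.16 depending on the generating regime.  The recovery benchmark
therefore uses a sharp-choice, symmetric-feedback regime
(β ~ U(2, 4), B_play = 0, κ weights (1, 1), η ~ U(0.1, 0.5)), where the
true fitted-vs-true correlation is ≈0.75 (β ≈ 0.89).  At the strongly
confirmation-biased cohort anchors the same correlation drops to ≈0.5 —
an honest identifiability limit of 714 binary choices, stated here so
that recovery numbers are read against the right baseline.

## Behavioral analyses

*Learning curves* average correct choice (play good / pass bad) per
trials-since-reversal position over post-reversal blocks, split by the
new contingency's noise level; a ±2-trial running mean (shrinking at
edges) is applied last and never before fitting.

*Breakpoints*: segmented least squares with per-segment intercept+slope,
minimum segment length 5, at most ⌊n/5⌋ − 1 breaks (5 for a 30-point
curve).  Dynamic programming yields the exact optimal placement per
break count (verified against exhaustive enumeration); the break count
is selected by the modified Schwarz (LWZ) criterion, whose inflated
penalty 0.299·(ln n)^2.1 per parameter compensates for optimizing the
placement before penalizing — a plain BIC reports spurious breaks on
~15% of pure-noise curves, LWZ on ~1%.  The first break splits learning
into early/late stages (the canonical split is position 10/11).

*Learning-rate SNR* = mean over reversals of the peak α within the first
5 post-reversal encounters, minus the mean over late-stage (positions
11+) misleading-feedback events of the peak α within the next 5
encounters of that stimulus.  The contrast is invariant to adding a
constant to all α values.  Peaks pool all noise levels; restricting both
terms to high-noise blocks reverses the drug-direction effect because
reversal peaks there are more η-dependent than noise peaks.

*Double-misleading accuracy*: among 30/70% stimuli, the probability that
the encounter following two consecutive late-stage misleading feedbacks
(within one block) is a correct choice.

*Performance regression*: OLS of total points on z-scored parameter
estimates with normal-theory intervals; rank-deficient designs raise an
error naming the collinear columns.

*η sweep*: mean total points per η on a grid, all other parameters
fixed; at the low-performer anchors the curve peaks at low-to-
intermediate η (≈0.2–0.3) and loses ≈120 points in the 0.8–1.0 band.

## Volatility/stochasticity filter

Generative model: reward rate x follows a Gaussian random walk with
variance v (volatility); outcomes are Gaussian around x with variance s
(stochasticity).  The inverses z = 1/v, y = 1/s evolve by multiplicative
Beta noise, z' = η⁻¹ z ε with ε ~ Beta(0.5η/(1−η), 0.5) and η = 1 − λ,
which leaves z a martingale (E[ε] = η); λ_v, λ_s act as update rates
(defaults 0.1, configurable — no canonical values exist).  Inference is
Rao-Blackwellized: a particle filter (default 1000 particles) over
(z, y) with Gaussian-predictive weight updates and systematic resampling
iff ESS/N < 0.5 (strict), and per-particle Kalman recursions
δ = o − m, α = (w+v)/(w+v+s), m' = m + αδ, w' = (1−α)(w+v).  Reported
trajectories are weight-averaged.  With λ → 0 and fixed v, s the
learning rate converges to the closed-form fixed point
α* = (−v + √(v² + 4sv))/(2s), which the tests verify.  Initial beliefs:
m₀ = 0.5, w₀ = 0.1, v₀ = s₀ = 0.1; the lesioned variant clamps s at
0.001 on every particle, forcing outcome noise to be read as volatility.

Task-structured runs use one filter per stimulus.  Gaussian outcome
streams (variance 0.01 low / 0.02 high / 0.05 random noise) serve the
volatility/stochasticity trajectory analyses; choice simulations feed
the filter the schedule's binary win/loss stream so that the outcomes
driving the agent are the same ones a subsequently fitted choice model
sees.  Choices apply a softmax with decision noise 3 to the gamble's
expected reward signal 2m − 1 (on the raw probability-scale belief the
softmax saturates at ≈0.82 and masks model differences).  Fitting M3 to
these agents yields higher η for the lesioned model and lower late-stage
accuracy under high outcome noise — the lesion phenotype mirrors
low-performing subjects.

## Synthetic cohorts

Cohorts cross baseline-performance group (low/high) with session
(placebo/drug) in a paired within-subject design: one base parameter
draw per subject; only η shifts between sessions (plus a 0.02 session
jitter); a subject's two sessions share outcome and choice random
streams, so paired contrasts isolate the η shift.  η anchors are the
reported group means (low 0.33 → 0.24, high 0.26 → 0.23), as are β
(2.11 low, 2.97 high) and play bias (0.04, −0.01); between-subject SDs
follow the convention SD ≈ SEM·√47 applied to reported SEMs.  The κ
anchors are the generator's own design (the source intercepts cannot be
mapped without an unreported confirmatory weight): low performers learn
from confirmatory and disconfirmatory feedback alike
(w = (0.5, 2.0)), which exposes them to misleading outcomes and makes η
consequential; high performers are confirmation-biased and shielded
(w = (−0.5, 3.0)).  This reproduces the group phenotypes — late-stage
high-noise accuracy ≈0.70 vs. ≈0.78, and an η-reduction benefit
(accuracy ≈ +0.005, SNR ≈ +0.002–0.004) confined to the low group.  The
per-subject effects are small relative to realization noise, so
direction checks use 400 subjects per group.

## What the synthetic data do and do not show

The generator emulates the task's structure and the model family's own
behavior; passing tests demonstrate internal consistency (correct
implementation, recoverability, reproducible directional effects), not
facts about human learners.  Real data add response-time structure,
missed trials, attention lapses, working-memory strategies and
session-order effects, none of which are modelled.  Point totals depend
strongly on the realized contingency layout, so only within-schedule
contrasts are meaningful.  Reported human effect sizes are not
reproduction targets; only directions of effects are.

## Numerical notes

All stochastic components take explicit integer seeds and are
deterministic given them.  The likelihood/simulation recursions are
numba-compiled with exact IEEE semantics (no fastmath); the pure-Python
fallbacks are bit-identical and cross-checked in the tests.  Degenerate
inputs are contracts, not crashes: infeasible task configurations raise
a configuration error, curves too short for a break are flagged with
zero breaks, undefined metrics (no misleading events, no qualifying
double-misleading sequences) return NaN with a warning, and particle
weight underflow falls back to uniform weights with a warning.
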