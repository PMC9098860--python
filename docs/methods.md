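# Methods

`cpatt` estimates the short-term average treatment effect on the treated
(ATT) for orthopedic/neurological treatments evaluated at four outcome
levels — body structures, specific gait kinematics, overall gait
kinematics, and functional mobility — from observational limb-level
cohorts. Because no such cohort is publicly deposited, the package ships a
synthetic-cohort generator that reproduces the statistical structure the
estimators must survive, together with the ground truth needed to test
them. This note documents the models, the generator, the numerical
choices, and what the tests do and do not establish.

## Causal framework

We work in the potential-outcomes framework. Each observation is one lower
limb at one treatment episode; subjects contribute up to two limbs, and
no independence across limbs of a subject is assumed anywhere (intervals
use a limb-level bootstrap). For a binary index treatment `z` and outcome
measured at baseline and follow-up, the estimand is

    ATT = E[ Y(1) − Y(0) | z = 1 ],

reported both in outcome units and as Cohen's d. All three estimators
assume ignorability given the covariate set: conditioning on the baseline
covariates (including the baseline value of every outcome) removes
confounding. The synthetic generator deliberately violates this slightly —
assignment depends on a latent severity factor observed only through noisy
proxies — so the tests measure robustness under realistic, not idealized,
conditions.

### Direct matching (DM)

One-to-one optimal-subset matching solved as a mixed-integer program
(HiGHS via `scipy.optimize.milp`):

* **Distance** — Mahalanobis distance on pooled ranks of the
  treatment-specific distance covariates (ties get average ranks; the rank
  covariance is pseudo-inverted when singular). Rank transformation makes
  the distance insensitive to heavy tails and monotone rescalings.
* **Propensity caliper** — pairs whose propensity gap exceeds 0.2 pooled-SD
  units incur a large additive penalty (soft caliper; default penalty
  2 × subset weight, i.e. a violating match is worse than leaving the limb
  unmatched).
* **Near-fine balance** — for every prior and interval co-treatment flag,
  the matched groups' counts may differ by at most 3% of the matched count
  (+1). Infeasible programs are relaxed along a fixed ladder (slacks ×2,
  ×4, then dropped) and the relaxation level is reported.
* **Moment balance** — optional per-variable constraint
  |matched mean difference| ≤ 0.05 pooled SD.
* **Optimal subset** — each unmatched treated limb costs the subset
  weight, by default the median of the distance matrix.

For tractability on large cohorts, candidate edges are pruned to each
treated limb's 12 cheapest controls and the solver accepts a 0.2% relative
optimality gap (both configurable; dense solves on small instances are
exact, which is what the brute-force oracle test checks). Ties among
equal-objective solutions are broken deterministically by the solver seed
path and pair lists are emitted sorted by treated id.

The DM effect is the mean over pairs of (change of treated limb − change
of matched control limb), where change = follow-up − baseline.

### Virtual twins (VT)

A single BART regression of the follow-up outcome on the uniform covariate
set (all exam covariates, classifications, prior and interval treatment
flags including the index flag, the four baseline outcomes, follow-up
interval). For each treated limb a *twin* row is created with the index
flag set to 0 and everything else unchanged; the per-limb effect is the
posterior-mean difference between the actual and twin predictions, and the
ATT averages these over the sample (matched subset or all treated).

### Bayesian causal forest (BCF)

The outcome is decomposed as

    y = μ(x, π̂) + τ(x) · z + ε,      ε ~ N(0, σ²),

with a prognostic forest μ (200 trees, tree-prior base 0.95 / power 2)
that sees the covariates plus the estimated propensity π̂, and a
treatment-moderating forest τ (200 trees, base 0.95 / power 3) fit by
Bayesian backfitting on the treated rows' residuals. Feeding π̂ to μ is
the defense against *targeted selection*: when assignment tracks expected
prognosis or benefit, a regularized outcome regression pushes that
association into the treatment term (regularization-induced confounding);
a single μ-split on π̂ absorbs it cheaply. By default π̂ is not given to
the τ forest (a switch enables it), matching the reference convention;
whether the moderating forest should also see π̂ is genuinely open, and
reports flag which convention was used.

The τ leaf prior is adaptive: leaf values are N(0, σ_τ²) with a
half-normal hyperprior on σ_τ of scale 0.674·SD(y)/√200, updated each
sweep by a log-scale random-walk Metropolis step. This adaptivity is
essential, not cosmetic: with 200 moderating trees a *fixed* leaf scale
prices a global offset at essentially zero prior cost, so the τ forest
soaks up whatever confounding μ has not explained, producing a systematic
null bias that the adaptive scale suppresses by collapsing σ_τ when the
data carry no effect. Only data-informed leaves (those reached by treated
rows) enter the hyperprior update; empty leaves hold fresh prior draws and
carry no information about the scale. The flip side of this adaptivity is
a small multiplicative shrinkage of genuine homogeneous effects — the
calibration/robustness tests quantify both faces of the tradeoff.

The BCF ATT is the posterior-mean τᵢ averaged over the treated limbs of
the requested sample.

### Propensity scores

Probit BART (Albert–Chib latent-normal augmentation, σ ≡ 1, leaf scale
3/(k√m)) on the same uniform covariate set minus the index flag.
Reported discrimination metrics (accuracy, sensitivity, specificity, AUC
by the rank statistic) come from an honest random-half holdout refit, not
from in-sample scores.

### Effect sizes, intervals, and categories

Cohen's d divides the raw ATT by the SD of the outcome change over all
analysis limbs (treated + controls). The standardizer is logged and
configurable; alternatives (control-change SD, baseline SD) change only
the scale, not the sign pattern. 95% intervals use 1000 percentile
bootstrap replicates resampling limbs (pairs, for DM); for VT and BCF each
replicate additionally samples one retained posterior draw, so the
interval carries model uncertainty as well — with shrunken per-limb point
effects, resampling alone can produce degenerate, badly undercovering
intervals. Categories follow the conventional thresholds on |d|: small
≥ 0.2, medium ≥ 0.5, large ≥ 0.8, very large ≥ 1.2, half-open upward;
estimates whose CI straddles zero keep their point-estimate category and
carry a `borderline` flag. The level-wise summary is the median and IQR
of d pooled over treatments and the five estimates per treatment
(DM-matched, VT-matched, VT-all, BCF-matched, BCF-all); a config option
first averages within treatment instead, since either pooling is
defensible.

## The BART engine

The sampler is a from-scratch Metropolis-within-Gibbs implementation of
the standard sum-of-trees model: m trees with
p(split at depth d) = base·(1+d)^(−power), conjugate N(0, σ_μ²) leaves
integrated out in the move acceptance, grow/prune/change proposals
(0.28/0.28/0.44), leaf values redrawn conjugately after every tree update,
and σ² from a scaled inverse-χ² full conditional (ν = 3 calibrated so the
prior puts 90% mass below the sample SD). Continuous responses are
rescaled to [−0.5, 0.5]; defaults are the published defaults of the
standard BART tooling (m = 50, base 0.95, power 2, k = 2). Numerical
conventions: split candidates are the unique observed values within the
leaf (excluding the minimum; `x < c` goes left), so both children are
always non-empty; trees are capped at depth 6 (the prior makes deeper
nodes vanishingly rare; the cap truncates the prior explicitly); factors
are one-hot encoded with "Miss" as an ordinary level, so trees split on
level indicators and an unseen level at prediction time encodes as
all-zero indicators. Hot loops are numba-compiled; a fit stores every
retained forest, so posteriors are serializable and predictions are exact
re-evaluations. Same seed ⇒ bit-identical posterior.

Degenerate inputs: a constant response short-circuits to an exact constant
posterior; a constant covariate simply never yields a valid cutpoint; probit
fits refuse single-class labels.

## The synthetic generator

The generator is the package's study-condition definition, not a test
fixture. Per subject: a standard-normal severity latent S; limbs get
L = √ρ·S + √(1−ρ)·e with within-subject correlation ρ = 0.5. Covariates
load on L: continuous exam measures with clinically plausible means and
signs, ordinal scores by thresholding latent Gaussians (monotone in
severity), GMFCS and topography at subject level. Functional mobility is
measured by a 23-item questionnaire: ordinal skill items generated from a
latent mobility score with per-item difficulties; the functional score is
the difficulty-weighted item average (weights fixed in config — real
calibration weights are not public, so they are a free parameter of the
emulation).

Treatment assignment is π(x) = expit(f(x) + λ·τ̃₁(x)) with f = 1.2·L
(prognosis-based confounding: the same L drives outcome drift) and τ̃₁ the
standardized level-1 effect; λ is the targeted-selection dial. Effect
heterogeneity is driven by centered age — independent of L — so that at
λ = 0 the propensity is uncorrelated with the effect (the defining
signature of absent targeted selection) while confounding persists. The intercept is calibrated by
bisection so realized prevalence hits its target (0.30 for the first
treatment, a 0.05–0.20 ramp for the other co-treatments).

Outcome changes follow change_k = −0.35·L + 0.15·(interval − mean)
+ Σ_j z_j·τ_k(x) + noise_k, with τ_k(x) = δ_k·(1 + 0.3·age_std) and a
default attenuating profile δ = (0.45, 0.22, 0.10, 0.02) — effects
propagate and wash out along the causal chain. All interval treatments
share the profile; prior treatments shift baselines only. Missingness
blanks categorical covariates, one continuous exam measure, and
questionnaire items at configurable rates (default: 20% GMFCS, 4% per
item), optionally shifted by GMFCS level to emulate informative
missingness. `null_change_sd` reports the change SD of the same design
with effects zeroed, so scenarios can state effects in change-SD units
without circular calibration.

What the generator does **not** emulate: raw kinematic waveforms, real
covariate joint distributions (not publicly characterized — ours are
stipulated), treatment-specific outcome measures (each level has one
shared outcome column), SEMLS-style interaction effects, or outcome-level
missingness. Passing tests therefore show the estimators survive
*this* selection/confounding/heterogeneity structure at desk scale; they
do not certify performance on any particular clinical database.

## Preprocessing rules

Eligibility: age < 25 years, follow-up in [0.75, 2.5) years (nine to under
thirty months), knee varus-valgus ROM ≤ 15°. Blank categorical/ordinal
entries become the literal level "Miss". The functional score is computed
when ≥ 18 of 23 items are present; with 18–22 items the missing items are
filled by single-pass ridge regressions (α = 1) of each item on the others,
trained on complete rows — a deliberate simplification of chained
equations, adequate for near-complete rows; below 18 items the score stays
missing and the row is excluded from functional-mobility analyses. Rows
with missing continuous covariates are dropped listwise before modeling.
SMDs use pooled-SD standardization for continuous variables and the
multivariate (Yang–Dalton) form √(dᵀS⁻d) over K−1 level proportions for
factors, with a pseudo-inverse when the pooled multinomial covariance is
singular.

## Problem sizes and budgets

Defaults were chosen as the smallest sizes at which the statistical
properties are comfortably measurable: cohorts of 400 subjects (800
limbs), 20 simulation replicates for calibration/recovery/robustness
properties, and a reduced MCMC budget of 250 burn-in / 500 retained draws
for routine runs. A `full_mcmc` switch restores the full 1000/1000
budget for final analyses; results at the two budgets agree well within
bootstrap uncertainty in our checks. The bootstrap uses 1000 replicates.

## Known limitations

* Ignorability is assumed; the generator's latent-severity design induces
  a small irreducible confounding that no estimator can remove.
* The bootstrap does not refit BART/BCF per replicate; model-uncertainty
  is injected via posterior-draw resampling instead of full refits.
* The matching solver's default edge pruning and optimality gap trade a
  provably optimal solution for speed on large cohorts; exactness is
  guaranteed (and tested) only on dense small instances.
* Single-chain MCMC with fixed burn-in; σ traces are retained but no
  automated convergence diagnostic gates the output.
* The categorical "Miss" level treats missingness as informative but
  cannot distinguish mechanisms; continuous-covariate missingness is
  handled by deletion, not imputation.
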