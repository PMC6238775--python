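# Methods

This note documents the models implemented in `pheasantcog`, their
assumptions, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical decisions that a user
re-running or extending the analyses should know about.

## Study design being modelled

A cohort of male pheasants is tested on a binary spatial discrimination
("top–bottom") task twice: as chicks (up to 30 trials: three sessions of 10)
and as adults (100 trials: five sessions of 20). Between the two assays the
birds live through hierarchy formation; adult social rank is inferred from
winner–loser agonistic interactions collected ad libitum in a multi-male
multi-female group aviary (SG condition). Adult cognitive testing happens
while each male is housed alone with two or four females (PD, "perceived
dominance" — a standardised, non-competitive social rank). Display behaviours
(crowing; lateral struts) are recorded in both conditions as a manipulation
check. Three questions structure the analysis: (1) is learning performance
consistent from chick to adult, (2) does chick performance predict adult
rank, (3) does rank-related variation in adult learning persist once rank is
standardised.

## Social rank: randomized Elo-ratings

Sequential Elo scoring updates ratings contest by contest: the winner's
expected score is `E = logit⁻¹((r_w − r_l)/s)` and both ratings move by
`k·(1 − E)` (winner up, loser down), which conserves the rating total
exactly. Because the ad libitum observation order is arbitrary, the sequence
is re-scored over `n_randomizations` uniformly random permutations of the
contest order and each bird's rating is averaged across replicates ("mean
Elo-rating"). Two diagnostics summarise hierarchy certainty:

- **Repeatability** `r`: the among-individual share of rating variance across
  replicate orderings, from one-way ANOVA variance components (individuals as
  groups, orderings as repeats). Steep, well-resolved hierarchies give `r`
  near 1; a flat hierarchy gives `r` near 0. Estimates are reported raw and
  may be negative; zero total variance is flagged NaN rather than guessed.
- **Split-half reliability**: the records are partitioned into two random
  near-equal halves, each half scored by the randomized-Elo procedure, and
  the two mean-rating vectors Spearman-correlated over the individuals present
  in both halves (fewer than 3 shared individuals: the split is skipped with a
  warning). Repeating over `n_splits` partitions gives a mean and 2.5%/97.5%
  quantiles.

**Constants.** The Elo update constants are conventions, not estimands — they
rescale ratings without changing rank order — and the original tooling's
values are not stated anywhere recoverable. Defaults: `k = 200`, initial
rating 0, logistic expected-score scale `s = 200` rating points,
`n_randomizations = 1000`, `n_splits = 100`. Every `HierarchyEstimate`
carries its config so outputs are traceable. Splits are uniformly random
rather than temporal because no ordering of the split is defined for
ad libitum data; a temporal split can be built by the caller from the
`order` column if wanted.

## Learning curves and derived metrics

Per (individual, phase), outcome is regressed on raw 1-based trial index by
maximum-likelihood logistic regression over a fixed window — first 20 trials
by default, so chick and adult curves are directly comparable; the full
available series can be requested. Two metrics follow:

- `x_final = logit⁻¹(b₀ + b₁·T)` with `T` the window's last trial: accuracy
  at the end of testing. `T` is the window end, not the bird's lifetime last
  trial, because cross-phase comparability is the point of the window.
- `y80 = (−ln 0.25 − b₀)/b₁`: the (possibly fractional, possibly negative,
  possibly beyond-window) trial at which the fitted curve crosses 80%
  correct. Undefined and NaN-flagged when `b₁ = 0`; negative values mean the
  criterion was already met before trial 1 and are reported as-is.

**Separation.** Short binary series separate easily (an all-correct bird has
no finite ML fit). Optimisation is bounded at |b| ≤ 15 — far outside any
behaviourally meaningful slope, so the bound never binds on regular data —
and a fit touching the cap (or with constant outcomes) is flagged
`separated`. Metrics are still computed from the capped fit but should be
read through the flag; they are not silently dropped, so the caller decides.

## Association and paired tests

- **ICC**: one-way random-effects intraclass correlation
  `(MS_among − MS_within)/(MS_among + (k−1)·MS_within)` with the F-based
  confidence interval; negative estimates reported raw. The one-way form is
  the right one here because the two "raters" (chick phase, adult phase) have
  no identity to condition on.
- **Spearman**: midrank ties; exact permutation p (full n! enumeration) for
  n ≤ 9, which covers the study's sample sizes, else the large-sample
  approximation. Two-sided.
- **Wilcoxon signed-rank**: zeros dropped, magnitudes midranked. Exact p only
  when no zeros were dropped and no magnitudes tie; otherwise normal
  approximation with continuity and tie corrections. This policy is fixed by
  the crow-rate contrast (10 paired males, two zero differences, printed
  p = 0.014): the exact test on the 8 nonzero differences would give 0.008,
  so the reference analysis demonstrably used the approximate path once zeros
  appeared. The same fixed policy applied to the adjusted strut increases
  gives p ≈ 0.09, not the printed 0.002; that printed value is inconsistent
  with the printed per-male rates under any standard signed-rank variant, and
  the package deliberately does not contort to reproduce it.
- **Standardization**: mean 0, sample (ddof = 1) SD 1.

## Trial-level GLMM

Adult choices on trials 2–100 are modelled as Bernoulli with logit link:
fixed effects for z-scored trial index, z-scored mean Elo-rating, their
interaction, number of females (factor, reference 2), cohort (factor,
reference I) and first-trial choice; a Gaussian random intercept per male.
Trial 1 is removed from the response and becomes the `first_choice`
covariate, since it precedes any learning opportunity. z-scores are computed
over the analysis rows (all males × trials 2–100).

**Estimation** is maximum likelihood — not REML — because fixed effects are
tested by likelihood-ratio tests of nested models on identical rows. The
marginal likelihood integrates the random intercept per male with *adaptive*
Gauss–Hermite quadrature: each male's integrand is re-centred at its
posterior mode (inner Newton iterations; the joint log-density is strictly
concave) and scaled by its curvature, then the Gauss–Hermite rule applied.
Order 15 by default; order 1 reproduces the Laplace approximation; order 25
changes cohort-scale log-likelihoods by under 1e-4. The outer optimiser is
L-BFGS-B with numerical gradients, σ bounded below by 1e-8, started from the
plain-logistic IRLS fit with σ = 0.5; because the profile in σ can be
locally flat near the boundary, a small σ grid is probed at the optimum and
optimisation restarted if anything beats it. Fits match `lme4::glmer`
(`nAGQ = 15`) to ~1e-5 in log-likelihood on simulated data.

**Random-structure check.** The intercept-only model is compared to a
correlated random-intercept+slope model (slope on z-scored trial;
unstructured 2×2 covariance via log-Cholesky; 2-D adaptive quadrature,
9 points per dimension) by LRT with df = 2 (slope variance + covariance).
The chi-square boundary correction is deliberately ignored, making the test
conservative; this mirrors how the reference analysis reports a plain
chi-square.

**Model search.** The minimum adequate model comes from backward elimination
by LRT at α = 0.05, never removing a main effect while its interaction is
retained. Odds ratios are `exp(estimate)`; tables report Wald 95% bounds on
both the link and odds scales.

## Display rates and the manipulation check

Rates are events per summed observation hour per (male, condition,
behaviour), so splitting a watch into records cannot change a rate. Crow
rates are never female-adjusted (a crow has no receiver); lateral struts are
divided by the number of females housed with the male (19 in SG; 2 or 4 in
PD) because available display targets differ enormously between conditions,
and only struts clearly directed at females are counted (records carry a
direction flag; male-directed and ambiguous records are excluded). The
SG→PD contrast is the per-male increase (PD − SG) tested by the signed-rank
policy above, with sign tallies reported alongside p.

## Synthetic cohorts: what they emulate, and what they don't

- `simulate_interactions`: `P(i beats j) = logit⁻¹(steepness·(aᵢ − aⱼ))`,
  dyads drawn uniformly (default) or with geometrically rank-biased weights.
  The logistic win model matches the Elo family being estimated downstream —
  a deliberate choice over a Thurstonian (probit) model. Default dimensions
  follow the cohort regime: 12 individuals, ~1,000 interactions, steepness 2
  (steep enough that certainty diagnostics sit above 0.9, as observed in the
  real cohorts).
- `simulate_trials`: Bernoulli outcomes from each bird's logistic curve.
  Population defaults (`b₀ ~ N(−0.7, 0.6)`, `b₁ ~ N(0.10, 0.05)`) describe
  birds starting near chance and typically crossing 80% within ~20 trials.
  Helpers impose chick→adult parameter correlation or rank–slope coupling
  (`b₁ = b̄₁ + coupling·ability + noise`) for power studies.
- `simulate_display_counts`: Poisson(rate × hours) counts; the bundled
  scenario doubles PD rates over SG.

Not emulated: observation bias (missed or misclassified interactions),
within-session dependence of trials (every trial is conditionally
independent given the curve), drift in rank over the observation window,
motivational dropout, and any spatial structure. Passing tests therefore
certify the estimators against their own model families — recovery, size and
power under correctly specified sampling — not robustness to the field
realities above. Truth objects are written as YAML sidecars next to each
dataset so tests never re-derive them.

## Problem sizes used in tests and the acceptance script

The study conventions (1,000 randomizations; 100 splits) are the package
defaults. The automated checks run the same estimators at reduced Monte-Carlo
scale — typically 100–200 randomizations, 10–50 splits, quadrature order
9–15, and 5–400 simulation replicates depending on the statistic — sizes at
which every targeted property is already stable (e.g. mean-Elo rank order is
identical at 200 vs 400 randomizations on a steep cohort). The GLMM recovery
check uses 400 replicate cohorts of 8 males × 99 trials so that the
Monte-Carlo error of its own 2-standard-error criterion is small.

## Known limitations

- Elo constants are conventions; absolute rating scales are not comparable
  across configs (rank order and diagnostics are).
- The published hierarchy table (repeatability 0.984/0.996) cannot be
  reproduced without the raw interaction data, which was never deposited; the
  package reproduces the *regime* on synthetic steep hierarchies instead.
- The printed strut-rate p = 0.002 is inconsistent with the printed per-male
  strut rates (see above) and is intentionally not reproduced.
- Exact Spearman enumeration is factorial; it is capped at n ≤ 9 by default.
- ML variance components with ~8–12 groups are noticeably downward-noisy
  (σ̂ may hit 0); this is a property of ML at these sizes, shared with
  `glmer`, not an implementation artefact.
- The deposited per-individual supplementary files must be exported to CSV
  and mapped (`datasets.load_supplementary`) before the three
  published-value reproductions in the acceptance tests can run; their exact
  headers are not described in the article, so the default column mapping is
  a documented guess to be adjusted against the real files.
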