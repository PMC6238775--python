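# pheasantcog

Statistical machinery for captive cognition studies that ask whether an
animal's position in a dominance hierarchy is a cause or a consequence of its
learning ability — built around the design used with male pheasants
(*Phasianus colchicus*): spatial-discrimination learning assayed as chicks and
again as adults, social rank inferred from agonistic interactions in a group
aviary, and adult learning re-assayed under a rank manipulation (each male
housed alone with females, experiencing conditions synonymous with high rank).

The package provides, as a tested library plus thin analysis drivers:

- **Randomized Elo-ratings** — social rank from winner–loser records, with the
  order-dependence of sequential Elo removed by averaging over many random
  re-orderings of the contest sequence. Hierarchy certainty is quantified by
  the repeatability of ratings across replicate orderings (one-way variance
  components) and by split-half Spearman reliability.
- **Logistic learning curves** — per-individual ML fits of
  `P(correct at trial t) = 1/(1 + exp(−(b₀ + b₁ t)))`, with the two derived
  metrics: accuracy on the final trial of the window, `x_final = logit⁻¹(b₀ +
  b₁·T)`, and trials to the 80% criterion, `y80 = (−ln 0.25 − b₀)/b₁`.
  Complete separation is capped (|b| ≤ 15) and flagged.
- **Small-sample inference** — one-way ICC with F-based intervals, Spearman
  correlation with exact permutation p for n ≤ 9, Wilcoxon signed-rank with a
  fixed zero/tie policy (zeros dropped; exact p only when no zeros or
  magnitude ties; otherwise normal approximation with continuity correction),
  and z-standardization.
- **Binomial random-intercept GLMM** — maximum-likelihood, with the random
  intercept integrated out per individual by adaptive Gauss–Hermite
  quadrature; likelihood-ratio tests, backward elimination to a minimum
  adequate model, and a correlated random-intercept+slope variant for testing
  the random structure (2-D adaptive quadrature).
- **Rank-manipulation check** — display rates per hour (crowing,
  female-directed lateral struts with female-density adjustment) contrasted
  between the social-group (SG) and perceived-dominance (PD) conditions.
- **Synthetic cohorts with known truth** — steepness-parameterised latent
  hierarchies (win probability logistic in ability difference), logistic
  learners with optional chick→adult correlation or rank–slope coupling, and
  Poisson display counts, so every estimator is testable without any raw data.

The published per-male display-rate table ships with the package
(`pheasantcog.datasets`); the deposited per-individual datasets do not, but
column-mapped adapters (`datasets.load_supplementary`) accept CSV exports of
them for the full reproduction.

## Worked example

The numbered drivers under `analysis/` run the whole design on a synthetic
cohort (12 males, 1,044 interactions, 30 chick + 100 adult trials each):

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_infer_hierarchy.py --seed 1
python analysis/03_fit_learning_curves.py
python analysis/04_consistency_and_rank.py
python analysis/05_adult_glmm.py
python analysis/06_rank_manipulation.py
```

Output (seed 1, abridged):

```
hierarchy over 12 males, 1044 interactions
  repeatability r = 0.910
  split-half r_s  = 0.986 [0.965, 1.000]
  Spearman(mean Elo, latent ability) = 1.000
...
Q2 association (n = 12):
  r_s(x_final, mean Elo) = -0.371 (p = 0.236, large-sample)
...
single-term LRTs:
       trial:elo: chi2 =  77.715, df = 1, p = 0.0000
minimum adequate model keeps: ['elo', 'trial', 'trial:elo']
random slopes needed? chi2 = 4.514, df = 2, p = 0.105
...
crow: 8 males increased, 2 unchanged, 0 decreased; W+ = 36.0 on n = 8,
      two-sided p = 0.0143 (normal-cc)
```

Reading this like the study: the simulated hierarchy is steep, so both
certainty diagnostics exceed 0.9 and mean Elo recovers the latent order
exactly. Chick learning parameters were generated independently of rank, and
the Q2 Spearman correlations are correspondingly unremarkable. Adult learning
*slopes* were coupled to rank, and the GLMM finds exactly that: a strongly
significant trial × rank interaction (higher-ranked males learn faster), all
nuisance terms eliminated, and no evidence that random slopes are needed
beyond the rank effect. The last two lines are real data — the published
per-male crow rates — where 8 of 10 males crowed more under the perceived
dominance manipulation (p ≈ 0.014).

A `pheasantcog` console script exposes the same stages
(`simulate`, `hierarchy`, `learn`, `q1`, `q2`, `q3`, `all`), each taking
`--seed` and `--config` (YAML; see `pheasantcog.io_formats.RunConfig`).

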