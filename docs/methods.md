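# Methods

## Model

`ltpasim` simulates weekly leisure-time physical activity (LTPA) in a
stylized adult community. The decision core is an extension of the
Continuous Opinions and Discrete Actions (CODA) family of opinion
models: each person carries a continuous internal intention, stored on
the log-odds scale, and emits a discrete weekly action (practiced /
did not practice). Observing an action — one's own or a neighbor's —
is treated as Bayesian evidence about whether practicing is the best
option, shifting the log-odds intention by `ln(alpha / (1 - alpha))`
per observation, where each `alpha` is the confidence that the
observed behavior reflects the best option.

Assumptions worth making explicit:

* **Synchronous weekly dynamics.** All intention updates read only the
  previous week's state, so the step is order-independent; behavior at
  week *t* is then drawn independently per person from the logistic
  transform of the new intention.
* **Static built environment.** Perceived site utilities are computed
  once at initialization and never change; the environment term
  `y = logit(u_max) / r` is a constant per person. Persons with no
  site inside their perception radius contribute `y = 0` and are
  barred from practicing.
* **Bounded intention.** Intention is hard-clamped to
  `[-L, L]`, `L = ln(0.97/0.03)`, which keeps the intention strength
  `w = 1 - |i|/L` in `[0, 1]` and the practice probability in
  `[0.03, 0.97]`. The bound models residual behavioral noise (illness,
  vacations) at both extremes. A consequence of the clamp is that the
  extremes are absorbing for the intention (not for behavior): once a
  person reaches `|i| = L`, `w = 0` and no further influence moves
  him.
* **Signed behavior codes.** Behaviors enter the social and habit
  increments as +1 (practiced) / -1 (did not). With the alternative
  {0, 1} coding and any `alpha > 1/2`, observations could only raise
  intention and the low-intention group could never grow, contradicting
  the population patterns the model targets. The `behavior_coding`
  switch ("pm1" / "01") allows exploring the other convention.
* **Non-toroidal grid, plain Euclidean distances** between patch
  centers; several persons may share a patch; "within the radius"
  means a closed ball, applied identically to sites and community.

## Parameters

| field | default | units / domain | meaning |
|---|---|---|---|
| `grid_side` | 50 | patches | square grid side |
| `n_persons` | 2000 | persons | population size |
| `prop_ltpa_sites` | 0.025 | fraction of patches | LTPA site density (calibrated) |
| `mean_ql`, `sd_ql` | 0.5, 0.2 | quality scale [0,1] | site-quality Normal, truncated to [0,1] (calibrated) |
| `n_activity_types` | 10 | — | available LTPA types |
| `perception_radius` | 9.0 | patches, domain [0, grid side] | perception range for sites and community |
| `k_network` | 5 | persons | proximal-network size (calibrated) |
| `p_rewire` | 0.15 | probability | per-link rewiring probability |
| `v_mean`, `v_sd` | 0.35, 0.25 | — | per-dyad subjective assessment Normal, truncated at 0.01 (calibrated) |
| `alpha_p`, `alpha_c` | 0.505 | (0,1) | network / community confidence weights (calibrated) |
| `alpha_b` | 0.52 | (0,1) | habit (own-behavior) confidence weight (calibrated) |
| `r_env` | 100 | — | damping of the built-environment term |
| `intention_split_frac` | 0.25 | — | share initialized in the low probability range |
| `intention_low_range`, `intention_high_range` | [0.03, 0.30], [0.31, 0.97] | probability | initial intention ranges |
| `horizon_weeks` | 520 | weeks | simulated horizon (624 in the analysis protocols) |

### Calibration

The site density, quality distribution, subjective-assessment
distribution, network size and the three confidence weights have no
directly observable empirical counterpart, so they were set by
pattern-oriented calibration (`calibrate_baseline`, a seeded random
search): candidate parameter sets are scored against (a) a mean LTPA
prevalence over the simulated decade inside the 35–50 % band reported
for adult populations, and close to the 48 % midpoint trend, (b) a
stable trend (|slope| < 1 percentage point/year of the yearly
prevalence), and (c) a U-shaped final intention distribution (low and
high bands each more populated than the intermediate band). The
shipped defaults meet all three at full scale (measured: mean
prevalence 47.2–47.5 %, |slope| ≤ 0.06 pp/yr, year-10 low/high ≈
0.53/0.47 with the intermediate band near zero, across several master
seeds).

Two calibration choices deserve comment. The confidence weights sit
close to 1/2: because behaviors are re-observed *every week*, and the
social increments aggregate dozens to hundreds of neighbors,
confidences even modestly above 1/2 compound into runaway consensus
(everyone practicing, or no one) within a few simulated years — a
degenerate regime incompatible with any of the target patterns. And
the subjective-assessment scale `v_mean = 0.35` places the median
person's best perceived utility below the 0.5 indifference point, so
the ambient built environment is mildly adverse: this reproduces the
empirical regime in which fewer than half of adults practice LTPA and
the average person is surrounded by more non-practicers than
practicers.

## Outputs

Four weekly population proportions: persons practicing (`prop_ltpa`),
and persons with low (probability-scale intention in [0.03, 0.25)),
intermediate ([0.25, 0.75]) and high ((0.75, 0.97]) intention. The
intention bands are computed from the logistic transform of the stored
log-odds. Analyses sample the series at weeks 52, 104, … ("yearly
data").

## Analysis protocols

* **Consistency** (`consistency_analysis`): for each candidate
  replication count *m*, 20 independent sets of *m* replications are
  generated; per output per yearly point, set 1 is compared with each
  of the other 19 by the Vargha–Delaney A test. Scores are folded
  (`0.5 + |A - 0.5|`) before the median/max summaries so "maximum A"
  measures deviation magnitude regardless of direction. The
  recommendation is the smallest *m* whose worst folded score stays
  below the small-difference threshold 0.56.
* **Robustness** (`robustness_analysis`): one parameter disturbed at a
  time (fourteen parameters: two personal, four social, eight built
  environment), disturbed-vs-baseline distributions A-tested; folded
  scores ≥ 0.71 flag significant sensitivity. Default sweep: five
  evenly spaced values over the documented domain.
* **Global sensitivity** (`global_sensitivity`): Latin Hypercube
  Sampling (one scenario per equal-width stratum per parameter) over
  six parameters — habit weight, perception radius, network and
  community weights, site density, mean quality. Each scenario is
  replicated; the replicate-mean output at each yearly point is the
  scenario-level observation (PRCC assumes one observation per LHS
  row). PRCC is computed by the residual-regression definition
  (rank-transform everything with average ties; regress the target
  column and the output on all other columns with intercept; correlate
  the residuals) and summarized min/max/mean/sd over the yearly
  points, with small (~0.2) / average (~0.5) / high (~0.8) effect-size
  labels.

### Sensitivity domains

The six global-SA domains are: habit weight [0.5, 0.53] (from no habit
formation to full polarization of the intention distribution within
the simulated decade), social weights [0.5, 0.52] (weak-evidence
range; see the calibration comment above), perception radius
[0, grid side] (its whole feasible range), site density [0, 0.03]
(a realistic urban range bracketing the baseline; site scarcity is
what keeps the radius relevant across its whole domain), mean quality
[0.3, 0.7] (the central band of the quality scale around the
baseline). At reduced scale (1000 persons, 100 scenarios, 10
replications each, 12 yearly points) this protocol recovers the
expected structure: perception radius and site density strongly
positive on prevalence, the habit weight strongly negative on the
intermediate intention band and mildly positive on prevalence, the
social weights and mean quality weak.

## Numerical choices

* Intention lives internally on the log-odds scale; initial values are
  drawn on the probability scale (25 % uniform in [0.03, 0.30], 75 %
  in [0.31, 0.97]) and transformed by the logit.
* Raw site utilities are clamped to [0.03, 0.97] so their log-odds are
  finite; the access distance is floored at one patch unit, keeping
  the access share of utility at most 1/3.
* k-nearest-neighbor ties are broken by a random permutation of person
  ids followed by a stable sort; rewired links are redrawn uniformly
  among persons outside the current ego list.
* Truncated normals are sampled exactly (inverse-CDF, via
  `scipy.stats.truncnorm`), not by clipping; a zero standard deviation
  degenerates to a point mass.
* Replication seeds are spawned from a master seed with
  `numpy.random.SeedSequence`, so replicate *r* is invariant to the
  total number of replicates requested; identical (parameters, seed)
  reproduce output CSVs byte for byte.
* Proportions are exact counts over the population; the three
  intention bands partition [0.03, 0.97] (low excludes 0.25, high
  excludes 0.75) and sum to 1 by construction.

## Scale of the shipped checks

The full-scale protocols (80 replications per scenario, 100 scenarios)
are expensive; the package's own acceptance checks run desk-scale
versions chosen to preserve the qualitative structure: the baseline
pattern check uses 20 replications at full population; the consistency
protocol runs m ∈ {1, 5, 20, 80} with 20 sets at 500 persons; the
global sensitivity analysis runs 100 scenarios × 10 replications at
1000 persons. The methods are identical at every scale — only
population and replication counts change.

## What the simulator does and does not show

All inputs are self-generated: the world is synthetic and parameters
are calibrated to reproduce aggregate published patterns, not any
particular place. Passing checks therefore demonstrate internal
consistency of the mechanism and reproduction of stylized facts — not
predictive validity for a real community. Known limitations: no
demographic attributes or heterogeneity in the perception radius;
sites do not adapt; intention is a single scalar rather than separate
psychological constructs; the hard intention clamp makes the extremes
absorbing, so long-run distributions concentrate at the bounds faster
than a model with soft saturation would. Under this clamp the
built-environment influence effectively ends for a person once his
intention freezes, which bounds how dominant the perception radius can
become in the global sensitivity analysis (mean PRCC on prevalence
around 0.77 at the shipped domains).
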