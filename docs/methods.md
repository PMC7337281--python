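# Methods

## Setting and notation

A two-arm randomized trial assigns participant *i* to treatment (T<sub>i</sub> = 1)
or control (T<sub>i</sub> = 0). The outcome y<sub>i</sub> is measured at follow-up
only when the observation indicator S<sub>i</sub> = 1; S<sub>i</sub> = 0 is
attrition. Baseline covariates **X**<sub>i</sub> are measured before assignment.
The naive estimator of the average treatment effect β is the OLS coefficient on
T in y = α + βT + ε fitted on complete cases (identical to the difference in
observed arm means); covariates may be added for precision. Complete-case
analysis is unbiased only under strong missingness assumptions, and those are
what this package is about.

## Attrition diagnostics

`attrition_rates` computes the per-arm observed proportions
q<sub>T=1</sub> = Σ1(T=1, S=1)/Σ1(T=1) and q<sub>T=0</sub> analogously, in
exact rational arithmetic, plus the trimming share
q = (max − min)/max and the identity of the less-attrited arm.

`power_after_attrition` quantifies the power cost of complete-case analysis in
a trial designed for 80% power: θ = 2.8 · (N<sub>os</sub>/N<sub>fs</sub>) − 1.96
and power = Φ(θ), so θ = 0.84 (80%) with no attrition and, e.g., θ = 0.14
(56%) when a quarter of outcomes are missing. The formula is implemented
exactly in this linear-in-the-ratio form, which is the form consistent with
that worked example; because the underlying power algebra would more naturally
involve √(N<sub>os</sub>/N<sub>fs</sub>), a `mode="sqrt"` variant is exposed
and the choice is explicit rather than silent. Both agree at ratio 1.

Missing-completely-at-random reasoning can be probed (never proven) two ways,
both provided: a linear probability model T = α + **X**′δ + ε with a joint
heteroskedasticity-robust Wald test of δ = 0 (`balance_test`, on the full,
observed-only, or post-trimming sample — the latter is the observable check of
monotone selection, `monotonicity_check`), and the comparison of adjusted and
unadjusted β on the same complete-case rows with a paired-bootstrap standard
error for the difference (`mcar_mar_comparison`). The linear probability model
is used deliberately — the test only asks whether δ = 0, not for
interpretable coefficients — and all regressions use HC1 covariance because
selected and trimmed samples are not homoskedastic by construction.

## Bounds

**Worst-case (Horowitz–Manski) bounds** fill every missing treated outcome
with one extreme of the declared outcome support and every missing control
outcome with the other, in the two patterns that minimize and maximize the
mean difference. They assume nothing about selection and are typically wide.

**Trimming (Lee) bounds** assume *monotone selection*: assignment can push the
observation probability in only one direction for every participant. The
less-attrited arm's observed outcome distribution is then trimmed by the share
q from its lower tail (one candidate) and its upper tail (the other); each
trimmed mean is differenced against the other arm's observed mean, and the two
candidates are sorted into (lower, upper) — computing both and sorting keeps
the code free of any assumption about which direction of the outcome is
"good". The interval identifies the ATE among never-attriters, the
subpopulation observed under either assignment, represented by the observed
participants of the arm that remains untrimmed.

The trimming primitive removes probability mass, not rows: with n observations
of mass 1/n each, the order statistic straddling the p-quantile keeps the
fractional remainder of its mass (`trimmed_mean`, default `fractional` mode).
This matches the population trimming formula, is invariant to row order even
under ties, and matters numerically: trimming 34% of 86 observations is not an
integer. An `integer` mode (trim ⌈p·n⌉ whole observations) replicates
implementations that round; replication attempts should run both.

**Conditional trimming** partitions the sample into discrete cells, trims each
cell by its own attrition differential in its own direction (cells whose
differential flips sign are retained and trim the other arm — dropping them
would bias the weights), and averages the per-cell bounds with weights equal
to each cell's share of observed participants in the *globally* untrimmed arm
— the never-attriter reference population. Cells below a minimum per-arm
observed count are pooled into an `(other)` cell (user-supplied cells) or
merged into the nearest leaf by tree-path distance (tree-derived cells); a
pooled cell that still lacks observed outcomes in one arm is an error, because
no trimmed mean exists for it.

**Uncertainty.** All bounds get a within-arm nonparametric bootstrap:
participants are resampled with replacement inside each arm and the *entire*
procedure — attrition rates, trim share, trim direction, per-cell bounds — is
recomputed per replicate (the RFLB conditioning scheme stays fixed; the screen
is a model-selection step, and re-running it per replicate would answer a
different question). The default report is the outer interval
[L − z·se<sub>L</sub>, U + z·se<sub>U</sub>], which covers the whole identified
set at the nominal level; an Imbens–Manski-style interval (critical value c
solving Φ(c + (U−L)/max(se)) − Φ(−c) = level), which covers the *parameter*
and is never wider, is available via `ci_method="imbens-manski"`. Replicates
with degenerate attrition (an arm losing all observed outcomes) are dropped
and counted; more than 20% dropped raises an error instead of a number.

A caveat found while validating: Lee-interval-inside-worst-case-interval is a
population relationship. Its finite-sample margin shrinks to ~0.01 outcome-SD
when one arm's observation rate approaches 1 (the worst-case filling mass
vanishes) while the attrition differential stays large, and sampling noise
then produces occasional reversals. The containment test therefore uses
moderate observation rates (0.60–0.92) at n ≥ 80 per arm, where the population
margin dominates.

## Random-forest Lee bounds

Conditioning requires discrete cells, which locks continuous covariates out of
the plain conditional procedure. The RFLB pipeline fixes that in four steps.

1. **Attrition forest.** A random-forest classifier predicts 1 − S from
   treatment, the covariates, and injected uniform-noise probe columns.
   Defaults: 500 trees, √p features per split, minimum leaf 5, stratified
   5-fold cross-validation, everything seeded.
2. **Importance screen.** Importance is *permutation* importance — impurity
   importance is biased toward continuous features, which would rig the
   benchmark comparison. Every row is scored by the fold model not trained on
   it; the pooled out-of-fold Brier score is the baseline, each feature group
   (all one-hot columns of a covariate move together) is permuted full-length
   with permutations shared across folds, and the importance is the mean score
   drop. Pooling before scoring keeps the estimate usable at trial sizes,
   where per-fold scores on ~40 rows are dominated by noise. Importances are
   normalized so the top feature scores 1. A covariate is a candidate only if
   its importance strictly exceeds the **benchmark bar**: by default the
   *maximum* importance over 5 noise probes. With a single probe the
   comparison is exchangeable under the null, so every noise covariate would
   pass ~half the time; the shadow-maximum rule drives that toward 1/(k+1)
   per screen. `benchmark_probes=1` reproduces the classical single-probe
   graph.
3. **Interaction confirmation.** Selective attrition tightens bounds only if
   the attrition–treatment covariation itself depends on the covariate. A
   second forest therefore uses treatment and the explicit products T·X<sub>j</sub>
   (T × level indicators for categoricals) *only* — main effects are excluded
   because they absorb ("mask") the products' signal — with T·probe columns as
   the interaction benchmark. Product permutations are drawn within arms
   (conditional permutation), so they break the covariate content of the
   product without destroying its treatment structure. Under the default
   `selection_rule="both"` a covariate enters the conditioning set only when
   it clears both screens; `"main-only"` relaxes this.
4. **Discretization.** A depth-limited decision tree (default: at most 4
   leaves) predicts the attrition indicator from the conditioning-set
   covariates alone — treatment never splits. Leaves become trimming cells;
   leaves below the minimum per-arm observed count (default 20; smaller values
   are appropriate for trials of a few hundred participants, e.g. 10 at
   n ≈ 200) are merged into their nearest neighbour by tree-path distance.
   Cell-wise conditional bounds and the bootstrap then run as above.

If the conditioning set is empty the pipeline *falls back* to unconditional
trimming bounds and flags it (`fallback_to_unconditional`) — the expected and
correct outcome when attrition relates to assignment but not to measured
covariates, as in the motivating trial's real attrition pattern.

## Synthetic trials

`TrialScenario` describes a generative trial: arm sizes (assignment is
fixed-margin, matching real trial allocation), a control outcome
N(μ, σ) with centered covariate loadings (so μ is exact and σ is the *total*
SD; the residual SD is reduced accordingly, and loadings that exceed the
budget are an error), a homogeneous additive effect β (y₁ = y₀ + β), and a
logistic attrition index with per-arm base observation rates, shared covariate
coefficients, treated-specific (interaction) coefficients, and — for
missingness not at random — coefficients on the latent control outcome
itself. Attrition never loads on the effect increment, so the never-attriter
ATE equals β exactly; that is the recovery target for coverage checks.

Monotone selection is enforced *by construction*: the higher-observation arm
draws a base layer S ~ Bernoulli(p(x)), and the other arm multiplies it by an
extra-retention Bernoulli, so assignment can only add dropout. Base rates are
exact under MCAR and approximate (centered-index) otherwise. Non-monotone
mechanisms draw the two arms independently.

The `zerophobia_preset` emulates a 193-participant acrophobia trial: 96
treated / 97 control, control outcome N(74.68, 21.55), effect −26.22 points
(treated observed mean 48.46), covariates gender ~ Bernoulli(0.6),
age ~ N(41, 13), and a baseline severity score ~ N(80, 20) loading 0.6 on the
outcome. Its attrition variants, chosen once as study conditions:

- `observed`: observation rates 56/96 (treated) and 86/97 (control),
  covariate-unrelated — the trial's actual pattern; expected trim share ≈ 0.34
  and the forest screen should select nothing.
- `interaction`: the same rates, with treated-arm retention loading 1.0
  log-odds per SD on gender and the severity score — a clearly selective
  planted mechanism under which conditioning demonstrably tightens bounds
  (at large n the treated observation rate spans ~0.33–0.69 across gender).
- `mcar`: equal 0.85 rates, trim share ≈ 0.
- `scale_effect(scenario, d)` rescales β to d·σ for effect-size studies
  (d ∈ {0.2, 0.4, 0.8} being the conventional small/medium/large sizes).

`run_simulation_study` replicates a scenario with sub-seeds spawned from one
master seed, runs each estimator per replicate, records bounds, widths, outer
CIs, and coverage of the never-attriter ATE, and aggregates to a comparison
table with percent width gain relative to unconditional trimming. Estimator
failures in a replicate are counted and excluded from that estimator's
aggregate.

What the generator does *not* emulate: heterogeneous treatment effects (the
never-attriter ATE would then differ from β), non-logistic attrition,
covariate measurement error, item-level missingness beyond the covariate
missing-indicator/drop-row policies, and clustered or longitudinal designs.
Passing tests show the estimators behave correctly under the stated
mechanisms, not that any particular real trial satisfies monotonicity.

## Numerical and design choices

- Trim-boundary ties carry fractional mass; results never depend on row order.
- Treatment coding never infers which arm is treated: two-level string
  codings require an explicit reference level, because a silent arm flip
  inverts every bound.
- Missing covariate values: `missing-indicator` (companion 0/1 column,
  observed-pooled-mean fill for continuous, dedicated level for categorical)
  or `drop-row`. The fill value is immaterial once the indicator is present.
- Collinearity is detected by rank and reported with the offending columns
  (pivoted QR), not silently absorbed.
- Forest and tree seeds all derive from the single analysis seed via seed
  sequences; identical data + config + seed give bit-identical reports,
  schemes, and bounds.
- Test-suite problem sizes: the screen behaviour suites run 100 replications
  (fallback) and 50 replications (tightening) at n = 193 with 100-tree
  forests and 4 permutation repeats; coverage runs 200 replications at
  n = 2,000. These sizes were chosen to make the Monte-Carlo assertions
  stable at desk scale.

## Known limitations

- The bootstrap treats the trim share as re-estimable but the RFLB
  conditioning scheme as fixed; model-selection uncertainty in the screen is
  not propagated into the confidence interval.
- Quantile treatment-effect bounds and regression-adjusted trimming variants
  are out of scope.
- The interaction screen tests products T·X<sub>j</sub> only; higher-order or
  covariate-covariate interactions are not screened.
- With heavy attrition in *both* arms the never-attriter subpopulation can be
  small and practically unrepresentative; the package reports bounds for it
  regardless, because that is what the trimming estimand is.
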