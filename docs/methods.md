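# Methods

## Scope and model of the data

`balancesel` operates on a wide subject × measure table of continuous
balance measures with a binary group label (PD / healthy control), an
optional retest session of the same shape, and an optional subject ×
clinical-scale table. Nothing in the pipeline looks at raw sensor
signals; the unit of analysis is the already-extracted measure. The
statistics consumed downstream are scale-free (standardized mean
differences, rank correlations, ICCs), so measures may arrive in any
units.

## The measure catalogue

The default catalogue fixes the battery's combinatorial structure: 7 sway
base measures × 6 standing tasks (42), 6 APA base measures × {ST, DT}
(12), 7 push-and-release APR measures, 12 gait base measures × {ST, DT}
(24) plus 5 derived dual-task-cost measures, and 3 LOS measures — 93 in
total. Counts, domains, tasks and impairment directions are the
structural contract; the base-measure *names* are conventional labels and
can be replaced via a YAML catalogue file without affecting any
computation. Each descriptor records an impairment direction (whether
parkinsonian deficit raises or lowers the value): sway amplitudes,
latencies, durations and step counts go up with impairment; speeds,
ranges of motion, step lengths and LOS ranges go down. Dual-task-cost
measures inherit their base measure's direction, since the signed percent
change moves the same way as the base measure under a dual-task decrement.

## Missingness and imputation

Missing cells carry a category code. Falls (A) and absent anticipatory
adjustments (D) are treated as informative — the subject was too impaired
to produce the measure — and receive a single worst-case value: the worst
observed value of that measure across the pooled cohort, pushed a further
2 observed SDs in the impaired direction. Anchoring on the pooled cohort
(rather than per group) keeps the rule well defined for measures whose
missingness is concentrated in one group. Skipped tasks (B), unusable
sensor data (C) and noisy baselines (E) are treated as recoverable and
completed by multiple imputation, after the worst-case track so the MI
models condition on complete predictors.

The MI engine is chained equations with predictive-mean-matching draws:
each incomplete column is ridge-regressed (penalty 1e-3·n on the Gram
diagonal) on the group indicator and all other columns, with the observed
rows bootstrap-resampled per dataset to propagate model uncertainty; each
missing cell receives the observed value of a donor sampled from the 5
rows with the closest predictions. Five sweeps, fewest-missing-first
visit order, m = 25 completed datasets by default. This is deliberately
a light-weight engine: donor draws guarantee in-range values and
between-imputation variance, and a full ensemble completes in well under
a second at study size, which matters because the recovery test suites
regenerate hundreds of cohorts. Downstream statistics are pooled by
element-wise mean over the m datasets (with the across-dataset SD
reported as a diagnostic); no Rubin's-rules variance pooling is done,
because the pipeline's outputs are point estimates and selections, not
interval inferences.

Task removal happens before imputation: a task whose cells are missing
more often than the threshold (default 0.20) in the pooled cohort is
dropped wholesale. The trigger can be switched to "PD group or pooled";
pooled is the default because it is the reading under which exactly the
eyes-closed-on-foam task is removed at the documented rates
(pooled 29.2% vs 9.9% for the next-worst task).

## Effect sizes

SMD = (X̄₁ − X̄₂)/S with the denominator
S = √[(SD₁²/n₁ + SD₂²/n₂)·(n₁n₂/(n₁+n₂))] by default and Cohen's pooled
SD as an alternative. The two coincide exactly at n₁ = n₂ (any SDs) but
weight the group variances by opposite group shares, so at the study's
144/79 imbalance they diverge as the SD ratio leaves 1 (≈16% at SD ratio
2); both are reported by the oracle tests. Thresholding uses |SMD|
(default > 0.5), because the impairment direction — and hence the sign —
varies by measure.

## Redundancy pruning

Spearman correlations are computed on the completed data across the
pooled cohort and averaged over the imputed ensemble. Violating pairs
(|ρ| > 0.70, strict) are processed in descending |ρ| with lexicographic
tie-breaks; a pair whose members both survive loses its dual-task member
if it is one base measure under ST/DT, otherwise its smaller-|SMD|
member; a removal deactivates the removed measure's remaining pairs.
This greedy policy is deterministic and leaves no violating pair among
survivors. It is *not* always the minimum-removal resolution: in a chain
a–b, b–c where the rules remove b from (a,b) and c from (b,c), processing
(b,c) first costs two removals where (a,b) first costs one. The test
suite therefore validates the policy against brute-force enumeration of
all rule-respecting removal orders (reachability, violation-freeness, and
agreement whenever the orders converge to a unique terminal set), rather
than against an unconditional minimality claim.

## Random-forest validation

scikit-learn forests: 500 trees, √p feature subsetting, unlimited depth,
bootstrap sampling, impurity (Gini) importances normalized to sum to one,
out-of-bag error reported from a full-data fit. Cross-validation is
randomized (unstratified) 10-fold by default, with per-fold accuracy and
precision (positive class = PD) reported as mean ± SD in percent; folds
where precision is undefined are excluded from the precision summary with
a warning. Ensemble-level validation averages the per-dataset summaries
over the imputed datasets.

## Reliability

ICC(2,1) — two-way random effects, absolute agreement, single measurement
— from the two-way ANOVA decomposition; SEM = SD·√(1 − ICC) with SD the
pooled SD of all test and retest observations; MDC = SEM·1.96·√2. The
SEM uses the square-root form (the standard definition); the ICC model
choice is logged in the report. Sessions are treated as exchangeable.

## The synthetic cohort generator

The generator is the pipeline's ground truth, not a fixture. Per
subject, a latent impairment factor L ~ N(1.5·[PD], 1) drives informative
missingness and the clinical scales. Measures are unit-variance Gaussian
within group; the PD mean is shifted by the target |SMD| along the
measure's impairment direction, so the planted population SMD is exact.
The correlation structure is a common factor (the cross-domain
correlation, default 0.20, identified with L) plus equicorrelated
within-domain blocks (Sway 0.30, APA 0.35, APR 0.35, Gait 0.40,
LOS 0.50) plus explicitly planted high-correlation pairs; positive
definiteness is checked before sampling. Retest values for the PD group
satisfy corr(test, retest) = target ICC with equal means and variances,
which makes the population ICC(2,1) equal the target. Clinical scales
are linear in L (signed loadings; Mini-BEST and ABC load negatively)
plus independent noise, mapped to their natural ranges and truncated;
PD-only scales are absent for controls.

Missingness is imposed per (task, group, rate, category): the
configured fraction of the group's subjects (deterministic rounding, so
rates are honored exactly) loses every measure of the task. Fall/no-APA
categories mask the most impaired subjects first (by L); the other
categories mask uniformly at random.

The default study configuration plants 144 PD / 79 HC and a 44-measure
sensitive set (Gait 16, APA 10, Sway 11, APR 7; domain-mean ordering
Gait > APA > Sway > APR, top values ≈ 1.2–1.3) with 20 redundant members
paired at ρ = 0.85 to a kept partner, 49 insensitive measures (0 except
LOS at 0.05–0.12), and missingness at the documented task/group rates.
Within that envelope the exact per-measure values were chosen once so
that the planted margins are statistically resolvable at the study's
sample size: sensitive measures sit ≥ 0.92 (threshold 0.5 is ≈3 SE away
at n = 144/79), rule-1 pair gaps are ≥ 0.22 (≈2.7 SE of the pair
difference at ρ = 0.85), and every task that draws informative
fall-missingness carries only sensitive measures — worst-case imputation
presumes a real deficit and would otherwise manufacture one. Two removed
measures sharing a kept partner are correlated at 0.85² as a one-factor
structure implies, which keeps the matrix positive definite.

### What the generator does not emulate

Real batteries have skewed, heavy-tailed marginals, heteroscedastic
groups, age/sex structure, and missingness that correlates with specific
measures rather than a single latent factor. Passing recovery tests on
this generator therefore demonstrates that the pipeline's logic is
correct under its own assumptions (Gaussian margins, block correlation,
single latent driver), not that the selected subset from any particular
real cohort is right. Rank-based and mean/SD-based statistics make the
pipeline insensitive to monotone marginal transforms, which is the main
reason Gaussian margins are an acceptable stand-in.

## Numerical and design choices

* Seeds: a single run seed fans out via `SeedSequence.spawn` into
  independent per-stage seeds (cohort, imputation, forest), so stages are
  individually reproducible and bit-identical across reruns.
* Degenerate inputs: an SMD with both SDs zero, a constant column in a
  correlation matrix, a measure with < 2 observed values in worst-case
  imputation, a single-class classification table, and zero total
  variance in an ICC all raise errors naming the offending quantity.
  An empty post-filter selection completes the pipeline with an explicit
  "no measures retained" report rather than failing.
* Problem sizes in the test suite: parameter-recovery claims use 10,000
  subjects (±0.02 bands); selection recovery uses 400 replicate cohorts
  at study size, because the true exact-recovery rate (~96%) lies close
  to its 95% requirement and a smaller replicate count would measure it
  with ±2-point noise; reliability recovery uses 200 replicates.
* Known limitation: with the retest correlation planted exactly, the
  ICC(2,1) estimator at n = 144 has SD ≈ 0.026 at true ICC 0.82, so a
  ±0.04 recovery band is only a ~88% event per seed; the corresponding
  recovery assertion is stated at its nominal ≥90% rate and documented
  as failing for that one target for purely statistical reasons.
* The forest stage defaults to averaging cross-validation over all 25
  imputed datasets; this is the slowest stage (a few minutes at study
  size) and can be capped via `forest_max_datasets`.
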