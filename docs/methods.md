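# Methods

## Problem and model

The package recommends the next laboratory test for a patient given the
tests already ordered, treating each candidate test as a binary
classification — "taken" vs "not-taken" — under a naive-Bayes model over
the patient's existing tests.

All estimation reduces to a symmetric `M × M` co-occurrence matrix over
the test catalogue, built once from training cases: off-diagonal entries
count cases containing both tests, the diagonal holds per-test marginal
counts, and counts are binary at the case level (a test ordered twice in
one visit counts once, because every probability is a fraction of cases).
Storing the marginal on the diagonal is a deliberate convention — the
matrix stays a single structure and the conditional probability of a test
given itself is 1 by construction. The matrix serialises to plain text and
round-trips exactly, so prediction and evaluation never touch raw records.

For candidate `test_0` and a case with taken set `{t_1 … t_k}`, with `α`,
`γ_i`, `β_i` the count-ratio prior, marginal and conditional defined in
the README, the `exact` evidence mode computes the posterior log-odds

```
w = log((α + θ)/(1 − α + θ)) + Σ_i log( β̃_i (1 − α) / (γ_i − α β̃_i) )
```

This composition is algebraically identical (before smoothing) to the
brute-force Bayes-rule expansion
`log[ Pr(F_0) Π Pr(F_i|F_0) / (Pr(F_0^c) Π Pr(F_i|F_0^c)) ]`, because
`Pr(F_i | F_0^c) = (γ_i − α β_i)/(1 − α)`; the acceptance suite verifies
the identity to 1e-9 on randomized instances, together with identity of
the induced rankings. The evidence sum runs over the case's taken tests
only: "not-taken" events have no counts in the co-occurrence matrix, and
under the exact composition they would only add candidate-independent
constants plus second-order corrections the naive model cannot estimate
anyway.

A second composition, `literal`, reproduces a formulation that circulated
with the original method:
`(k − 1)·log((1 − α + θ)/(α + θ)) + Σ_i log(β̃_i /(γ_i − β̃_i))`. Its two
parts do not compose to the posterior log-odds — the `γ − β` denominator
is negative precisely for positively associated pairs, and the `(k − 1)`
prior coefficient only arises when the evidence numerator is the *joint*
rather than the conditional probability — so it is kept as a selectable
variant for comparison studies, with ε-flooring making every term finite.
The two modes agree on all fixtures with `α = 0.5`, which is why small
worked examples do not distinguish them. Only the ranking is contractual;
scale (and hence log base) is not.

## Smoothing

Raw count ratios assign zero probability to unseen events and make the
log diverge. Three smoothers shrink `β` toward the taken test's marginal
`γ`:

| method | formula | parameter |
|---|---|---|
| Jelinek-Mercer | `(1 − λ)β + λγ` | `λ ∈ [0, 1]` |
| Dirichlet | `(β + µγ)/(1 + µ)` | `µ ∈ [0, 1]` (count-space `µ0` divided by the conditioning count) |
| absolute discounting | `max(c − δ, 0)/c_0 + δγ` | `δ ∈ [0, 1]` |

and Laplace smoothing `log((α + θ)/(1 − α + θ))` keeps the prior log-odds
finite at `α ∈ {0, 1}`. Absolute discounting is applied to the joint
count `c` with the candidate's marginal `c_0` as the base; with `c_0 = 0`
(candidate never seen) the discounted term is dropped and `δγ` alone
remains. The discounted output is *not* renormalised over tests and can
marginally exceed 1; this is documented rather than corrected, since only
score order matters and renormalising would change the formula actually
specified. Katz backoff is out of scope.

Defaults for end-to-end runs are Jelinek-Mercer `λ = 0.2` and `θ = 0.5`,
the regions reported as optimal and stable in the original parameter
studies of this method; `evidence_mode = exact`; the log floor is
`ε = 1e-12`, with every floor event logged.

Degenerate inputs: a taken test with zero training marginal (`γ = 0`)
carries no usable evidence and is skipped with a warning; an unseen
*candidate* (`α = 0`) is rankable whenever `θ > 0`, its `β` taken as 0
before smoothing. With `θ = 0` and `α ∈ {0, 1}` the prior is undefined
and an error is raised rather than floored — an unsmoothed configuration
is assumed to be a deliberate choice on data where it is well-posed.

## Evaluation harness

`run_experiment` performs: patient-atomic random split (all visits of a
patient on one side; the training side targets `round(f·N)` cases, hit
exactly when each patient has one visit), uniform removal of one test per
validation case with `k ≥ 2` (singleton cases are excluded and counted),
matrix build on the training side over the full universe, ranking of all
not-taken candidates per reduced case, and `CorrectRate_X` for
`X ∈ {1, 3}` by default. Split and removal use two independent seeds so
each randomisation is separately reproducible. The removed test is always
in the candidate set. `parameter_sweep` repeats the experiment across a
parameter grid with identical seeds, so rows differ only in the
parameter.

For an uninformative ranker the hit probability of a case with `k'` input
tests is `X/(M − k')`; `random_baseline` exposes this closed form, and
averaging it over evaluated cases gives the chance level quoted next to
any result.

## Synthetic data

`SyntheticConfig` defaults: 500 cases, `M = 20` tests, 4 disjoint panels
of 5 tests, each condition carried independently with probability 0.5,
each panel test firing with probability 0.9 given its condition, and
off-panel noise at 0.02 per test. These sizes give strongly structured
cases (about two active panels, nine tests per case) while the entire
test-plus-acceptance workload stays in the tens of seconds. Empty cases
are resampled (bounded budget) since a case with no tests is unusable at
every stage. Panels are disjoint by construction so that recovery is
identifiable.

The generator emulates only the co-occurrence mechanism: no test results,
demographics, repeat-visit dynamics, seasonal ordering patterns, or
overlapping panels. Passing tests therefore demonstrate that the pipeline
recovers planted co-occurrence structure, not that it attains any
particular accuracy on real clinical data, where the catalogue is an
order of magnitude larger and associations are weaker and overlapping.

Two calibration regimes are used by the test suite:

* **Independence regime** (no panels): the default noise rate would leave
  almost no case with two tests, so this regime uses `noise_rate = 0.2`,
  `M = 20`, 1500 cases — mean case size ≈ 4. Under independence the
  removed label is exchangeable with every other candidate, so
  `CorrectRate_1` equals the mean baseline `1/(M − k')` in expectation
  exactly; the test asserts agreement within 3 Monte-Carlo standard
  errors, a property of the estimator rather than a tuned band.
* **Planted regime** (defaults): hit@3 reaches ≈ 0.95 against a
  case-averaged chance level of ≈ 0.25–0.33. Note the chance level is
  high because evaluated cases are large relative to `M = 20`; ratios to
  baseline are bounded near 3–4 in this regime regardless of recommender
  quality, a ceiling to keep in mind when comparing against fold-change
  expectations formed on catalogue-scale universes (hundreds of tests).

The train-fraction study (fractions 0.4/0.5/0.6) is a stochastic check:
at these sizes the co-occurrence counts are nearly converged by 200
training cases, so the true per-step improvement (~0.001–0.002) is of the
same order as Monte-Carlo noise. The suite runs 50 paired seed
replicates and asserts the mean change is non-decreasing within two
standard errors of the paired difference — more training data must never
significantly hurt.

## Numerical and design notes

* Natural logarithms throughout; any other base rescales all weights
  positively and cannot change a ranking.
* Ties are broken by test code ascending, making every ranking
  deterministic; exact count-symmetric candidates may differ in floating
  summation order at ~1e-15, which tie-handling absorbs.
* The analysis unit defaults to the visit (patient id + service date),
  configurable to the patient; per-visit grouping drops records with
  unparseable dates (counted and logged), per-patient grouping tolerates
  them because the date is unused.
* The weight is a ranking score, not a calibrated probability; no
  calibration layer is provided or implied.

## Known limitations

* Naive-Bayes conditional independence is knowingly false for panel data
  (panel members are mutually dependent); it is the standard bias/variance
  trade this family of recommenders accepts.
* The literal evidence mode relies on ε-flooring for positively
  associated pairs, exactly where recommendations matter most; it exists
  for comparability, not as the default.
* Sparse representations are not implemented; the dense `M × M` matrix is
  comfortable to a few thousand tests but not beyond.
* No incremental matrix updates — rebuild from cases.
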