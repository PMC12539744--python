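# Methods

## The data-generating process

phenosim models a parallel-group placebo-controlled trial in which the
benefit of a treatment is fully determined by a non-linear rule over
three of seven phenotype covariates. All covariates are drawn
independently and uniformly (integers for continuous-style variables,
fair coins for binary ones except where noted); the responder rule is

* responsive if X ≥ 95, unconditionally;
* otherwise responsive if Z = 1 and 50 ≤ Y ≤ 90;
* otherwise responsive if Z = 0, 90 ≤ X ≤ 94 and 50 ≤ Y ≤ 90.

All interval bounds are inclusive, and the X floor of 95 belongs to the
unconditional branch (so the conditional Z-absent window is the integers
90–94). Exhaustive enumeration of the 6222-cell (X, Y, Z) grid gives the
responder probability 2782/6222 = 0.447123, with conditional responder
probabilities 2211/3111 given Z = 1 and 571/3111 given Z = 0. These
exact rationals are the oracle that the test suite measures sampling
behaviour against.

Randomisation is simple (per-patient Bernoulli(½)), not blocked: arm
sizes are random, matching the behaviour of a trial whose realised split
is 509/491 rather than a forced 500/500. The outcome change is
N(10, 3²) for treated responders and N(0, 3²) for treated
non-responders and all placebo patients. Changes ≥ 5 count as clinically
meaningful; thresholding the realised change at 5 yields the noisy
"trial outcome" label whose per-class agreement with ground truth is
Φ(5/3) ≈ 0.952 — the ceiling for any classifier scored against those
labels.

**Seed architecture.** One master seed spawns five named child streams —
phenotypes, randomisation, outcomes, noise variables, and ML
(fold shuffling + tree subsampling). Scenarios that must share a cohort
(baseline vs deficiency) simply share the master seed; scenarios that
must redraw everything (power replicates, excess grid points) derive
fresh masters from indexed spawn keys. A run's manifest records all of
this, and rerunning from the same manifest is byte-identical.

## Noisy-variable banks (excess scenario)

Of `n_noisy` extra variables, ⌊n/6⌋ each covary with X, Y (variable plus
N(0, 10²) noise, population correlation ≈ 0.83 with the parent) and Z
(binary, with exactly round(⅔·n_patients) randomly chosen patients
matching their Z). The remainder are independent: alternating
Bernoulli(0.10) and uniform integers 18–100, in fixed index order,
remainder assigned to the independent class. Two points were genuinely
open and are recorded as configurable choices:

* the non-matching third of a Z-linked variable defaults to 1 − Z
  (`z_mismatch="flip"`), which yields a *weaker* proxy (corr ⅓ with Z)
  than filling with fair coins would (corr ⅔); `"uniform"` is available;
* class sizes round down per linked class with the remainder going to
  the independent class, so small banks (e.g. 5 variables) are entirely
  independent while any multiple of 6 realises the exact
  1/6–1/6–1/6–1/2 split.

## Traditional analysis

Effect estimates are unadjusted between-arm mean differences with
z-based (1.96) 95% intervals using unpooled variances; at ~500 per arm
the t-based alternative differs in the third decimal, and the z form is
what the confidence intervals elsewhere in the pipeline (binomial
accuracy CIs) also use. Subgroup estimates deliberately carry no
multiplicity adjustment — the point of the exercise is what a
conventional forest table would show. Default subgroup cut-points are
median splits for continuous covariates and levels for binary ones;
rule-threshold splits can be passed explicitly. NNT is the reciprocal
risk difference of reaching the clinically-meaningful threshold, with a
+∞ signal for non-positive risk differences. The responsive /
non-responsive contrasts use Welch's t for continuous variables and a
two-proportion z-test for binary ones. `detectable_effect` implements
the standard two-sample normal-approximation minimal detectable
difference, (z₁₋α/₂ + z_power)·σ·√(2/n); with σ = 3 it gives 1.063 at
125 per arm and 0.532 at 500 per arm.

Closed-form expectations used by the tests: the expected effect estimate
is 10 × 0.447123 ≈ 4.47; the expected NNT is
1/(0.447123·(Φ(5/3) − (1 − Φ(5/3)))) ≈ 2.47.

## Machine-learning analysis

Both learners see treatment-arm patients only (placebo outcomes carry no
information about responsiveness) and are trained on the noisy outcome
labels; ground truth is used exclusively at evaluation. Continuous
features are centred and scaled to unit variance with statistics from
each training fold only; binary features pass through. A single fixed
hyperparameter setting is used, with no tuning: XGBoost binary classifier with
depth 3, learning rate 0.1, 100 rounds, 0.8 row and per-tree feature
subsampling (hist tree method, base score 0.5, single thread for
determinism); logistic regression with L2 penalty (C = 1), lbfgs,
tolerance 10⁻⁴, ≤ 100 iterations, augmented with all pairwise distinct
products of the scaled features (no squares — squares of scaled uniforms
carry almost no extra signal and the pairwise reading is the
conservative one). Folds are plain shuffled K-fold, unstratified, with
a 0.5 probability threshold; every patient is predicted exactly once by
the model that never trained on them. Accuracy CIs are normal-
approximation binomial intervals clipped to [0, 1].

## Shapley interrogation

Attributions are exact TreeSHAP values computed by the booster itself in
margin (log-odds) units, where additivity — base value plus feature
contributions equals the model margin — holds to float32 precision
(≈ 10⁻⁶ relative). By default each fold's model explains its own
held-out patients, so the explained population is identical to the
out-of-fold-predicted population; a refit-on-all-rows variant sits
behind `out_of_fold=False`. Features are ranked by summed |attribution|
across all predictions, ties broken alphabetically. The three standard
slices condition exactly as the rule analysis requires: X unfiltered, Y
where X < 90, and Z where X < 90 and 50 ≤ Y ≤ 90; binned
predicted-responsive proportions use unit-width integer bins (two bins
for Z).

## Scenario scales and what the tests show

The test suite and acceptance script run at the study's own scale —
1000-patient trials, 5-fold CV — with replication chosen so that
Monte-Carlo noise is small relative to each tolerance: 20 independent
seeds for the ML accuracy distributions, 200–1000 replicate trials for
the traditional estimates (simulation-only, so cheap), 100 end-to-end
replicates for the power analysis, and the scaled noisy-variable grid
{5, 1005, 5005, 10005} with three replicate sweeps (per-point single-run
accuracy has ≈ 1.5–2-point sampling noise from cohort resampling, so
flatness is judged on per-point means whose standard error is ≈ 1
point).

Because the generator is the study itself, passing tests demonstrate
properties of the *specified* synthetic world only: covariates are
mutually independent and uniformly distributed, data are complete, the
outcome is a clean two-Gaussian mixture, and the responder rule is
deterministic. None of these hold in real trials, so the accuracy
levels here are upper bounds on what comparable pipelines achieve on
real data, not forecasts.

## Known limitations

* With thousands of correlated proxy variables, per-feature Shapley
  credit for X spreads across its ~n/6 proxies; X's own summed
  |attribution| can fall below individual noisy variables even while
  ground-truth accuracy stays high. Grouped or clustered attribution
  would be needed to make the ranking robust in that regime; only
  per-feature ranking is implemented.
* The excess sweep shows a small (≈ 2–4 point) ground-truth accuracy
  cost once ≥ 1000 noisy variables are present, flat thereafter up to
  10 005.
* No missing data, adverse events, time-course outcomes, or
  hyperparameter search — all deliberately out of scope.
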