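# phenosim

Simulated randomised controlled trials with a hidden, rule-driven,
heterogeneous treatment response — and a head-to-head comparison of what
traditional inferential statistics and cross-validated machine learning
each recover from the same trial data.

**Who it is for.** Clinical-trial methodologists, biostatisticians and
ML-in-medicine researchers who want a fully specified, reproducible
test-bed in which the "ground truth" of treatment responsiveness is known
exactly, so the conclusions of any analysis strategy can be scored against
it — something impossible in a real trial.

## The model

A cohort of *n* = 1000 patients carries seven independent covariates:
age ~ U{18..100}, sex ~ Bern(½), V1 ~ Bern(½), V2 ~ U{0..200},
X ~ U{50..100}, Y ~ U{40..100}, Z ~ Bern(½). A patient is latently
**responsive** iff

```
X ≥ 95   ∨   (Z = 1 ∧ 50 ≤ Y ≤ 90)   ∨   (Z = 0 ∧ 90 ≤ X ≤ 94 ∧ 50 ≤ Y ≤ 90)
```

Exhaustive enumeration of the 51 × 61 × 2 grid gives the responder
fraction 2782/6222 ≈ 0.4471. Patients are randomised 1:1 (per-patient
fair coin); the outcome change is N(10, 3²) for treated responders and
N(0, 3²) for everyone else. Changes ≥ 5 are deemed clinically meaningful.

Against this generator the package runs:

* **Traditional analysis** — between-arm mean difference with 95% CI
  (z-based, unpooled variances), unadjusted subgroup forest table, number
  needed to treat (reciprocal risk difference at threshold 5), and
  responsive-vs-non-responsive descriptive contrasts.
* **ML analysis** — gradient-boosted trees (XGBoost: depth 3, η = 0.1,
  100 rounds, 0.8 row/feature subsampling) and an L2 logistic comparator
  with all pairwise interaction products, both trained on treatment-arm
  patients with noisy outcome labels (change ≥ 5) under 5-fold
  out-of-fold prediction, then scored against both the outcome labels and
  the latent ground truth.
* **Interrogation** — exact TreeSHAP attributions in margin units,
  feature ranking by summed |SHAP|, and conditional slices that recover
  the rule's thresholds from the fitted model.
* **Perturbations** — a *deficiency* scenario (Z withheld from the
  learners), an *excess* sweep (up to 10 000 extra noisy covariates, part
  correlated with X/Y/Z), and a replicate *power* analysis (fraction of
  end-to-end runs beating 90% ground-truth accuracy).

## Worked example

```python
import phenosim as ps

cfg = ps.ScenarioConfig(master_seed=0)
res = ps.run_baseline(cfg)

e = res.overall_effect
print(f"arms: {res.trial['arm'].value_counts().to_dict()}")
print(f"effect: {e.mean_diff:.2f} (95% CI {e.ci_low:.2f} to {e.ci_high:.2f})")
print(f"NNT: {res.nnt:.2f}")
for key in ("xgb_vs_outcome", "xgb_vs_truth", "lr_vs_truth"):
    s = res.confusion[key]
    print(f"{key}: {100*s.accuracy:.1f}% "
          f"(95% CI {100*s.accuracy_ci[0]:.1f}-{100*s.accuracy_ci[1]:.1f})")
print("ranking:", list(res.ranking["feature"]))

s = ps.run_deficiency(cfg).confusion["xgb_vs_truth"]
print(f"deficiency xgb_vs_truth: {100*s.accuracy:.1f}%")
```

prints

```
arms: {'placebo': 502, 'treatment': 498}
effect: 4.90 (95% CI 4.32 to 5.48)
NNT: 2.30
xgb_vs_outcome: 94.0% (95% CI 91.9-96.1)
xgb_vs_truth: 99.2% (95% CI 98.4-100.0)
lr_vs_truth: 80.1% (95% CI 76.6-83.6)
ranking: ['z', 'y', 'x', 'v2', 'age', 'sex', 'v1']
deficiency xgb_vs_truth: 72.9%
```

Reading: the trial "works" (effect ≈ 4.9, NNT ≈ 2.3) even though 55% of
patients cannot benefit; the boosted model identifies who actually
responds with 99% ground-truth accuracy — *above* its 94% agreement with
the noisy labels it was trained on — the three response-determining
variables top the attribution ranking, and withholding the single
variable Z collapses ground-truth accuracy to 73%.

The same pipeline is scriptable from the shell:

```bash
phenosim run --scenario baseline --n 1000 --seed 0 --out out/baseline
phenosim run --scenario power --seed 0 --config power.json --out out/power
```

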