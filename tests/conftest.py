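"""Shared fixtures.

The expensive fixtures are session-scoped and shared across test modules:
``baseline_battery`` runs the full baseline + deficiency analysis for 20
independent master seeds (the sampling distribution most distributional
checks are made against), and ``replicate_effects`` runs 1000 fast
simulate-and-estimate replicates for the traditional-statistics coverage
checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from phenosim import (
    ScenarioConfig,
    estimate_effect,
    number_needed_to_treat,
    run_baseline,
    run_deficiency,
    simulate_trial,
)

N_BATTERY_SEEDS = 20


def _slice_stats(result) -> dict:
    """Summaries of the three threshold-recovering slices of one run."""
    xpts, _ = result.slices["x"]
    ypts, _ = result.slices["y"]
    zpts, _ = result.slices["z"]
    y_outside = ypts[(ypts["value"] < 50) | (ypts["value"] > 90)]
    return {
        "x_high_pred_frac": xpts.loc[xpts["value"] >= 95, "predicted_label"].mean(),
        "y_outside_mean_attr": y_outside["attribution"].mean(),
        "z_present_mean_attr": zpts.loc[zpts["value"] == 1, "attribution"].mean(),
        "z_absent_mean_attr": zpts.loc[zpts["value"] == 0, "attribution"].mean(),
    }


@pytest.fixture(scope="session")
def baseline_battery():
    """Baseline + deficiency analyses over independent master seeds."""
    runs = []
    for seed in range(N_BATTERY_SEEDS):
        cfg = ScenarioConfig(master_seed=seed)
        base = run_baseline(cfg)
        deficient = run_deficiency(cfg)
        runs.append(
            {
                "seed": seed,
                "result": base,
                "effect": base.overall_effect.mean_diff,
                "nnt": base.nnt,
                "acc_xgb_outcome": base.confusion["xgb_vs_outcome"].accuracy,
                "acc_xgb_truth": base.confusion["xgb_vs_truth"].accuracy,
                "acc_lr_outcome": base.confusion["lr_vs_outcome"].accuracy,
                "acc_lr_truth": base.confusion["lr_vs_truth"].accuracy,
                "acc_deficiency_truth": deficient.confusion["xgb_vs_truth"].accuracy,
                "top3": set(base.ranking["feature"].head(3)),
                "importances": dict(
                    zip(base.ranking["feature"], base.ranking["importance"])
                ),
                "additivity_error": base.attribution.additivity_error(),
                "max_margin": float(base.attribution.margins.abs().max()),
                **_slice_stats(base),
            }
        )
    return runs


@pytest.fixture(scope="session")
def replicate_effects():
    """(effect estimate, NNT) pairs over 1000 fast replicate trials."""
    effects, nnts, covered = [], [], []
    expected = 10.0 * 2782 / 6222  # responder fraction times responder mean
    for seed in range(1000):
        trial = simulate_trial(1000, seed=[7, seed])
        treated = trial["arm"] == "treatment"
        t = trial.loc[treated, "outcome_change"]
        p = trial.loc[~treated, "outcome_change"]
        est = estimate_effect(t, p)
        effects.append(est.mean_diff)
        covered.append(est.ci_low <= expected <= est.ci_high)
        nnts.append(number_needed_to_treat(t, p))
    return {
        "effects": np.array(effects),
        "nnts": np.array(nnts),
        "coverage": float(np.mean(covered)),
    }
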