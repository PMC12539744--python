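"""Orchestration of the four study scenarios.

* ``baseline`` — one simulated trial, the traditional inferential analysis
  on both arms, boosted and logistic out-of-fold prediction on the
  treatment arm (against trial-outcome labels and ground truth), Shapley
  ranking and the three threshold-recovering slices.
* ``deficiency`` — the identical trial (same master seed) re-analysed with
  the response-determining binary variable z withheld from the learners.
* ``excess`` — a sweep over growing banks of noisy variables; the cohort
  is resampled at every grid point with a fresh seed.
* ``power`` — replicate end-to-end baseline runs scoring the fraction in
  which the boosted model beats a ground-truth accuracy criterion.

Every run is fully reproducible from its manifest: one master seed
determines the four generator streams plus the ML fold/subsample seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CORE_VARIABLES,
    VARIABLE_RANGES,
    NoiseSpec,
    OutcomeModel,
    ResponseRule,
    add_noise_variables,
    remove_variable,
    simulate_trial,
)
from .interpret import SliceSpec, attribute, rank_features, slice_attributions
from .models import (
    BoostParams,
    ConfusionSummary,
    LogisticParams,
    binarize_outcome,
    evaluate,
    oof_predict,
)
from .stats import estimate_effect, number_needed_to_treat, subgroup_effects

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "ExcessResult",
    "PowerResult",
    "run_baseline",
    "run_deficiency",
    "run_excess",
    "run_power",
    "run_scenario",
    "write_report",
]

log = logging.getLogger(__name__)

DEFAULT_NOISE_GRID = tuple(range(5, 10001, 100))


@dataclass(frozen=True)
class ScenarioConfig:
    """Shared configuration for all scenarios."""

    n_patients: int = 1000
    master_seed: int = 0
    scenario: str = "baseline"
    noise_grid: tuple = DEFAULT_NOISE_GRID
    n_replicates: int = 500
    success_accuracy: float = 0.90
    k_folds: int = 5
    rule: ResponseRule = field(default_factory=ResponseRule)
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    boost_params: BoostParams = field(default_factory=BoostParams)
    logistic_params: LogisticParams = field(default_factory=LogisticParams)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.success_accuracy < 1:
            raise ValueError("success_accuracy must lie strictly between 0 and 1")
        if list(self.noise_grid) != sorted(self.noise_grid):
            raise ValueError("noise_grid must be ascending")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_grid"] = list(self.noise_grid)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ScenarioResult:
    """Everything one baseline/deficiency run produced, plus provenance."""

    scenario: str
    config: ScenarioConfig
    trial: pd.DataFrame
    overall_effect: object
    subgroup_estimates: list
    nnt: float
    confusion: dict  # e.g. {"xgb_vs_truth": ConfusionSummary, ...}
    ranking: pd.DataFrame
    slices: dict  # feature -> (points, bins)
    attribution: object
    predictions: dict
    dropped_variable: str | None
    provenance: dict


@dataclass
class ExcessResult:
    """Accuracy curve over the noisy-variable grid."""

    config: ScenarioConfig
    curve: pd.DataFrame  # n_noisy, accuracies + CIs, top-3 features
    provenance: dict


@dataclass
class PowerResult:
    """Replicate end-to-end detection summary."""

    n_runs: int
    n_success: int
    success_fraction: float
    accuracies: list[float]
    config: ScenarioConfig
    provenance: dict


def _ml_seed(master_seed) -> int:
    """Fifth child stream of the master seed, reduced to a 31-bit int."""
    ss = np.random.SeedSequence(master_seed).spawn(5)[4]
    return int(ss.generate_state(1)[0] % (2**31))


def _ml_analysis(
    trial: pd.DataFrame,
    config: ScenarioConfig,
    drop: str | None = None,
    learners: tuple = ("xgb", "lr"),
    interrogate: bool = True,
):
    """Treatment-arm out-of-fold analysis shared by all scenarios."""
    treated = trial[trial["arm"] == "treatment"].set_index("patient_id")
    feature_cols = [c for c in treated.columns if c not in ("arm", "responsive_truth", "outcome_change")]
    features = treated[feature_cols]
    if drop is not None:
        features = remove_variable(features, drop)
    labels = binarize_outcome(
        treated["outcome_change"], config.outcome_model.clinically_meaningful_threshold
    )
    truth = treated["responsive_truth"]
    seed = _ml_seed(config.master_seed)

    predictions, confusion = {}, {}
    if "xgb" in learners:
        predictions["xgb"] = oof_predict(features, labels, config.boost_params, config.k_folds, seed)
    if "lr" in learners:
        predictions["lr"] = oof_predict(features, labels, config.logistic_params, config.k_folds, seed)
    for name, pred in predictions.items():
        confusion[f"{name}_vs_outcome"] = evaluate(pred, pd.Series(labels, index=features.index))
        confusion[f"{name}_vs_truth"] = evaluate(pred, truth)

    table = ranking = slices = None
    if interrogate and "xgb" in predictions:
        table = attribute(predictions["xgb"])
        ranking = rank_features(table)
        slices = _standard_slices(table, trial, config.rule, dropped=drop)
    return predictions, confusion, table, ranking, slices


def _standard_slices(table, trial, rule: ResponseRule, dropped: str | None = None) -> dict:
    """The three threshold-recovering conditional views.

    x unfiltered; y where x is below the conditional window; z under the
    double filter (x below the window and y inside the responsive band).
    """
    x_lo = VARIABLE_RANGES["x"][0]
    below_window = ("x", (x_lo, rule.x_mid_low - 1))
    specs = {
        "x": SliceSpec("x"),
        "y": SliceSpec("y", filters=(below_window,)),
        "z": SliceSpec("z", filters=(below_window, ("y", (rule.y_low, rule.y_high)))),
    }
    out = {}
    for feat, spec in specs.items():
        if dropped is not None and (feat == dropped or any(f == dropped for f, _ in spec.filters)):
            continue
        out[feat] = slice_attributions(table, spec, trial)
    return out


def _provenance(config: ScenarioConfig, **extra) -> dict:
    prov = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "seed_streams": ["phenotypes", "randomisation", "outcomes", "noise", "ml"],
        "ml_seed": _ml_seed(config.master_seed),
        "config_hash": config.digest(),
    }
    prov.update(extra)
    return prov


def run_baseline(config: ScenarioConfig, _drop: str | None = None) -> ScenarioResult:
    t0 = time.perf_counter()
    trial = simulate_trial(config.n_patients, config.rule, config.outcome_model, config.master_seed)
    treated_mask = trial["arm"] == "treatment"
    t_out = trial.loc[treated_mask, "outcome_change"]
    p_out = trial.loc[~treated_mask, "outcome_change"]
    overall = estimate_effect(t_out, p_out, "overall")
    subgroups = subgroup_effects(trial)
    nnt = number_needed_to_treat(
        t_out, p_out, config.outcome_model.clinically_meaningful_threshold
    )
    predictions, confusion, table, ranking, slices = _ml_analysis(trial, config, drop=_drop)
    scenario = "baseline" if _drop is None else "deficiency"
    log.info("%s scenario finished in %.1fs", scenario, time.perf_counter() - t0)
    return ScenarioResult(
        scenario=scenario,
        config=config,
        trial=trial,
        overall_effect=overall,
        subgroup_estimates=subgroups,
        nnt=nnt,
        confusion=confusion,
        ranking=ranking,
        slices=slices,
        attribution=table,
        predictions=predictions,
        dropped_variable=_drop,
        provenance=_provenance(config, scenario=scenario, dropped_variable=_drop),
    )


def run_deficiency(config: ScenarioConfig, drop: str = "z") -> ScenarioResult:
    """Same trial as baseline under the same master seed; ``drop`` (default
    z) is withheld from model training, never from the generator."""
    return run_baseline(config, _drop=drop)


def run_excess(config: ScenarioConfig, resample: bool = True) -> ExcessResult:
    """Boosted-classifier accuracy as noisy-variable banks grow.

    Each grid point resamples the whole cohort with a fresh seed by
    default; ``resample=False`` augments one fixed baseline cohort
    instead (ablation mode).
    """
    rows = []
    base_trial = None
    if not resample:
        base_trial = simulate_trial(
            config.n_patients, config.rule, config.outcome_model, config.master_seed
        )
    for i, n_noisy in enumerate(config.noise_grid):
        point_seed = [config.master_seed, 1, i] if resample else config.master_seed
        trial = base_trial if base_trial is not None else simulate_trial(
            config.n_patients, config.rule, config.outcome_model, point_seed
        )
        spec = dataclasses.replace(config.noise_spec, n_noisy=int(n_noisy))
        noisy_trial = add_noise_variables(trial, spec, [config.master_seed, 2, i])
        point_cfg = dataclasses.replace(
            config,
            master_seed=point_seed if isinstance(point_seed, int) else int(
                np.random.SeedSequence(point_seed).generate_state(1)[0] % (2**31)
            ),
        )
        t0 = time.perf_counter()
        _, confusion, _, ranking, _ = _ml_analysis(
            noisy_trial, point_cfg, learners=("xgb",), interrogate=True
        )
        out_ci = confusion["xgb_vs_outcome"].accuracy_ci
        tru_ci = confusion["xgb_vs_truth"].accuracy_ci
        rows.append(
            {
                "n_noisy": int(n_noisy),
                "accuracy_vs_outcome": confusion["xgb_vs_outcome"].accuracy,
                "outcome_ci_low": out_ci[0],
                "outcome_ci_high": out_ci[1],
                "accuracy_vs_truth": confusion["xgb_vs_truth"].accuracy,
                "truth_ci_low": tru_ci[0],
                "truth_ci_high": tru_ci[1],
                "top3_features": ",".join(ranking["feature"].head(3).sort_values()),
            }
        )
        log.info("excess point n_noisy=%d done in %.1fs", n_noisy, time.perf_counter() - t0)
    return ExcessResult(
        config=config,
        curve=pd.DataFrame(rows),
        provenance=_provenance(config, scenario="excess", resample=resample),
    )


def run_power(config: ScenarioConfig) -> PowerResult:
    """Replicate the entire generation + boosted-CV pipeline and score the
    fraction of runs beating the ground-truth accuracy criterion."""
    accuracies = []
    for r in range(config.n_replicates):
        rep_seed = int(
            np.random.SeedSequence([config.master_seed, 3, r]).generate_state(1)[0] % (2**31)
        )
        rep_cfg = dataclasses.replace(config, master_seed=rep_seed)
        trial = simulate_trial(rep_cfg.n_patients, rep_cfg.rule, rep_cfg.outcome_model, rep_seed)
        _, confusion, *_ = _ml_analysis(
            trial, rep_cfg, learners=("xgb",), interrogate=False
        )
        accuracies.append(confusion["xgb_vs_truth"].accuracy)
    successes = int(np.sum(np.asarray(accuracies) > config.success_accuracy))
    return PowerResult(
        n_runs=config.n_replicates,
        n_success=successes,
        success_fraction=successes / config.n_replicates,
        accuracies=accuracies,
        config=config,
        provenance=_provenance(config, scenario="power"),
    )


def run_scenario(config: ScenarioConfig):
    """Dispatch on ``config.scenario``."""
    runner = {
        "baseline": run_baseline,
        "deficiency": run_deficiency,
        "excess": run_excess,
        "power": run_power,
    }.get(config.scenario)
    if runner is None:
        raise ValueError(f"unknown scenario: {config.scenario!r}")
    return runner(config)


def _effects_frame(estimates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": e.label,
                "n_treatment": e.n_treatment,
                "n_placebo": e.n_placebo,
                "mean_diff": e.mean_diff,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
            }
            for e in estimates
        ]
    )


def write_report(result, output_dir) -> list[Path]:
    """Serialise a scenario result as CSV/JSON artifacts.

    Baseline/deficiency: trial table, forest table, confusion summaries,
    attribution ranking, long-form attributions, slice tables, manifest.
    Excess: the accuracy curve + manifest.  Power: the per-run accuracies
    and success fraction + manifest.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_json(name: str, payload: dict):
        path = out / name
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        written.append(path)

    def _write_csv(name: str, frame: pd.DataFrame):
        path = out / name
        frame.to_csv(path, index=False)
        written.append(path)

    if isinstance(result, ScenarioResult):
        _write_csv("trial.csv", result.trial)
        effects = _effects_frame([result.overall_effect] + list(result.subgroup_estimates))
        _write_csv("forest_table.csv", effects)
        tag = f"_without_{result.dropped_variable}" if result.dropped_variable else ""
        for key, summary in result.confusion.items():
            payload = summary.to_dict()
            payload["scenario"] = result.scenario
            payload["omitted_variable"] = result.dropped_variable
            _write_json(f"confusion_{key}{tag}.json", payload)
        _write_csv("feature_ranking.csv", result.ranking)
        _write_csv("attributions.csv", result.attribution.to_long(result.trial))
        for feat, (points, bins) in result.slices.items():
            _write_csv(f"slice_{feat}_points.csv", points)
            _write_csv(f"slice_{feat}_bins.csv", bins)
        _write_json(
            "manifest.json",
            {
                "provenance": result.provenance,
                "config": result.config.to_dict(),
                "nnt": result.nnt,
                "overall_effect": dataclasses.asdict(result.overall_effect),
            },
        )
    elif isinstance(result, ExcessResult):
        _write_csv("excess_curve.csv", result.curve)
        _write_json(
            "manifest.json", {"provenance": result.provenance, "config": result.config.to_dict()}
        )
    elif isinstance(result, PowerResult):
        _write_json(
            "power.json",
            {
                "n_runs": result.n_runs,
                "n_success": result.n_success,
                "success_fraction": result.success_fraction,
                "accuracies": result.accuracies,
            },
        )
        _write_json(
            "manifest.json", {"provenance": result.provenance, "config": result.config.to_dict()}
        )
    else:
        raise TypeError(f"cannot report a {type(result).__name__}")
    return written
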