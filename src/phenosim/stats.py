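"""Traditional inferential analysis of a simulated trial.

Effect estimates are unadjusted mean differences between arms with
z-based (1.96) 95% confidence intervals using unpooled variances; the
number needed to treat is the reciprocal risk difference at the
clinically-meaningful outcome threshold.  Subgroup estimates are reported
without multiplicity adjustment, mirroring conventional forest-plot
reporting of a primary trial outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .cohort import CORE_VARIABLES, ResponseRule

__all__ = [
    "EffectEstimate",
    "GroupComparison",
    "estimate_effect",
    "subgroup_effects",
    "default_subgroups",
    "number_needed_to_treat",
    "compare_by_truth",
    "detectable_effect",
]

_Z95 = 1.96


@dataclass(frozen=True)
class EffectEstimate:
    """Mean outcome-change difference (treatment − placebo) with 95% CI."""

    label: str
    n_treatment: int
    n_placebo: int
    mean_diff: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class GroupComparison:
    """Descriptive responsive-vs-non-responsive contrast for one variable."""

    variable: str
    mean_nonresponsive: float
    sd_nonresponsive: float
    mean_responsive: float
    sd_responsive: float
    p_value: float


def estimate_effect(treatment_outcomes, placebo_outcomes, label: str = "overall") -> EffectEstimate:
    """Unpooled-variance z interval for the between-arm mean difference."""
    t = np.asarray(treatment_outcomes, dtype=float)
    p = np.asarray(placebo_outcomes, dtype=float)
    if t.size == 0 or p.size == 0:
        raise ValueError("both outcome collections must be non-empty")
    diff = t.mean() - p.mean()
    var_t = t.var(ddof=1) if t.size > 1 else 0.0
    var_p = p.var(ddof=1) if p.size > 1 else 0.0
    half = _Z95 * math.sqrt(var_t / t.size + var_p / p.size)
    return EffectEstimate(label, t.size, p.size, diff, diff - half, diff + half)


def default_subgroups(
    trial: pd.DataFrame, rule: ResponseRule | None = None
) -> list[tuple[str, np.ndarray]]:
    """Per-variable subgroup masks: binary variables split on 0/1,
    continuous ones on the cohort median (rule-threshold splits for x and
    y can be obtained by passing explicit definitions instead)."""
    defs: list[tuple[str, np.ndarray]] = []
    for name in CORE_VARIABLES:
        vals = trial[name].to_numpy()
        if set(np.unique(vals)) <= {0, 1}:
            defs.append((f"{name}=1", vals == 1))
            defs.append((f"{name}=0", vals == 0))
        else:
            med = np.median(vals)
            defs.append((f"{name}>={med:g}", vals >= med))
            defs.append((f"{name}<{med:g}", vals < med))
    return defs


def subgroup_effects(
    trial: pd.DataFrame,
    subgroup_definitions: Sequence[tuple[str, np.ndarray | Callable]] | None = None,
) -> list[EffectEstimate]:
    """One unadjusted effect estimate per subgroup.

    A definition is (label, boolean mask) or (label, predicate on the
    trial frame).  Subgroups with an empty arm yield an estimate whose
    statistics are NaN (reported, not raised).
    """
    if subgroup_definitions is None:
        subgroup_definitions = default_subgroups(trial)
    treated = (trial["arm"] == "treatment").to_numpy()
    outcome = trial["outcome_change"].to_numpy()
    out: list[EffectEstimate] = []
    for label, sel in subgroup_definitions:
        mask = np.asarray(sel(trial) if callable(sel) else sel, dtype=bool)
        t = outcome[mask & treated]
        p = outcome[mask & ~treated]
        if t.size == 0 or p.size == 0:
            out.append(EffectEstimate(label, t.size, p.size, math.nan, math.nan, math.nan))
        else:
            out.append(estimate_effect(t, p, label))
    return out


def number_needed_to_treat(treatment_outcomes, placebo_outcomes, threshold: float = 5.0) -> float:
    """NNT = 1 / (risk difference of reaching the threshold).

    Returns ``inf`` when the risk difference is zero or negative (no
    finite number of treated patients yields one extra success).
    """
    t = np.asarray(treatment_outcomes, dtype=float)
    p = np.asarray(placebo_outcomes, dtype=float)
    if t.size == 0 or p.size == 0:
        raise ValueError("both outcome collections must be non-empty")
    risk_diff = (t >= threshold).mean() - (p >= threshold).mean()
    if risk_diff <= 0:
        return math.inf
    return 1.0 / risk_diff


def compare_by_truth(trial: pd.DataFrame, variable: str) -> GroupComparison:
    """Contrast one covariate between latent responders and non-responders.

    Continuous variables use Welch's two-sample t test; binary ones a
    two-proportion z test.  Means/SDs are reported per truth group either
    way (for a binary variable the mean is its prevalence).
    """
    truth = trial["responsive_truth"].to_numpy()
    vals = trial[variable].to_numpy(dtype=float)
    resp, non = vals[truth == 1], vals[truth == 0]
    if resp.size == 0 or non.size == 0:
        raise ValueError("both truth groups must be non-empty")
    binary = set(np.unique(vals)) <= {0.0, 1.0}
    if binary:
        counts = np.array([resp.sum(), non.sum()])
        nobs = np.array([resp.size, non.size])
        if counts[0] / nobs[0] == counts[1] / nobs[1]:
            p_value = 1.0
        else:
            _, p_value = proportions_ztest(counts, nobs)
    elif np.var(resp) == 0 and np.var(non) == 0 and resp.mean() == non.mean():
        p_value = 1.0
    else:
        _, p_value = sps.ttest_ind(resp, non, equal_var=False)
    return GroupComparison(
        variable,
        float(non.mean()),
        float(non.std(ddof=1)),
        float(resp.mean()),
        float(resp.std(ddof=1)),
        float(p_value),
    )


def detectable_effect(
    n_per_arm: int, power: float = 0.8, alpha: float = 0.05, sd: float = 3.0
) -> float:
    """Minimal detectable two-sample mean difference (normal approximation):
    (z_{1-alpha/2} + z_{power}) * sd * sqrt(2 / n_per_arm)."""
    if not 0 < power < 1 or not 0 < alpha < 1:
        raise ValueError("power and alpha must lie strictly between 0 and 1")
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be positive")
    z = sps.norm.ppf(1 - alpha / 2) + sps.norm.ppf(power)
    return float(z * sd * math.sqrt(2.0 / n_per_arm))
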