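"""Simulated clinical cohorts with a hidden, rule-determined treatment response.

This module is the data-generating process for a parallel-group,
placebo-controlled trial of a treatment whose benefit depends on the
interaction of three phenotype variables.  Each patient carries seven
covariates drawn independently:

===========  =========================================
variable     marginal distribution
===========  =========================================
``age``      integer, uniform on [18, 100]
``sex``      Bernoulli(1/2)
``v1``       Bernoulli(1/2)
``v2``       integer, uniform on [0, 200]
``x``        integer, uniform on [50, 100]
``y``        integer, uniform on [40, 100]
``z``        Bernoulli(1/2)
===========  =========================================

A patient is *ground-truth responsive* to the treatment when

* ``x >= 95``, regardless of anything else; or
* ``z = 1`` and ``50 <= y <= 90``; or
* ``z = 0`` and ``90 <= x <= 94`` and ``50 <= y <= 90``.

``age``, ``sex``, ``v1`` and ``v2`` never influence responsiveness — they
exist so analyses must separate signal from plausible-looking noise.
Responsiveness is latent: trial analyses only observe the realised outcome
change, which is N(10, 3) for treated responders and N(0, 3) for everyone
else (placebo patients and treated non-responders alike).

Randomisation is simple per-patient Bernoulli(1/2), so arm sizes are
themselves random (a 1000-patient trial typically splits near 509/491
rather than exactly 500/500).

Four independent random streams (phenotypes, randomisation, outcomes,
noise variables) are spawned from one master seed, so perturbation
scenarios can hold the cohort fixed while re-drawing other components.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CORE_VARIABLES",
    "VARIABLE_RANGES",
    "ResponseRule",
    "OutcomeModel",
    "NoiseSpec",
    "seed_streams",
    "draw_phenotypes",
    "is_responsive",
    "responsive_mask",
    "simulate_trial",
    "add_noise_variables",
    "remove_variable",
]

#: The seven core phenotype variables, in canonical column order.
CORE_VARIABLES = ("age", "sex", "v1", "v2", "x", "y", "z")

#: Inclusive integer range of each core variable.
VARIABLE_RANGES = {
    "age": (18, 100),
    "sex": (0, 1),
    "v1": (0, 1),
    "v2": (0, 200),
    "x": (50, 100),
    "y": (40, 100),
    "z": (0, 1),
}

_BINARY_CORE = ("sex", "v1", "z")


@dataclass(frozen=True)
class ResponseRule:
    """Thresholds of the non-linear responder rule over (x, y, z).

    ``x_high`` is the unconditional-response floor for x (inclusive);
    ``x_mid_low`` opens the conditional x-window [x_mid_low, x_high - 1]
    that applies when z is absent; ``y_low``/``y_high`` bound the inclusive
    y-band required whenever x < x_high.
    """

    x_high: int = 95
    x_mid_low: int = 90
    y_low: int = 50
    y_high: int = 90

    def __post_init__(self) -> None:
        if not self.x_mid_low < self.x_high:
            raise ValueError("x_mid_low must be strictly below x_high")
        if not self.y_low < self.y_high:
            raise ValueError("y_low must be strictly below y_high")
        x_lo, x_hi = VARIABLE_RANGES["x"]
        y_lo, y_hi = VARIABLE_RANGES["y"]
        if not (x_lo <= self.x_mid_low and self.x_high <= x_hi):
            raise ValueError("x thresholds outside the declared range of x")
        if not (y_lo <= self.y_low and self.y_high <= y_hi):
            raise ValueError("y thresholds outside the declared range of y")


@dataclass(frozen=True)
class OutcomeModel:
    """Gaussian outcome-change model, in arbitrary outcome units.

    Treated responders draw their change from N(mu_responsive, sigma);
    everyone else from N(mu_nonresponsive, sigma).  ``sigma = 0`` is
    permitted as a degenerate noise-free variant.
    """

    mu_responsive: float = 10.0
    mu_nonresponsive: float = 0.0
    sigma: float = 3.0
    clinically_meaningful_threshold: float = 5.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not self.mu_responsive > self.mu_nonresponsive:
            raise ValueError("mu_responsive must exceed mu_nonresponsive")


@dataclass(frozen=True)
class NoiseSpec:
    """Recipe for banks of uninformative ("noisy") extra variables.

    Of ``n_noisy`` variables, ``n_noisy // 6`` covary with each of x, y
    (variable + N(0, sd_x_noise)) and z (binary, with exactly
    ``round(z_match_fraction * n_patients)`` randomly chosen entries equal
    to the patient's z); the remainder are independent, alternating
    Bernoulli(``indep_binary_prevalence``) and uniform integers on
    ``indep_continuous_range``.  ``z_mismatch`` controls entries of a
    z-linked variable not selected to match: ``"flip"`` sets them to
    ``1 - z``, ``"uniform"`` redraws them fair-coin.
    """

    n_noisy: int = 0
    sd_x_noise: float = 10.0
    z_match_fraction: float = 2.0 / 3.0
    indep_binary_prevalence: float = 0.10
    indep_continuous_range: tuple[int, int] = (18, 100)
    z_mismatch: str = "flip"

    def __post_init__(self) -> None:
        if self.n_noisy < 0:
            raise ValueError("n_noisy must be non-negative")
        if not 0 < self.z_match_fraction <= 1:
            raise ValueError("z_match_fraction must lie in (0, 1]")
        if not 0 <= self.indep_binary_prevalence <= 1:
            raise ValueError("indep_binary_prevalence must lie in [0, 1]")
        if self.z_mismatch not in ("flip", "uniform"):
            raise ValueError("z_mismatch must be 'flip' or 'uniform'")

    def class_sizes(self) -> dict[str, int]:
        """Deterministic split of ``n_noisy`` into the four classes.

        Each linked class gets ``n_noisy // 6``; the remainder is
        independent (so the defaults realise the 1/6, 1/6, 1/6, 1/2 split
        whenever ``n_noisy`` is a multiple of 6).
        """
        linked = self.n_noisy // 6
        return {
            "x_linked": linked,
            "y_linked": linked,
            "z_linked": linked,
            "independent": self.n_noisy - 3 * linked,
        }


_STREAMS = ("phenotypes", "randomisation", "outcomes", "noise")


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def seed_streams(master_seed) -> dict[str, np.random.SeedSequence]:
    """Spawn the four named child streams from one master seed.

    Spawning is deterministic, so any component can be re-derived in
    isolation: e.g. the ``phenotypes`` stream alone reproduces the cohort
    while the ``outcomes`` stream is replaced.
    """
    children = _as_seedseq(master_seed).spawn(len(_STREAMS))
    return dict(zip(_STREAMS, children))


def draw_phenotypes(n: int, seed) -> pd.DataFrame:
    """Draw ``n`` independent phenotype records.

    Returns a DataFrame with the seven core columns in canonical order,
    integer dtype, indexed 0..n-1.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(_as_seedseq(seed))
    cols = {}
    for name in CORE_VARIABLES:
        lo, hi = VARIABLE_RANGES[name]
        cols[name] = rng.integers(lo, hi + 1, size=n)
    return pd.DataFrame(cols)


def _check_ranges(x, y, z) -> None:
    x, y, z = np.asarray(x), np.asarray(y), np.asarray(z)
    for name, vals in (("x", x), ("y", y), ("z", z)):
        lo, hi = VARIABLE_RANGES[name]
        if np.any(vals < lo) or np.any(vals > hi):
            raise ValueError(f"{name} value outside its declared range [{lo}, {hi}]")


def responsive_mask(x, y, z, rule: ResponseRule | None = None, *, validate: bool = True):
    """Vectorised ground-truth responder rule; returns an int (0/1) array."""
    rule = rule or ResponseRule()
    if validate:
        _check_ranges(x, y, z)
    x, y, z = np.asarray(x), np.asarray(y), np.asarray(z)
    y_band = (y >= rule.y_low) & (y <= rule.y_high)
    mask = (
        (x >= rule.x_high)
        | ((z == 1) & y_band)
        | ((z == 0) & (x >= rule.x_mid_low) & (x < rule.x_high) & y_band)
    )
    return mask.astype(np.int64)


def is_responsive(x: int, y: int, z: int, rule: ResponseRule | None = None) -> int:
    """Scalar responder rule: 1 if (x, y, z) is treatment-responsive."""
    return int(responsive_mask(x, y, z, rule))


def simulate_trial(
    n: int,
    rule: ResponseRule | None = None,
    model: OutcomeModel | None = None,
    seed=0,
) -> pd.DataFrame:
    """Simulate a full 1:1-randomised placebo-controlled trial.

    Draws ``n`` phenotypes, computes latent responsiveness, assigns arms by
    per-patient fair coin, and realises the outcome change from the
    two-Gaussian model.  Columns: ``patient_id`` (1..n), the seven core
    variables, ``arm`` ("treatment"/"placebo"), ``responsive_truth``,
    ``outcome_change``.
    """
    if n < 2:
        raise ValueError("a trial needs at least 2 patients")
    rule = rule or ResponseRule()
    model = model or OutcomeModel()
    streams = seed_streams(seed)

    cohort = draw_phenotypes(n, streams["phenotypes"])
    truth = responsive_mask(cohort["x"], cohort["y"], cohort["z"], rule, validate=False)

    rng_arm = np.random.default_rng(streams["randomisation"])
    treated = rng_arm.integers(0, 2, size=n).astype(bool)

    rng_out = np.random.default_rng(streams["outcomes"])
    mu = np.where(treated & (truth == 1), model.mu_responsive, model.mu_nonresponsive)
    outcome = rng_out.normal(mu, model.sigma) if model.sigma > 0 else mu.astype(float)

    trial = cohort.copy()
    trial.insert(0, "patient_id", np.arange(1, n + 1))
    trial["arm"] = np.where(treated, "treatment", "placebo")
    trial["responsive_truth"] = truth
    trial["outcome_change"] = outcome
    return trial


def _noise_names(n_noisy: int) -> list[str]:
    width = max(4, len(str(n_noisy)))
    return [f"n{i:0{width}d}" for i in range(1, n_noisy + 1)]


def add_noise_variables(cohort: pd.DataFrame, spec: NoiseSpec, seed) -> pd.DataFrame:
    """Append ``spec.n_noisy`` uninformative variables to a cohort.

    Class assignment follows a fixed index order: x-linked block first,
    then y-linked, z-linked, then independents (alternating binary /
    continuous).  The input cohort is never modified.
    """
    if spec.n_noisy == 0:
        return cohort.copy()
    sizes = spec.class_sizes()
    n_pat = len(cohort)
    rng = np.random.default_rng(_as_seedseq(seed))

    block = np.empty((n_pat, spec.n_noisy), dtype=np.float64)
    pos = 0

    for var in ("x", "y"):
        k = sizes[f"{var}_linked"]
        if k:
            base = cohort[var].to_numpy(dtype=np.float64)[:, None]
            block[:, pos : pos + k] = base + rng.normal(0.0, spec.sd_x_noise, size=(n_pat, k))
            pos += k

    k = sizes["z_linked"]
    if k:
        z = cohort["z"].to_numpy(dtype=np.float64)[:, None]
        n_match = int(round(spec.z_match_fraction * n_pat))
        # per-column random permutation: the first n_match ranks match z
        ranks = np.argsort(rng.random((n_pat, k)), axis=0)
        match = np.zeros((n_pat, k), dtype=bool)
        np.put_along_axis(match, ranks[:n_match, :], True, axis=0)
        if spec.z_mismatch == "flip":
            other = 1.0 - z
        else:
            other = rng.integers(0, 2, size=(n_pat, k)).astype(np.float64)
        block[:, pos : pos + k] = np.where(match, z, other)
        pos += k

    k = sizes["independent"]
    if k:
        n_binary = (k + 1) // 2  # even independent indices are binary
        n_cont = k - n_binary
        indep = np.empty((n_pat, k))
        indep[:, 0::2] = (
            rng.random((n_pat, n_binary)) < spec.indep_binary_prevalence
        ).astype(np.float64)
        if n_cont:
            lo, hi = spec.indep_continuous_range
            indep[:, 1::2] = rng.integers(lo, hi + 1, size=(n_pat, n_cont))
        block[:, pos : pos + k] = indep
        pos += k

    noisy = pd.DataFrame(block, columns=_noise_names(spec.n_noisy), index=cohort.index)
    return pd.concat([cohort, noisy], axis=1)


def remove_variable(cohort: pd.DataFrame, name: str) -> pd.DataFrame:
    """Return a copy of the cohort lacking ``name`` (KeyError if absent)."""
    if name not in cohort.columns:
        raise KeyError(name)
    return cohort.drop(columns=[name])
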