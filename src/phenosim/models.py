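"""Cross-validated prediction of treatment response from phenotype data.

Two learners, trained on treatment-arm patients only and on the noisy
trial-outcome label (change >= 5), never on ground truth:

* a gradient-boosted tree classifier (XGBoost; depth 3, learning rate 0.1,
  100 rounds, 0.8 row and feature subsampling), and
* an L2-regularised logistic comparator augmented with all pairwise
  feature products.

Both produce out-of-fold predictions under unstratified shuffled k-fold
(k = 5 by default): every patient is predicted exactly once, by the model
that never saw them.  Continuous features are centred/scaled using
training-fold statistics only; binary features pass through unscaled.
Accuracy intervals use the normal approximation to the binomial.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.preprocessing import PolynomialFeatures
from xgboost import XGBClassifier

__all__ = [
    "BoostParams",
    "LogisticParams",
    "PredictionSet",
    "ConfusionSummary",
    "binarize_outcome",
    "infer_binary_columns",
    "standardize",
    "oof_predict",
    "evaluate",
    "accuracy_ci",
]

_Z95 = 1.96


@dataclass(frozen=True)
class BoostParams:
    """Fixed gradient-boosting hyperparameters (no tuning by design)."""

    max_depth: int = 3
    learning_rate: float = 0.1
    n_rounds: int = 100
    row_subsample: float = 0.8
    feature_subsample: float = 0.8
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.max_depth < 1 or self.n_rounds < 1:
            raise ValueError("depth and rounds must be >= 1")
        if not (0 < self.row_subsample <= 1 and 0 < self.feature_subsample <= 1):
            raise ValueError("subsample fractions must lie in (0, 1]")


@dataclass(frozen=True)
class LogisticParams:
    """L2 logistic-regression comparator settings (lbfgs solver)."""

    tolerance: float = 1e-4
    max_iterations: int = 100
    include_pairwise_interactions: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class PredictionSet:
    """Out-of-fold predictions plus everything needed to interrogate them.

    ``ids``/``predicted_label``/``fold_index`` are aligned to the original
    row order of the feature frame.  ``models`` holds one fitted
    per-fold estimator, ``fold_rows`` the positional held-out indices of
    each fold and ``fold_features`` the scaled held-out design matrix each
    model was asked to predict (for gradient boosting, the matrix its
    Shapley attributions are computed on).
    """

    ids: np.ndarray
    predicted_label: np.ndarray
    fold_index: np.ndarray
    feature_names: list[str]
    models: list
    fold_rows: list[np.ndarray]
    fold_features: list[pd.DataFrame]
    params: object
    seed: int
    features: pd.DataFrame
    labels: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": self.ids, "fold": self.fold_index, "predicted_label": self.predicted_label}
        )


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts with derived rates and a binomial accuracy CI."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    accuracy_ci: tuple[float, float]

    @classmethod
    def from_labels(cls, predicted, reference) -> "ConfusionSummary":
        pred = np.asarray(predicted, dtype=int)
        ref = np.asarray(reference, dtype=int)
        tp = int(np.sum((pred == 1) & (ref == 1)))
        fp = int(np.sum((pred == 1) & (ref == 0)))
        fn = int(np.sum((pred == 0) & (ref == 1)))
        tn = int(np.sum((pred == 0) & (ref == 0)))

        def _rate(num, den):
            return num / den if den else math.nan

        total = tp + fp + fn + tn
        return cls(
            tp, fp, fn, tn,
            sensitivity=_rate(tp, tp + fn),
            specificity=_rate(tn, tn + fp),
            ppv=_rate(tp, tp + fp),
            npv=_rate(tn, tn + fn),
            accuracy=_rate(tp + tn, total),
            accuracy_ci=accuracy_ci(tp + tn, total),
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
        }


def binarize_outcome(outcome_changes, threshold: float = 5.0) -> np.ndarray:
    """Label 1 iff the outcome change is at or above the threshold."""
    vals = np.asarray(outcome_changes, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("outcome changes must be finite")
    return (vals >= threshold).astype(int)


def infer_binary_columns(features: pd.DataFrame) -> np.ndarray:
    """Boolean mask of columns whose observed values are a subset of {0, 1}."""
    mask = np.zeros(features.shape[1], dtype=bool)
    for j, col in enumerate(features.columns):
        u = pd.unique(features[col])
        mask[j] = np.isin(u, (0, 1)).all()
    return mask


def standardize(
    features: pd.DataFrame,
    binary_mask: np.ndarray | None = None,
    fit_rows: np.ndarray | None = None,
) -> pd.DataFrame:
    """Centre/scale continuous columns using statistics from ``fit_rows``.

    Binary columns pass through untouched.  A continuous column constant
    on the fit rows is left unscaled with a warning.
    """
    if binary_mask is None:
        binary_mask = infer_binary_columns(features)
    arr = features.to_numpy(dtype=float, copy=True)
    fit = arr if fit_rows is None else arr[np.asarray(fit_rows)]
    if fit.shape[0] == 0:
        raise ValueError("fit_rows must select at least one row")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0)
    degenerate = (~binary_mask) & (sd == 0)
    if degenerate.any():
        names = list(features.columns[degenerate])
        warnings.warn(f"zero-variance continuous column(s) left unscaled: {names}")
    scale = (~binary_mask) & (sd > 0)
    arr[:, scale] = (arr[:, scale] - mean[scale]) / sd[scale]
    return pd.DataFrame(arr, columns=features.columns, index=features.index)


def _interaction_frame(scaled: pd.DataFrame) -> pd.DataFrame:
    """Append all pairwise (distinct) products of the scaled features."""
    poly = PolynomialFeatures(degree=2, interaction_only=True, include_bias=False)
    arr = poly.fit_transform(scaled.to_numpy())
    names = poly.get_feature_names_out(scaled.columns)
    return pd.DataFrame(arr, columns=list(names), index=scaled.index)


def _make_model(params, seed: int):
    if isinstance(params, BoostParams):
        return XGBClassifier(
            max_depth=params.max_depth,
            learning_rate=params.learning_rate,
            n_estimators=params.n_rounds,
            subsample=params.row_subsample,
            colsample_bytree=params.feature_subsample,
            objective="binary:logistic",
            base_score=0.5,
            tree_method="hist",
            eval_metric="logloss",
            n_jobs=params.n_jobs,
            random_state=seed,
        )
    if isinstance(params, LogisticParams):
        # default penalty is ridge (L2) with C=1.0
        return LogisticRegression(
            tol=params.tolerance,
            max_iter=params.max_iterations,
            solver="lbfgs",
        )
    raise TypeError(f"unsupported model params: {type(params).__name__}")


def oof_predict(
    features: pd.DataFrame,
    labels,
    model_params,
    k_folds: int = 5,
    seed: int = 0,
) -> PredictionSet:
    """Unstratified shuffled k-fold out-of-fold prediction.

    Scaling (and, for the logistic comparator, the pairwise-interaction
    expansion) is fitted on each training split only, so no information
    leaks from held-out patients.  Deterministic under a fixed seed.
    """
    y = np.asarray(labels, dtype=int)
    n = len(features)
    if n != y.size:
        raise ValueError("features and labels must have equal length")
    if n < k_folds:
        raise ValueError("need at least as many rows as folds")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present overall")
    binary_mask = infer_binary_columns(features)
    logistic = isinstance(model_params, LogisticParams)

    predicted = np.empty(n, dtype=int)
    fold_of = np.empty(n, dtype=int)
    models, fold_rows, fold_features = [], [], []
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)  # tolerate degenerate noise columns
        for i, (train_idx, test_idx) in enumerate(kf.split(features)):
            y_train = y[train_idx]
            if len(np.unique(y_train)) < 2:
                raise ValueError(f"training split of fold {i} contains a single class")
            scaled = standardize(features, binary_mask, fit_rows=train_idx)
            if logistic and model_params.include_pairwise_interactions:
                scaled = _interaction_frame(scaled)
            model = _make_model(model_params, seed)
            model.fit(scaled.iloc[train_idx], y_train)
            test_scaled = scaled.iloc[test_idx]
            predicted[test_idx] = np.asarray(model.predict(test_scaled), dtype=int)
            fold_of[test_idx] = i
            models.append(model)
            fold_rows.append(test_idx)
            fold_features.append(test_scaled)

    return PredictionSet(
        ids=np.asarray(features.index),
        predicted_label=predicted,
        fold_index=fold_of,
        feature_names=list(features.columns),
        models=models,
        fold_rows=fold_rows,
        fold_features=fold_features,
        params=model_params,
        seed=seed,
        features=features,
        labels=y,
    )


def evaluate(predictions: PredictionSet, reference_labels) -> ConfusionSummary:
    """Score out-of-fold predictions against a reference labelling.

    ``reference_labels`` may be a pandas Series indexed by patient id (any
    order) or a plain array aligned with ``predictions.ids``.
    """
    if isinstance(reference_labels, pd.Series):
        if set(reference_labels.index) != set(predictions.ids):
            raise ValueError("reference label ids do not match predicted ids")
        ref = reference_labels.loc[predictions.ids].to_numpy()
    else:
        ref = np.asarray(reference_labels)
        if ref.size != predictions.ids.size:
            raise ValueError("reference labels length does not match predictions")
    return ConfusionSummary.from_labels(predictions.predicted_label, ref)


def accuracy_ci(correct: int, total: int) -> tuple[float, float]:
    """Normal-approximation binomial 95% CI for a proportion, clipped to [0, 1]."""
    if total < 1:
        raise ValueError("total must be at least 1")
    if not 0 <= correct <= total:
        raise ValueError("correct must lie between 0 and total")
    p = correct / total
    half = _Z95 * math.sqrt(p * (1 - p) / total)
    return (max(0.0, p - half), min(1.0, p + half))
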