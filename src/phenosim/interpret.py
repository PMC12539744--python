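"""Shapley-additive interrogation of fitted gradient-boosted classifiers.

Attributions are exact TreeSHAP values in margin (log-odds) units, where
additivity is exact: per patient, the base value plus the sum of feature
attributions equals the model's margin output.  By default each fold
model explains its own held-out patients, so the explained population is
exactly the out-of-fold-predicted population; a refit-on-everything
variant is available behind ``out_of_fold=False``.

Feature influence is ranked by the summed absolute attribution across all
predictions; conditional slices (scatter of value vs attribution plus a
binned predicted-responsive proportion) recover the responder rule's
thresholds from the fitted model alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost

from .models import BoostParams, PredictionSet, _make_model, infer_binary_columns, standardize

__all__ = ["AttributionTable", "SliceSpec", "attribute", "rank_features", "slice_attributions"]


@dataclass
class AttributionTable:
    """Per-patient, per-feature Shapley attributions in margin units."""

    attributions: pd.DataFrame  # rows indexed by patient id, one column per feature
    base_values: pd.Series
    margins: pd.Series
    predicted_label: pd.Series

    @property
    def patient_ids(self) -> np.ndarray:
        return np.asarray(self.attributions.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.attributions.columns)

    def additivity_error(self) -> float:
        """max |base + sum(attributions) - margin| over patients."""
        total = self.base_values + self.attributions.sum(axis=1)
        return float(np.max(np.abs(total - self.margins)))

    def to_long(self, cohort: pd.DataFrame | None = None) -> pd.DataFrame:
        """Long-form (patient_id, feature, value, attribution, predicted_label)."""
        long = self.attributions.reset_index(names="patient_id").melt(
            id_vars="patient_id", var_name="feature", value_name="attribution"
        )
        if cohort is not None:
            vals = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
            long["value"] = [
                vals.at[pid, feat] for pid, feat in zip(long["patient_id"], long["feature"])
            ]
        long["predicted_label"] = self.predicted_label.loc[long["patient_id"]].to_numpy()
        return long


@dataclass(frozen=True)
class SliceSpec:
    """A conditional view of one feature's attributions.

    ``filters`` holds (feature, condition) pairs where a condition is an
    inclusive (low, high) interval or an exact (binary) value.  ``n_bins``
    overrides the default binning of the overlaid prediction-proportion
    histogram (default: unit-width integer bins for continuous features,
    one bin per level for binary ones).
    """

    target_feature: str
    filters: tuple = ()
    n_bins: int | None = None


def _contributions(model, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    booster = model.get_booster()
    dm = xgboost.DMatrix(features, feature_names=list(features.columns))
    contribs = booster.predict(dm, pred_contribs=True)
    return contribs[:, :-1], contribs[:, -1]  # per-feature terms, base value


def attribute(predictions: PredictionSet, out_of_fold: bool = True) -> AttributionTable:
    """Exact TreeSHAP attributions for a fitted boosted prediction set.

    With ``out_of_fold=True`` (default) each fold model explains the
    patients it predicted; with ``False`` a single model refit on all rows
    explains everyone.
    """
    if not isinstance(predictions.params, BoostParams):
        raise ValueError("attributions are defined for the gradient-boosted classifier only")

    if out_of_fold:
        n = predictions.ids.size
        attr = np.empty((n, len(predictions.feature_names)))
        base = np.empty(n)
        margin = np.empty(n)
        for model, rows, feats in zip(
            predictions.models, predictions.fold_rows, predictions.fold_features
        ):
            if list(feats.columns) != predictions.feature_names:
                raise ValueError("fold feature schema does not match the prediction set")
            a, b = _contributions(model, feats)
            attr[rows] = a
            base[rows] = b
            booster = model.get_booster()
            dm = xgboost.DMatrix(feats, feature_names=list(feats.columns))
            margin[rows] = booster.predict(dm, output_margin=True)
        predicted = predictions.predicted_label
    else:
        X = predictions.features
        scaled = standardize(X, infer_binary_columns(X))
        model = _make_model(predictions.params, predictions.seed)
        model.fit(scaled, predictions.labels)
        attr, base = _contributions(model, scaled)
        dm = xgboost.DMatrix(scaled, feature_names=list(scaled.columns))
        margin = model.get_booster().predict(dm, output_margin=True)
        predicted = np.asarray(model.predict(scaled), dtype=int)

    ids = predictions.ids
    return AttributionTable(
        attributions=pd.DataFrame(attr, index=ids, columns=predictions.feature_names),
        base_values=pd.Series(base, index=ids),
        margins=pd.Series(margin, index=ids),
        predicted_label=pd.Series(predicted, index=ids),
    )


def rank_features(table: AttributionTable) -> pd.DataFrame:
    """Features by summed |attribution| (descending; ties alphabetical)."""
    if table.attributions.empty:
        raise ValueError("attribution table is empty")
    importance = table.attributions.abs().sum(axis=0)
    ranked = (
        importance.rename("importance")
        .rename_axis("feature")
        .reset_index()
        .sort_values(["importance", "feature"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
    return ranked


def _apply_filters(values: pd.DataFrame, filters) -> np.ndarray:
    mask = np.ones(len(values), dtype=bool)
    for feat, cond in filters:
        if feat not in values.columns:
            raise KeyError(feat)
        col = values[feat].to_numpy()
        if np.isscalar(cond):
            mask &= col == cond
        else:
            lo, hi = cond
            if lo is not None:
                mask &= col >= lo
            if hi is not None:
                mask &= col <= hi
    return mask


def slice_attributions(
    table: AttributionTable, spec: SliceSpec, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conditional scatter points and binned predicted-responsive proportions.

    Returns ``(points, bins)``: points has one row per patient passing all
    filters (patient_id, value, attribution, predicted_label); bins gives,
    per target-feature value bin, the patient count and the fraction
    predicted responsive.  An empty slice yields two empty frames.
    """
    vals = cohort.set_index("patient_id") if "patient_id" in cohort.columns else cohort
    vals = vals.loc[table.patient_ids]
    mask = _apply_filters(vals, spec.filters)
    ids = table.patient_ids[mask]
    points = pd.DataFrame(
        {
            "patient_id": ids,
            "value": vals.loc[ids, spec.target_feature].to_numpy(),
            "attribution": table.attributions.loc[ids, spec.target_feature].to_numpy(),
            "predicted_label": table.predicted_label.loc[ids].to_numpy(),
        }
    )
    if points.empty:
        return points, pd.DataFrame(columns=["bin", "n", "proportion_responsive"])

    if spec.n_bins is not None:
        edges = np.histogram_bin_edges(points["value"], bins=spec.n_bins)
        which = np.clip(np.digitize(points["value"], edges[1:-1]), 0, spec.n_bins - 1)
        centers = (edges[:-1] + edges[1:]) / 2
        key = centers[which]
    else:
        key = np.round(points["value"].to_numpy()).astype(int)  # unit-width integer bins
    grouped = points.groupby(key)["predicted_label"]
    bins = pd.DataFrame(
        {
            "bin": grouped.mean().index,
            "n": grouped.size().to_numpy(),
            "proportion_responsive": grouped.mean().to_numpy(),
        }
    )
    return points, bins
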