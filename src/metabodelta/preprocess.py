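"""Preprocessing of GC-MS metabolite intensity tables and paired glucose measurements.

The raw input is a samples x metabolites matrix of relative intensities in
which a missing entry means the metabolite fell below the instrument's limit
of detection (LOD), plus a clinical table holding the two fasting-glucose
measurements and the elapsed follow-up time. This module turns those into
the analysis-ready objects: a LOD-imputed, log-transformed, centred feature
matrix and the response Δglucose = (follow-up − baseline) / elapsed years,
in mg/(dl·a).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "ClinicalTable",
    "CLINICAL_COLUMNS",
    "compute_delta_glucose",
    "impute_lod",
    "log_normalize",
]

STAGES = ("raw", "imputed", "log_normalized")

#: Required columns of a clinical table, in canonical order.
CLINICAL_COLUMNS = (
    "gender",
    "waist_cm",
    "bmi",
    "age_years",
    "glucose_baseline",
    "glucose_followup",
    "elapsed_years",
)


@dataclasses.dataclass
class FeatureMatrix:
    """Samples x metabolite intensity matrix with a processing-stage tag.

    Parameters
    ----------
    values
        DataFrame indexed by subject id with one column per metabolite
        feature id. NaN marks a below-LOD (missing) measurement; it is only
        legal in the ``raw`` stage.
    stage
        One of ``raw`` (positive intensities, NaN allowed), ``imputed``
        (positive, no NaN) or ``log_normalized`` (real-valued, no NaN).
    feature_names
        Optional display names keyed by feature id. Display names may repeat
        (two chromatographic peaks can resolve to the same compound); all
        joins are by the unique feature id.
    """

    values: pd.DataFrame
    stage: str = "raw"
    feature_names: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate subject id {dup!r}")
        arr = self.values.to_numpy(dtype=float)
        if self.stage in ("imputed", "log_normalized") and np.isnan(arr).any():
            raise ValueError(f"stage {self.stage!r} must not contain missing entries")
        if self.stage in ("raw", "imputed"):
            with np.errstate(invalid="ignore"):
                bad = arr <= 0
            if bad.any():
                i, j = map(int, np.argwhere(bad)[0])
                raise ValueError(
                    f"non-positive intensity at subject {self.values.index[i]!r}, "
                    f"feature {self.values.columns[j]!r} in stage {self.stage!r}"
                )
        if self.feature_names is not None:
            self.feature_names = self.feature_names.reindex(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def subject_ids(self) -> list:
        return list(self.values.index)

    def subset(self, feature_ids: Iterable) -> "FeatureMatrix":
        """Column subset preserving stage and names."""
        ids = list(feature_ids)
        missing = [f for f in ids if f not in self.values.columns]
        if missing:
            raise KeyError(f"unknown feature ids {missing}")
        names = None if self.feature_names is None else self.feature_names.loc[ids]
        return FeatureMatrix(self.values[ids].copy(), stage=self.stage, feature_names=names)


@dataclasses.dataclass
class ClinicalTable:
    """Per-subject covariates plus the paired fasting-glucose measurements.

    ``gender`` is categorical ("female"/"male"); waist circumference in cm,
    BMI in kg/m², age in years, the two glucose levels in mg/dl and the
    elapsed follow-up time in years (strictly positive).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns {missing}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate subject id {dup!r}")
        for col in ("glucose_baseline", "glucose_followup"):
            bad = self.data.index[self.data[col].to_numpy(dtype=float) <= 0]
            if len(bad):
                raise ValueError(f"non-positive {col} for subject {bad[0]!r}")
        bad = self.data.index[self.data["elapsed_years"].to_numpy(dtype=float) <= 0]
        if len(bad):
            raise ValueError(f"non-positive elapsed_years for subject {bad[0]!r}")

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


def compute_delta_glucose(clinical: ClinicalTable) -> pd.Series:
    """Annualised fasting-glucose change Δglucose, in mg/(dl·a).

    Δglucose_i = (glucose_followup_i − glucose_baseline_i) / elapsed_years_i.
    The positive-elapsed-time precondition is enforced by ``ClinicalTable``.
    """
    d = clinical.data
    delta = (d["glucose_followup"] - d["glucose_baseline"]) / d["elapsed_years"]
    return delta.astype(float).rename("delta_glucose")


def impute_lod(matrix: FeatureMatrix) -> FeatureMatrix:
    """Replace each below-LOD entry by 0.7 x the feature's minimum observed value.

    Missingness in GC-MS tables of this kind arises only from concentrations
    below the detection limit, so a small surrogate below every observed
    value is substituted: 0.7 times the per-feature minimum. Observed entries
    are unchanged; the operation is idempotent. A feature with no observed
    value at all has no defined minimum and is an error.
    """
    if matrix.stage == "imputed":
        return matrix
    if matrix.stage != "raw":
        raise ValueError(f"impute_lod expects a raw matrix, got stage {matrix.stage!r}")
    values = matrix.values.copy()
    arr = values.to_numpy(dtype=float)
    all_missing = np.isnan(arr).all(axis=0)
    if all_missing.any():
        feat = values.columns[int(np.argmax(all_missing))]
        raise ValueError(f"feature {feat!r} has no observed values; cannot impute LOD")
    fill = 0.7 * np.nanmin(arr, axis=0)
    mask = np.isnan(arr)
    arr[mask] = np.broadcast_to(fill, arr.shape)[mask]
    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return FeatureMatrix(out, stage="imputed", feature_names=matrix.feature_names)


def log_normalize(matrix: FeatureMatrix, mode: str = "feature_median") -> FeatureMatrix:
    """Natural-log transform followed by median centering.

    ``mode="feature_median"`` (default) centres each feature's log-intensity
    to zero median. ``mode="sample_then_feature"`` first removes each
    sample's median log-intensity (a per-sample loading correction) and then
    centres features. Both are strictly increasing per feature, so
    within-feature ranks — and hence any rank-based screen — are untouched.
    """
    if matrix.stage != "imputed":
        raise ValueError(f"log_normalize expects an imputed matrix, got stage {matrix.stage!r}")
    if mode not in ("feature_median", "sample_then_feature"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    arr = matrix.values.to_numpy(dtype=float)
    bad = arr <= 0
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"non-positive entry at subject {matrix.values.index[i]!r}, "
            f"feature {matrix.values.columns[j]!r}"
        )
    logged = np.log(arr)
    if mode == "sample_then_feature":
        logged = logged - np.median(logged, axis=1, keepdims=True)
    logged = logged - np.median(logged, axis=0, keepdims=True)
    out = pd.DataFrame(logged, index=matrix.values.index, columns=matrix.values.columns)
    return FeatureMatrix(out, stage="log_normalized", feature_names=matrix.feature_names)
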