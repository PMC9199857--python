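"""Invalid-value repair and global standardization.

Morphometric tables extracted by atlas registration carry two kinds of
invalid entries — empty cells and infinities — and per-atlas magnitudes that
differ by orders of magnitude (volumes above 10,000 next to thicknesses
below 10).  Repair replaces empties with 0 and infinities with the feature
column's finite mean; standardization then maps every entry through one
global z-transform, (x - mean) / std, with the mean and the *population*
standard deviation taken over all N x M entries of the (repaired, filtered)
matrix.

Both steps are exposed as scikit-learn transformers so they compose with
``sklearn.pipeline.Pipeline``; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import FeatureMatrix
from .registry import AtlasRegistry, filter_most_detailed


class DegenerateScaleError(ValueError):
    """All entries identical: the global standard deviation is zero."""


class InvalidValueRepairer(TransformerMixin, BaseEstimator):
    """Replace missing entries with 0 and infinite entries with column means.

    ``fit`` records, per feature column, the mean over the column's *finite*
    entries (before any replacement); ``transform`` substitutes that mean for
    infinities and 0 for NaNs.  A column with no finite entry at all gets
    replacement value 0 and a warning.

    Attributes
    ----------
    column_means_ : ndarray of shape (n_features,)
        Finite-entry mean per column; 0 for all-invalid columns.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        finite = np.isfinite(X)
        counts = finite.sum(axis=0)
        sums = np.where(finite, X, 0.0).sum(axis=0)
        dead = counts == 0
        if dead.any():
            warnings.warn(
                f"{int(dead.sum())} column(s) contain no finite entries; "
                "their infinities are replaced with 0",
                RuntimeWarning,
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(dead, 0.0, sums / np.maximum(counts, 1))
        self.column_means_ = means
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "column_means_")
        X = np.array(X, dtype=float, copy=True)
        X[np.isnan(X)] = 0.0
        inf = np.isinf(X)
        if inf.any():
            X[inf] = np.broadcast_to(self.column_means_, X.shape)[inf]
        return X


class GlobalStandardizer(TransformerMixin, BaseEstimator):
    """Z-transform with a single scalar mean and standard deviation.

    Unlike the usual per-feature scaler, the statistics are the grand mean
    and population standard deviation over *all* entries of the fit matrix;
    this rescales every atlas block onto one magnitude without destroying
    the between-feature structure within an atlas.  A per-feature mode is
    available via ``per_feature=True`` for experimentation.

    Parameters
    ----------
    per_feature : bool, default False
        Use per-column statistics instead of the global scalars.

    Attributes
    ----------
    mean_ : float or ndarray
    std_ : float or ndarray
        Population standard deviation(s); fitting raises
        :class:`DegenerateScaleError` when zero.
    """

    def __init__(self, per_feature: bool = False):
        self.per_feature = per_feature

    def fit(self, X, y=None):
        X = self._validate_finite(X)
        axis = 0 if self.per_feature else None
        mean = X.mean(axis=axis)
        std = X.std(axis=axis)  # population (ddof=0)
        if np.any(std == 0):
            raise DegenerateScaleError(
                "standard deviation is zero (all entries identical); "
                "cannot standardize"
            )
        self.mean_ = mean
        self.std_ = std
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = self._validate_finite(X)
        return (X - self.mean_) / self.std_

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        return np.asarray(X, dtype=float) * self.std_ + self.mean_

    @staticmethod
    def _validate_finite(X):
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError(
                "matrix contains non-finite entries; run invalid-value "
                "repair (InvalidValueRepairer / repair_invalid) first"
            )
        return X

    def stats(self) -> dict:
        check_is_fitted(self, "mean_")
        if self.per_feature:
            return {"mean": np.asarray(self.mean_).tolist(),
                    "std": np.asarray(self.std_).tolist()}
        return {"mean": float(self.mean_), "std": float(self.std_)}


def repair_invalid(matrix: FeatureMatrix) -> FeatureMatrix:
    """Return a copy of ``matrix`` with every entry finite."""
    repaired = InvalidValueRepairer().fit_transform(matrix.values)
    return replace(matrix, values=repaired)


def fit_standardizer(matrix: FeatureMatrix,
                     per_feature: bool = False) -> GlobalStandardizer:
    """Fit the global (or per-feature) standardization statistics."""
    return GlobalStandardizer(per_feature=per_feature).fit(matrix.values)


def standardize(matrix: FeatureMatrix,
                scaler: GlobalStandardizer) -> FeatureMatrix:
    """Apply previously fitted standardization statistics."""
    return replace(matrix, values=scaler.transform(matrix.values))


def preprocess_pipeline(
    matrix: FeatureMatrix,
    registry: AtlasRegistry,
    *,
    filter_atlases: bool = True,
    repair: bool = True,
    standardization: bool = True,
    per_feature: bool = False,
) -> tuple[FeatureMatrix, AtlasRegistry, Optional[GlobalStandardizer]]:
    """Full preprocessing chain: filter -> repair -> standardize.

    Each step is individually switchable (for ablation); the standardization
    statistics are always computed on the *filtered, repaired* matrix, so an
    out-of-span column can never influence them.  Returns the transformed
    matrix, the (possibly re-indexed) registry, and the fitted standardizer
    (``None`` when standardization is off).
    """
    if filter_atlases:
        registry = filter_most_detailed(registry)
        matrix, registry = matrix.select(registry)
    if repair:
        matrix = repair_invalid(matrix)
    scaler = None
    if standardization:
        scaler = fit_standardizer(matrix, per_feature=per_feature)
        matrix = standardize(matrix, scaler)
    return matrix, registry, scaler
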