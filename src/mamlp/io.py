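"""Feature-table container and the readers/writers shared by all stages.

Feature tables are CSV: header row of feature identifiers, first column the
sample ID, optional ``label`` column with values NC/MCI/AD.  Missing entries
are empty fields; infinities are the tokens ``inf`` / ``-inf``.  Stats,
manifests, metrics and truth records are JSON; configs are YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .registry import AtlasRegistry, column_indices, reindex

#: Fixed class order used everywhere (confusion matrices, ties, softmax heads).
CLASS_NAMES: tuple[str, str, str] = ("NC", "MCI", "AD")
CLASS_TO_INDEX = {c: i for i, c in enumerate(CLASS_NAMES)}


class ParseError(ValueError):
    """Feature-table file violates the CSV contract."""


@dataclass
class FeatureMatrix:
    """An N x M real-valued samples-by-features table.

    Attributes
    ----------
    values : ndarray of shape (n_samples, n_features)
        Feature values; may contain NaN (missing) and +/-inf before repair.
    sample_ids : list of str
    labels : ndarray of int or None
        Class codes NC=0, MCI=1, AD=2 when present.
    feature_names : list of str or None
    """

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    labels: Optional[np.ndarray] = None
    feature_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError(
                f"values must be a non-empty 2-D matrix, got shape "
                f"{self.values.shape}"
            )
        n = self.values.shape[0]
        if not self.sample_ids:
            self.sample_ids = [f"S{i:05d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_names(self) -> Optional[list[str]]:
        if self.labels is None:
            return None
        return [CLASS_NAMES[k] for k in self.labels]

    def select(self, registry: AtlasRegistry) -> tuple["FeatureMatrix", AtlasRegistry]:
        """Restrict columns to the registry's spans; re-index the registry.

        Returns the column-sliced matrix together with the registry whose
        spans are re-packed onto the new contiguous layout.  Sample order and
        labels are unchanged.
        """
        from .registry import LayoutError

        if registry.max_column > self.n_features:
            bad = max(registry, key=lambda v: v.span[1])
            raise LayoutError(
                f"atlas {bad.name!r} span {bad.span} exceeds matrix width "
                f"{self.n_features}"
            )
        cols = column_indices(registry)
        names = ([self.feature_names[c] for c in cols]
                 if self.feature_names else None)
        mat = replace(self, values=self.values[:, cols], feature_names=names)
        return mat, reindex(registry)


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read a feature-table CSV.

    Empty fields become NaN, ``inf``/``-inf`` tokens become infinities.
    Duplicate sample IDs, ragged rows and non-numeric cells are rejected.
    """
    try:
        df = pd.read_csv(path, dtype={0: str}, keep_default_na=False,
                         na_values=[""], float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a sample-ID column plus features")
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        dup = next(s for s in ids if ids.count(s) > 1)
        row = ids.index(dup) + 2  # 1-based, after header
        raise ParseError(f"{path}: duplicate sample ID {dup!r} (row {row})")
    df = df.iloc[:, 1:]
    labels = None
    if "label" in df.columns:
        raw = df.pop("label").tolist()
        if any(str(v).strip() for v in raw):
            try:
                labels = np.array([CLASS_TO_INDEX[str(v).strip()] for v in raw])
            except KeyError as exc:
                raise ParseError(
                    f"{path}: unknown label {exc.args[0]!r} "
                    f"(expected one of {CLASS_NAMES})"
                ) from None
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric cell in column {col!r}: {exc}")
    return FeatureMatrix(values=values, sample_ids=ids, labels=labels,
                         feature_names=list(df.columns))


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature-table CSV (inverse of :func:`read_feature_table`)."""
    names = matrix.feature_names or [f"f{j}" for j in range(matrix.n_features)]
    df = pd.DataFrame(matrix.values, columns=names)
    df.insert(0, "sample_id", matrix.sample_ids)
    if matrix.labels is not None:
        df["label"] = matrix.label_names()
    df.to_csv(path, index=False, na_rep="", float_format="%.17g")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def labels_from_names(names: Sequence[str]) -> np.ndarray:
    return np.array([CLASS_TO_INDEX[n] for n in names], dtype=int)
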