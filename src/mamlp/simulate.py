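"""Synthetic multi-atlas morphometry generator.

Emulates the statistical structure of a multi-atlas gray-matter
volume / cortical-thickness table for a three-class NC / MCI / AD cohort:

* class counts 781 / 1,148 / 671 (2,600 samples total);
* per-atlas magnitude heterogeneity — atlas blocks are scaled by
  multiplicative factors log-spaced across roughly 5 to 15,000, so block
  means span from below 10 to above 10,000;
* disease signal as ordered class-mean shifts: on a random ``affected``
  subset of each atlas's features, the class means move monotonically
  NC < MCI < AD (in a per-feature random direction) by ``effect_size``
  within-class standard deviations per stage, mimicking progressive
  atrophy;
* sporadic contamination — each cell is independently replaced by a missing
  marker (NaN) or a signed infinity at small configured rates, mimicking
  atlas-registration failures.

Feature noise is independent across features; real inter-ROI correlation
structure is deliberately not modelled (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import FeatureMatrix
from .registry import AtlasRegistry, default_registry

#: NC / MCI / AD cohort sizes of the emulated dataset.
DEFAULT_CLASS_COUNTS = (781, 1148, 671)


@dataclass
class SimConfig:
    """Generative parameters for the synthetic cohort.

    Parameters
    ----------
    class_counts : (int, int, int)
        Samples per class in NC, MCI, AD order.
    registry : AtlasRegistry or None
        Atlas layout to populate; ``None`` means the packaged 13-atlas
        (filtered) registry with 2 features per ROI.
    effect_size : float
        Class-mean shift per disease stage, in within-class SD units, on
        affected features.
    affected_fraction : float
        Fraction of each atlas's features carrying class signal.
    scale_range : (float, float)
        Low/high per-atlas multiplicative magnitude factors (log-spaced
        across atlases).
    nan_rate, inf_rate : float
        Per-cell probabilities of a missing / infinite marker.
    seed : int
    """

    class_counts: tuple[int, int, int] = DEFAULT_CLASS_COUNTS
    registry: Optional[AtlasRegistry] = None
    effect_size: float = 1.0
    affected_fraction: float = 0.2
    scale_range: tuple[float, float] = (5.0, 15000.0)
    nan_rate: float = 0.001
    inf_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be nonnegative")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if not 0.0 <= self.affected_fraction <= 1.0:
            raise ValueError("affected_fraction must lie in [0, 1]")
        if min(self.scale_range) <= 0:
            raise ValueError("scale factors must be positive")
        for name in ("nan_rate", "inf_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")

    def resolved_registry(self) -> AtlasRegistry:
        reg = self.registry if self.registry is not None else default_registry(filtered=True)
        if len(reg) == 0:
            raise ValueError("registry is empty; nothing to simulate")
        return reg


def generate_dataset(config: SimConfig) -> tuple[FeatureMatrix, dict]:
    """Draw a labelled synthetic cohort plus its ground-truth record.

    Per sample of class k, feature f of atlas a is
    ``scale_a * (base_f + shift_{k,f} + noise)`` with ``noise ~ N(0, 1)``,
    ``base_f`` log-normal (so volumes are positive and right-skewed), and
    ``shift_{k,f} = effect_size * level_k * sign_f`` on affected features
    (``level`` = 0/1/2 for NC/MCI/AD, ``sign_f`` a random direction), 0
    elsewhere.  Contamination is applied afterwards, independently per cell.

    Returns the feature matrix (with labels) and a truth record holding the
    per-atlas scales, affected feature indices and signs, and the exact
    contaminated cell positions.
    """
    reg = config.resolved_registry()
    rng = np.random.default_rng(config.seed)
    n = sum(config.class_counts)
    if n == 0:
        raise ValueError("no samples requested")
    m = reg.total_features
    if reg.max_column != m:
        raise ValueError("registry spans must be contiguous from 0; "
                         "re-index the registry before simulating")

    labels = np.repeat(np.arange(3), config.class_counts)
    labels = labels[rng.permutation(n)]
    levels = labels.astype(float)  # NC=0, MCI=1, AD=2 disease stage

    scales = np.geomspace(config.scale_range[0], config.scale_range[1],
                          num=len(reg))
    base = rng.lognormal(mean=0.0, sigma=0.5, size=m)

    col_scale = np.empty(m)
    signs = np.zeros(m)
    affected_truth = {}
    for a, version in enumerate(reg):
        start, end = version.span
        col_scale[start:end] = scales[a]
        width = end - start
        n_aff = int(round(config.affected_fraction * width))
        aff = rng.choice(width, size=n_aff, replace=False) + start
        aff.sort()
        signs[aff] = rng.choice([-1.0, 1.0], size=n_aff)
        affected_truth[version.name] = aff.tolist()

    shift_per_feature = config.effect_size * signs  # per disease stage
    values = base[None, :] + levels[:, None] * shift_per_feature[None, :]
    values = values + rng.standard_normal((n, m))
    values *= col_scale[None, :]

    u = rng.random((n, m))
    nan_mask = u < config.nan_rate
    inf_mask = (~nan_mask) & (u < config.nan_rate + config.inf_rate)
    inf_signs = rng.choice([-np.inf, np.inf], size=int(inf_mask.sum()))
    values[nan_mask] = np.nan
    values[inf_mask] = inf_signs

    matrix = FeatureMatrix(
        values=values,
        sample_ids=[f"S{i:05d}" for i in range(n)],
        labels=labels,
        feature_names=[f"f{j:05d}" for j in range(m)],
    )
    truth = {
        "seed": config.seed,
        "effect_size": config.effect_size,
        "class_counts": list(config.class_counts),
        "atlas_scales": {v.name: float(s) for v, s in zip(reg, scales)},
        "affected_features": affected_truth,
        "feature_signs": signs.tolist(),
        "nan_cells": np.argwhere(nan_mask).tolist(),
        "inf_cells": np.argwhere(inf_mask).tolist(),
    }
    return matrix, truth


def contamination_report(matrix: FeatureMatrix, truth: dict) -> dict:
    """Count missing / infinite cells and check them against the truth
    record's bookkeeping."""
    n_missing = int(np.isnan(matrix.values).sum())
    n_infinite = int(np.isinf(matrix.values).sum())
    rec_missing = len(truth["nan_cells"])
    rec_infinite = len(truth["inf_cells"])
    return {
        "n_missing": n_missing,
        "n_infinite": n_infinite,
        "matches_truth": (n_missing == rec_missing
                          and n_infinite == rec_infinite),
    }
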