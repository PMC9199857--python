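"""Multi-atlas feature layout: atlas versions, families, and filtering.

A brain *atlas* (template) parcellates the cortex and subcortex into regions
of interest (ROIs); morphometric features (gray-matter volume, mean cortical
thickness) are extracted per ROI, and the feature table concatenates the
per-atlas blocks column-wise.  Several *versions* of the same atlas family
(e.g. all Schaefer resolutions) carry largely redundant information, so the
pipeline keeps only the most detailed version of each family before any
modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence


class ManifestError(ValueError):
    """Malformed atlas manifest (missing or ill-typed field)."""


class LayoutError(ValueError):
    """Inconsistent feature-column layout (overlap or out-of-bounds span)."""


@dataclass(frozen=True)
class AtlasVersion:
    """One atlas version and the half-open column span it occupies.

    Parameters
    ----------
    name : str
        Unique version identifier, e.g. ``"AAL3v1"``.
    family : str
        Family key grouping versions of the same parcellation, e.g. ``"AAL"``.
    roi_count : int
        Number of regions of interest; the detail measure used for filtering.
    span : tuple of (int, int)
        Half-open ``[start, end)`` column interval in the feature matrix.
    """

    name: str
    family: str
    roi_count: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.name:
            raise ManifestError("atlas version needs a non-empty name")
        if not self.family:
            raise ManifestError(f"atlas {self.name!r}: empty family key")
        if not isinstance(self.roi_count, int) or self.roi_count < 1:
            raise ManifestError(
                f"atlas {self.name!r}: roi_count must be a positive integer, "
                f"got {self.roi_count!r}"
            )
        start, end = self.span
        if end <= start or start < 0:
            raise LayoutError(
                f"atlas {self.name!r}: span [{start}, {end}) is empty or negative"
            )

    @property
    def n_features(self) -> int:
        return self.span[1] - self.span[0]


@dataclass(frozen=True)
class AtlasRegistry:
    """Ordered catalogue of atlas versions with pairwise-disjoint spans."""

    versions: tuple[AtlasVersion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [v.name for v in self.versions]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ManifestError(f"duplicate atlas version name {dup!r}")
        spans = sorted(self.versions, key=lambda v: v.span[0])
        for a, b in zip(spans, spans[1:]):
            if b.span[0] < a.span[1]:
                raise LayoutError(
                    f"feature spans of {a.name!r} {a.span} and "
                    f"{b.name!r} {b.span} overlap"
                )

    def __len__(self) -> int:
        return len(self.versions)

    def __iter__(self):
        return iter(self.versions)

    @property
    def total_features(self) -> int:
        """Sum of span lengths over all versions."""
        return sum(v.n_features for v in self.versions)

    @property
    def families(self) -> list[str]:
        """Family keys in first-appearance order."""
        seen: dict[str, None] = {}
        for v in self.versions:
            seen.setdefault(v.family, None)
        return list(seen)

    @property
    def max_column(self) -> int:
        return max((v.span[1] for v in self.versions), default=0)

    def to_manifest(self) -> list[dict]:
        return [
            {"name": v.name, "family": v.family, "roi_count": v.roi_count,
             "span": list(v.span)}
            for v in self.versions
        ]


def load_registry(manifest: str | Path | Sequence[dict]) -> AtlasRegistry:
    """Load and validate an atlas registry.

    ``manifest`` is either a path to a JSON file or an already-parsed list of
    objects ``{"name", "family", "roi_count", "span": [start, end)}`` with
    0-based half-open column indices.
    """
    if isinstance(manifest, (str, Path)):
        with open(manifest) as fh:
            entries = json.load(fh)
    else:
        entries = list(manifest)
    if not isinstance(entries, list):
        raise ManifestError("manifest must be a list of atlas objects")
    versions = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise ManifestError(f"manifest entry {i} is not an object")
        missing = {"name", "family", "roi_count", "span"} - set(entry)
        if missing:
            raise ManifestError(
                f"manifest entry {i} missing field(s): {sorted(missing)}"
            )
        span = entry["span"]
        if (not isinstance(span, (list, tuple)) or len(span) != 2
                or not all(isinstance(s, int) for s in span)):
            raise ManifestError(
                f"manifest entry {i} ({entry['name']!r}): span must be a "
                f"two-integer [start, end) pair, got {span!r}"
            )
        versions.append(
            AtlasVersion(
                name=entry["name"],
                family=entry["family"],
                roi_count=entry["roi_count"],
                span=(span[0], span[1]),
            )
        )
    return AtlasRegistry(versions=tuple(versions))


def default_registry(filtered: bool = False) -> AtlasRegistry:
    """The packaged 30-version / 13-family registry.

    The packaged layout is synthetic: each version occupies ``2 * roi_count``
    consecutive columns (one volume and one thickness feature per ROI), laid
    out in catalogue order.  With ``filtered=True`` the most detailed version
    per family is kept (13 versions) and the spans are re-packed
    contiguously from column 0.
    """
    ref = resources.files("mamlp.data") / "atlas_manifest.json"
    reg = load_registry(json.loads(ref.read_text()))
    return reindex(filter_most_detailed(reg)) if filtered else reg


def filter_most_detailed(registry: AtlasRegistry) -> AtlasRegistry:
    """Keep one version per family: the one with maximal ``roi_count``.

    Ties break toward the first-listed version; relative order is preserved
    and spans are left unchanged (column selection happens separately in
    :func:`select_columns`).
    """
    best: dict[str, AtlasVersion] = {}
    for v in registry:
        cur = best.get(v.family)
        if cur is None or v.roi_count > cur.roi_count:
            best[v.family] = v
    keep = set(id(v) for v in best.values())
    return AtlasRegistry(
        versions=tuple(v for v in registry if id(v) in keep)
    )


def assign_depth(roi_count: int) -> int:
    """Number of linear layers for an atlas subnetwork.

    Atlases parcellated into more than 100 ROIs get a three-linear-layer
    network; coarser atlases get two.  Exactly 100 ROIs falls in the
    two-layer branch (strict inequality).
    """
    if not isinstance(roi_count, int) or roi_count < 1:
        raise ValueError(f"roi_count must be a positive integer, got {roi_count!r}")
    return 3 if roi_count > 100 else 2


def reindex(registry: AtlasRegistry) -> AtlasRegistry:
    """Re-pack spans contiguously from 0 in registry order."""
    versions, start = [], 0
    for v in registry:
        end = start + v.n_features
        versions.append(
            AtlasVersion(v.name, v.family, v.roi_count, (start, end))
        )
        start = end
    return AtlasRegistry(versions=tuple(versions))


def column_indices(registry: AtlasRegistry) -> list[int]:
    """Concatenated column indices of all spans in registry order."""
    idx: list[int] = []
    for v in registry:
        idx.extend(range(v.span[0], v.span[1]))
    return idx
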