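"""Occurrence-percentile thresholding, climate clipping, consensus summation,
conflict masking, and area accounting."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Raster

__all__ = [
    "BinaryMap",
    "ConsensusMap",
    "threshold_at_occurrences",
    "clip_to_climate",
    "consensus_sum",
    "mask_conflict",
    "area_by_class",
]


@dataclass
class BinaryMap:
    raster: Raster  # values in {0, 1} or NaN
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = self.raster.values
        ok = np.isnan(v) | (v == 0) | (v == 1)
        if not ok.all():
            raise ValueError("binary map must contain only 0, 1 and nodata")


@dataclass
class ConsensusMap:
    raster: Raster  # values in {0..n} or NaN
    inputs: list = field(default_factory=list)


def threshold_at_occurrences(
    surface: Raster, points: pd.DataFrame, retained_fraction: float, min_points: int = 10
) -> tuple[float, BinaryMap]:
    """Binary habitat map retaining at least ``retained_fraction`` of the
    occurrence values.

    The threshold is the type-1 (lower-interpolation) ``1 - retained_fraction``
    quantile of the surface values at the points, so the retention guarantee
    is exact.
    """
    if not 0.0 < retained_fraction <= 1.0:
        raise ValueError("retained_fraction must lie in (0, 1]")
    vals = surface.sample(points["lon"].to_numpy(float), points["lat"].to_numpy(float))
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("all occurrence points fall on nodata")
    if vals.size < min_points:
        raise ValueError(f"need at least {min_points} points on valid cells")
    thr = float(np.quantile(vals, 1.0 - retained_fraction, method="lower"))
    binary = np.where(surface.valid, (surface.values >= thr).astype(float), np.nan)
    return thr, BinaryMap(
        surface.with_values(binary),
        {"threshold": thr, "retained_fraction": retained_fraction, "n_points": int(vals.size)},
    )


def _require_aligned(a: Raster, b: Raster) -> None:
    if not a.grid.aligned_with(b.grid):
        raise ValueError("rasters are not aligned")


def clip_to_climate(habitat: BinaryMap, climate: BinaryMap) -> BinaryMap:
    """Cellwise AND of habitat and climate suitability."""
    _require_aligned(habitat.raster, climate.raster)
    h, c = habitat.raster.values, climate.raster.values
    out = np.where(np.isnan(h) | np.isnan(c), np.nan, ((h > 0) & (c > 0)).astype(float))
    prov = {"habitat": habitat.provenance, "climate_clip": climate.provenance}
    return BinaryMap(habitat.raster.with_values(out), prov)


def consensus_sum(binaries: list[BinaryMap], expected_n: int | None = 3) -> ConsensusMap:
    """Cellwise integer sum of binary habitat maps; nodata if any input is."""
    if expected_n is not None and len(binaries) != expected_n:
        raise ValueError(f"expected {expected_n} binary maps, got {len(binaries)}")
    if not binaries:
        raise ValueError("need at least one binary map")
    for b in binaries[1:]:
        _require_aligned(binaries[0].raster, b.raster)
    stack = np.stack([b.raster.values for b in binaries])
    invalid = np.isnan(stack).any(axis=0)
    total = np.where(invalid, np.nan, np.nansum(stack, axis=0))
    return ConsensusMap(
        binaries[0].raster.with_values(total), [b.provenance for b in binaries]
    )


def mask_conflict(consensus: ConsensusMap, conflict: BinaryMap) -> ConsensusMap:
    """Zero the consensus wherever the conflict mask is 1."""
    _require_aligned(consensus.raster, conflict.raster)
    v = consensus.raster.values
    out = np.where(np.nan_to_num(conflict.raster.values) > 0, 0.0, v)
    out = np.where(np.isnan(v), np.nan, out)
    return ConsensusMap(
        consensus.raster.with_values(out),
        consensus.inputs + [{"conflict_mask": conflict.provenance}],
    )


def area_by_class(consensus: ConsensusMap, cell_area_km2: float) -> pd.DataFrame:
    """Cell counts and area per consensus class; conserves total valid area."""
    if cell_area_km2 <= 0:
        raise ValueError("cell_area_km2 must be positive")
    v = consensus.raster.values
    valid = ~np.isnan(v)
    classes = np.unique(v[valid]).astype(int) if valid.any() else np.array([], dtype=int)
    rows = []
    for c in sorted(set(classes) | {0, 1, 2, 3} if valid.any() else []):
        n = int(np.sum(v[valid] == c))
        rows.append({"consensus_class": c, "cell_count": n, "area_km2": n * cell_area_km2})
    return pd.DataFrame(rows, columns=["consensus_class", "cell_count", "area_km2"])
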