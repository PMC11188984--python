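"""Expert-driven habitat suitability index.

S = road_curve(distance to major road) x slope_curve(slope)
    x (f_barren + f_desert + f_grass + f_shrub),
then cells dominated by urban/agriculture are zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import Raster, RasterStack

__all__ = ["ResponseCurve", "ExpertModel", "default_curves", "expert_suitability"]

SUM_CLASSES = ("barren", "desert", "grass", "shrub")
ZERO_CLASSES = ("urban", "agriculture")


@dataclass
class ResponseCurve:
    """Piecewise-linear suitability curve, clamped to its end values."""

    breakpoints: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if bp.size != v.size or bp.size < 2:
            raise ValueError("need matching breakpoints and values (>= 2)")
        if not np.all(np.diff(bp) > 0):
            raise ValueError("breakpoints must be strictly ascending")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("curve values must lie in [0, 1]")

    def __call__(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.breakpoints, self.values)

    def to_dict(self) -> dict:
        return {"breakpoints": list(self.breakpoints), "values": list(self.values)}

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseCurve":
        return cls(tuple(d["breakpoints"]), tuple(d["values"]))


@dataclass
class ExpertModel:
    road_curve: ResponseCurve
    slope_curve: ResponseCurve
    sum_classes: tuple[str, ...] = SUM_CLASSES
    zero_classes: tuple[str, ...] = ZERO_CLASSES
    zero_threshold: float = 0.5  # combined conflict fraction above which S = 0


def default_curves(config: dict | None = None) -> ExpertModel:
    """Packaged default curves; every piece overridable via ``config``.

    The numeric breakpoints are declared configuration values (flat terrain
    and road-distant cells maximal), not literature facts.
    """
    config = config or {}
    road = (
        ResponseCurve.from_dict(config["road_curve"])
        if "road_curve" in config
        else ResponseCurve((0.0, 1000.0), (0.0, 1.0))
    )
    slope = (
        ResponseCurve.from_dict(config["slope_curve"])
        if "slope_curve" in config
        else ResponseCurve((10.0, 30.0), (1.0, 0.0))
    )
    return ExpertModel(
        road,
        slope,
        tuple(config.get("sum_classes", SUM_CLASSES)),
        tuple(config.get("zero_classes", ZERO_CLASSES)),
        float(config.get("zero_threshold", 0.5)),
    )


def expert_suitability(stack: RasterStack, model: ExpertModel) -> Raster:
    """Apply the multiplicative index; conflict-dominated cells set to 0."""
    needed = ["dist_major_road", "slope"] + [
        f"frac_{c}" for c in model.sum_classes + model.zero_classes
    ]
    missing = [n for n in needed if n not in stack]
    if missing:
        raise KeyError(f"stack missing layers: {missing}")
    fr = [stack[f"frac_{c}"].values for c in model.sum_classes]
    fz = [stack[f"frac_{c}"].values for c in model.zero_classes]
    total = np.nansum([np.nan_to_num(a) for a in fr + fz], axis=0)
    if np.nanmax(total) > 1.0 + 1e-6:
        raise ValueError("cover fractions sum to more than 1")
    cover_sum = sum(fr)
    s = (
        model.road_curve(stack["dist_major_road"].values)
        * model.slope_curve(stack["slope"].values)
        * cover_sum
    )
    conflict = sum(fz)
    s = np.where(conflict > model.zero_threshold, 0.0, s)
    invalid = np.isnan(stack["dist_major_road"].values) | np.isnan(stack["slope"].values)
    invalid |= np.isnan(cover_sum)
    s = np.where(invalid, np.nan, s)
    return Raster(stack.grid, s)
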