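"""Occurrence filtering, seasonal splitting, thinning, background sampling,
and covariate extraction.

Occurrence sets are plain pandas DataFrames with columns
``lon, lat, year, month, precision_m, basis, subspecies, source``
(extra columns pass through untouched). Every filter logs in/out counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid, RasterStack

logger = logging.getLogger(__name__)

__all__ = [
    "filter_records",
    "split_seasons",
    "thin_to_cell",
    "sample_background",
    "extract_covariates",
    "assemble_niche_reduction",
    "SampleTable",
    "WINTER_MONTHS",
    "SUMMER_MONTHS",
]

WINTER_MONTHS = frozenset({11, 12, 1, 2})
SUMMER_MONTHS = frozenset({5, 6, 7, 8, 9})

OCC_COLUMNS = ["lon", "lat", "year", "month", "precision_m", "basis", "subspecies", "source"]


@dataclass
class SampleTable:
    """Labeled presence/background rows with extracted covariates."""

    data: pd.DataFrame  # point_id, label, lon, lat, month, <covariates...>
    covariate_names: list[str]
    n_dropped_nodata: int = 0
    source_tag: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.covariate_names if c not in self.data.columns]
        if missing:
            raise ValueError(f"covariate columns missing from table: {missing}")
        if self.data[self.covariate_names].isna().any().any():
            raise ValueError("SampleTable must not contain nodata covariates")

    @property
    def labels(self) -> np.ndarray:
        return (self.data["label"].to_numpy() == "presence").astype(int)

    @property
    def X(self) -> np.ndarray:
        return self.data[self.covariate_names].to_numpy(dtype=float)

    def presences(self) -> pd.DataFrame:
        return self.data[self.data["label"] == "presence"]

    def backgrounds(self) -> pd.DataFrame:
        return self.data[self.data["label"] == "background"]


def filter_records(
    occ: pd.DataFrame,
    min_year: int | None = None,
    max_year: int | None = None,
    max_precision_m: float | None = None,
    lon_max: float | None = None,
) -> pd.DataFrame:
    """Year / precision / basis / longitude-outlier filters.

    Records east of ``lon_max`` (lon > lon_max) are dropped, fossil records
    always, and records with missing precision whenever a precision cap is set.
    """
    if min_year is not None and max_year is not None and min_year > max_year:
        raise ValueError("min_year must be <= max_year")
    n_in = len(occ)
    keep = pd.Series(True, index=occ.index)
    if "basis" in occ.columns:
        keep &= occ["basis"] != "fossil"
    if min_year is not None:
        keep &= occ["year"] >= min_year
    if max_year is not None:
        keep &= occ["year"] <= max_year
    if max_precision_m is not None:
        prec = pd.to_numeric(occ.get("precision_m"), errors="coerce")
        keep &= prec.notna() & (prec <= max_precision_m)
    if lon_max is not None:
        keep &= occ["lon"] <= lon_max
    out = occ[keep].reset_index(drop=True)
    logger.info("filter_records: %d in, %d retained", n_in, len(out))
    return out


def split_seasons(occ: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Winter (Nov-Feb) / summer (May-Sep) split; Mar, Apr, Oct excluded."""
    month = pd.to_numeric(occ.get("month"), errors="coerce")
    n_missing = int(month.isna().sum())
    if n_missing:
        logger.warning("split_seasons: dropping %d records with missing month", n_missing)
    winter = occ[month.isin(WINTER_MONTHS)].reset_index(drop=True)
    summer = occ[month.isin(SUMMER_MONTHS)].reset_index(drop=True)
    logger.info(
        "split_seasons: %d winter, %d summer, %d excluded",
        len(winter),
        len(summer),
        len(occ) - len(winter) - len(summer),
    )
    return winter, summer


def thin_to_cell(occ: pd.DataFrame, template: Grid) -> pd.DataFrame:
    """At most one record per template cell; ties keep the lowest input index."""
    if occ.empty:
        return occ.copy()
    row, col = template.index_of(occ["lon"].to_numpy(), occ["lat"].to_numpy())
    cell = row.astype(np.int64) * template.n_cols + col
    first = pd.Series(np.arange(len(occ))).groupby(cell, sort=False).min().to_numpy()
    out = occ.iloc[np.sort(first)].reset_index(drop=True)
    logger.info("thin_to_cell: %d in, %d retained", len(occ), len(out))
    return out


def sample_background(
    presences: pd.DataFrame,
    template: Grid,
    seed,
    buffer_km: float = 25.0,
    n: int | None = None,
    valid: np.ndarray | None = None,
    months=None,
) -> pd.DataFrame:
    """Uniform points in the union of buffer disks around presences.

    Sampling is cell-based (uniform over eligible cells, jittered within the
    cell). ``months`` optionally gives the set of months to draw uniformly
    for month-matched extraction.
    """
    if presences.empty:
        raise ValueError("need at least one presence to buffer around")
    n = len(presences) if n is None else n
    rng = np.random.default_rng(seed)
    pres_mask = np.zeros(template.shape, dtype=bool)
    row, col = template.index_of(presences["lon"].to_numpy(), presences["lat"].to_numpy())
    ok = (row >= 0) & (row < template.n_rows) & (col >= 0) & (col < template.n_cols)
    pres_mask[row[ok], col[ok]] = True
    if not pres_mask.any():
        raise ValueError("no presences fall on the template grid")
    dist = ndimage.distance_transform_edt(~pres_mask, sampling=template.cell_size)
    eligible = dist <= buffer_km * 1000.0
    if valid is not None:
        eligible &= valid
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ValueError("buffer contains no valid cells")
    pick = rng.choice(idx, size=n)
    r, c = np.unravel_index(pick, template.shape)
    x, y = template.cell_center(r, c)
    jit = (rng.random((2, n)) - 0.5) * template.cell_size
    out = pd.DataFrame({"lon": x + jit[0], "lat": y + jit[1]})
    if months is not None:
        out["month"] = rng.choice(np.asarray(sorted(months)), n)
    return out


def _monthly_groups(names: list[str]) -> dict[str, dict[int, str]]:
    """Group layer names of the form var_MM by variable."""
    groups: dict[str, dict[int, str]] = {}
    for name in names:
        if "_" in name:
            var, _, suffix = name.rpartition("_")
            if suffix.isdigit() and 1 <= int(suffix) <= 12:
                groups.setdefault(var, {})[int(suffix)] = name
    return {v: m for v, m in groups.items() if len(m) == 12}


def extract_covariates(
    points: pd.DataFrame,
    stack: RasterStack,
    label: str = "presence",
    month_matched: bool = False,
    source_tag: str = "unknown",
) -> SampleTable:
    """Cell values of every layer at each point; month-matched layers read
    the layer of the row's own month. Rows hitting nodata are dropped."""
    grid = stack.grid
    lon = points["lon"].to_numpy(dtype=float)
    lat = points["lat"].to_numpy(dtype=float)
    inside = grid.contains(lon, lat)
    if not inside.all():
        raise ValueError(f"{(~inside).sum()} points fall outside the grid")
    groups = _monthly_groups(stack.names) if month_matched else {}
    monthly_members = {n for g in groups.values() for n in g.values()}
    static_names = [n for n in stack.names if n not in monthly_members]

    data = {
        "point_id": np.arange(len(points)),
        "label": label,
        "lon": lon,
        "lat": lat,
    }
    month = (
        pd.to_numeric(points["month"], errors="coerce").to_numpy()
        if "month" in points.columns
        else np.full(len(points), np.nan)
    )
    data["month"] = month
    cov_names: list[str] = []
    for name in static_names:
        data[name] = stack[name].sample(lon, lat)
        cov_names.append(name)
    if month_matched:
        if np.isnan(month).any():
            raise ValueError("month_matched extraction requires a month for every point")
        for var, by_month in sorted(groups.items()):
            vals = np.full(len(points), np.nan)
            for m, layer in by_month.items():
                sel = month == m
                if sel.any():
                    vals[sel] = stack[layer].sample(lon[sel], lat[sel])
            data[var] = vals
            cov_names.append(var)
    df = pd.DataFrame(data)
    good = df[cov_names].notna().all(axis=1)
    n_dropped = int((~good).sum())
    if n_dropped:
        logger.info("extract_covariates: dropped %d rows on nodata", n_dropped)
    return SampleTable(
        df[good].reset_index(drop=True), cov_names, n_dropped_nodata=n_dropped, source_tag=source_tag
    )


def assemble_niche_reduction(
    occ: pd.DataFrame,
    historical_max_year: int = 1950,
    supplement_tag: str = "arid_subspecies",
    n_supplement: int = 20,
    seed=0,
) -> pd.DataFrame:
    """Historical-era records plus a random supplement of tagged modern records."""
    hist = occ[occ["year"] <= historical_max_year]
    modern_tagged = occ[(occ["year"] > historical_max_year) & (occ["subspecies"] == supplement_tag)]
    rng = np.random.default_rng(seed)
    k = min(n_supplement, len(modern_tagged))
    supp = (
        modern_tagged.iloc[rng.choice(len(modern_tagged), size=k, replace=False)]
        if k
        else modern_tagged
    )
    out = pd.concat([hist, supp], ignore_index=True)
    logger.info(
        "assemble_niche_reduction: %d historical + %d supplemental records", len(hist), k
    )
    return out
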