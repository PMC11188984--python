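"""AUC and continuous Boyce index for suitability surfaces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Raster

__all__ = ["auc", "boyce", "cross_evaluate", "EvalReport"]


def auc(presence_scores, background_scores) -> float:
    """Probability a random presence outranks a random background point.

    Mann-Whitney formulation via midranks; ties count half.
    """
    pres = np.asarray(presence_scores, dtype=float)
    back = np.asarray(background_scores, dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("both score lists must be nonempty")
    ranks = stats.rankdata(np.concatenate([pres, back]))
    r1 = ranks[: pres.size].sum()
    u = r1 - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * back.size))


def boyce(
    surface: Raster,
    presence_points: pd.DataFrame,
    n_windows: int = 101,
    window_width: float = 0.1,
    rm_duplicates: bool = True,
    min_presences: int = 20,
) -> tuple[float, pd.DataFrame]:
    """Continuous Boyce index with overlapping moving windows.

    For each window, P = fraction of presences whose score falls inside and
    E = fraction of valid map cells inside; the index is the Spearman rank
    correlation between window midpoint and P/E over windows with E > 0.
    Successive duplicate P/E values are dropped before correlating (standard
    continuous-index behaviour). A constant surface returns (nan, empty).
    """
    vals = surface.values[surface.valid]
    scores = surface.sample(
        presence_points["lon"].to_numpy(float), presence_points["lat"].to_numpy(float)
    )
    scores = scores[~np.isnan(scores)]
    if scores.size < min_presences:
        raise ValueError(f"need at least {min_presences} presences on valid cells")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return float("nan"), pd.DataFrame(columns=["midpoint", "P", "E", "PE"])
    width = window_width * (hi - lo)
    mids = np.linspace(lo + width / 2, hi - width / 2, n_windows)
    rows = []
    for m in mids:
        a, b = m - width / 2, m + width / 2
        p = np.mean((scores >= a) & (scores <= b))
        e = np.mean((vals >= a) & (vals <= b))
        if e > 0:
            rows.append((m, p, e, p / e))
    table = pd.DataFrame(rows, columns=["midpoint", "P", "E", "PE"])
    pe = table["PE"].to_numpy()
    mid = table["midpoint"].to_numpy()
    if rm_duplicates and len(pe) > 1:
        keep = np.concatenate([[True], np.diff(pe) != 0])
        pe, mid = pe[keep], mid[keep]
    if len(pe) < 2 or np.all(pe == pe[0]):
        return float("nan"), table
    rho = stats.spearmanr(mid, pe).statistic
    return float(rho), table


@dataclass
class EvalReport:
    model_name: str
    dataset_name: str
    auc: float
    boyce: float
    n_presence: int
    n_background: int
    bin_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def cross_evaluate(
    models: dict[str, tuple[Raster, str]],
    datasets: dict[str, tuple[pd.DataFrame, str]],
    pairing: list[tuple[str, str]],
    background: pd.DataFrame | None = None,
    allow_self: bool = False,
    seed: int = 0,
) -> list[EvalReport]:
    """Evaluate suitability surfaces against points from independent sources.

    ``models`` maps name -> (surface, training source tag); ``datasets`` maps
    name -> (points, source tag). A pairing whose tags match is refused unless
    ``allow_self``. Background scores default to all valid surface cells
    (subsampled for AUC).
    """
    rng = np.random.default_rng(seed)
    reports = []
    for model_name, dataset_name in pairing:
        surface, train_tag = models[model_name]
        points, data_tag = datasets[dataset_name]
        if train_tag == data_tag and not allow_self:
            raise ValueError(
                f"refusing to evaluate {model_name!r} on its own training source "
                f"{data_tag!r} (pass allow_self to override)"
            )
        pres = surface.sample(points["lon"].to_numpy(float), points["lat"].to_numpy(float))
        pres = pres[~np.isnan(pres)]
        if background is not None:
            back = surface.sample(
                background["lon"].to_numpy(float), background["lat"].to_numpy(float)
            )
            back = back[~np.isnan(back)]
        else:
            vals = surface.values[surface.valid]
            back = vals if vals.size <= 10_000 else rng.choice(vals, 10_000, replace=False)
        b, table = boyce(surface, points)
        reports.append(
            EvalReport(
                model_name,
                dataset_name,
                auc=auc(pres, back),
                boyce=b,
                n_presence=int(pres.size),
                n_background=int(back.size),
                bin_table=table,
            )
        )
    return reports
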