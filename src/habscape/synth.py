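"""Synthetic landscapes, occurrences, movement tracks, and pseudo-future climate.

Every generator is a pure function of (config, seed) so downstream stages can
be tested against known ground truth: the suitability surface, the selection
coefficients that drove the simulated movement, and the additive climate
shifts behind each pseudo-GCM are all recorded in :class:`LandscapeTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import (
    Grid,
    Raster,
    RasterStack,
    class_fractions,
    distance_to_features,
    focal_density,
    slope_from_elevation,
    tpi,
)

__all__ = [
    "LandscapeTruth",
    "LandscapePack",
    "gaussian_random_field",
    "make_landscape",
    "landscape_covariates",
    "true_suitability",
    "sample_occurrences",
    "simulate_tracks",
    "make_future",
]

COVER_CLASSES = ("grass", "shrub", "barren", "desert", "agriculture", "urban")

MONTH_NAMES = [f"{m:02d}" for m in range(1, 13)]


@dataclass
class LandscapeTruth:
    """Ground-truth parameters behind one synthetic landscape.

    ``grf_params`` maps layer name to (mean, sill, range) with the
    correlation range expressed in *cells* so configs are grid-agnostic;
    :func:`make_landscape` converts to map units.
    """

    grf_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "tmin": (0.0, 4.0, 15.0),
            "tmax": (12.0, 4.0, 15.0),
            "precip": (400.0, 120.0**2, 20.0),
            "elevation": (500.0, 200.0**2, 25.0),
        }
    )
    cover_classes: tuple[str, ...] = COVER_CLASSES
    cover_prevalence: tuple[float, ...] = (0.30, 0.25, 0.15, 0.15, 0.10, 0.05)
    beta_true: dict[str, float] = field(
        default_factory=lambda: {"intercept": -1.0, "frac_grass": 2.0, "frac_shrub": 1.0}
    )
    movement_params: tuple[float, float, float] = (2.0, 150.0, 1.0)  # gamma shape, scale (m), kappa
    future_delta: dict[str, float] = field(
        default_factory=lambda: {"tmin": 2.5, "tmax": 3.0, "precip": -60.0}
    )
    gcm_noise_sd: float = 0.5
    seasonal_amplitude: float = 8.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name, (_, sill, rng) in self.grf_params.items():
            if sill < 0:
                raise ValueError(f"{name}: sill must be >= 0")
            if rng <= 0:
                raise ValueError(f"{name}: range must be > 0")
        shape, scale, kappa = self.movement_params
        if shape <= 0 or scale <= 0:
            raise ValueError("gamma shape and scale must be positive")
        if kappa < 0:
            raise ValueError("von Mises kappa must be >= 0")
        if len(self.cover_prevalence) != len(self.cover_classes):
            raise ValueError("one prevalence per cover class required")


@dataclass
class LandscapePack:
    monthly_climate: RasterStack  # tmin_MM, tmax_MM, precip
    elevation: Raster
    cover_class: Raster
    road_mask: Raster
    truth: LandscapeTruth

    @property
    def grid(self) -> Grid:
        return self.elevation.grid


def gaussian_random_field(grid: Grid, mean: float, sill: float, range_: float, seed) -> Raster:
    """Stationary GRF with exponential covariance via circulant embedding."""
    if range_ <= 0:
        raise ValueError("range must be positive")
    if sill < 0:
        raise ValueError("sill must be >= 0")
    if sill == 0:
        return Raster(grid, np.full(grid.shape, float(mean)))
    rng = np.random.default_rng(seed)
    nr, nc = grid.shape
    # embed on a doubled torus so the circulant covariance is (near) valid
    mr, mc = 2 * nr, 2 * nc
    ii = np.minimum(np.arange(mr), mr - np.arange(mr))
    jj = np.minimum(np.arange(mc), mc - np.arange(mc))
    h = np.hypot(ii[:, None], jj[None, :])  # lag in cells
    cov = sill * np.exp(-h * grid.cell_size / range_)
    lam = np.fft.fft2(cov).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative embedding eigenvalues
    noise = rng.standard_normal((mr, mc)) + 1j * rng.standard_normal((mr, mc))
    f = np.fft.fft2(noise * np.sqrt(lam / (mr * mc)))
    fld = f.real[:nr, :nc]
    return Raster(grid, mean + fld)


def _seasonal_cycle(month: int, amplitude: float) -> float:
    # month 7 warmest, month 1 coldest
    return amplitude * np.cos(2 * np.pi * (month - 7) / 12.0)


def make_landscape(truth: LandscapeTruth, grid: Grid) -> LandscapePack:
    """Deterministic landscape pack for a truth config and grid."""
    if grid.n_rows < 50 or grid.n_cols < 50:
        raise ValueError("grid must be at least 50x50 for track simulation")
    ss = np.random.SeedSequence(truth.master_seed)
    seeds = iter(ss.spawn(16))

    def grf(name):
        mean, sill, rng_ = truth.grf_params[name]
        return gaussian_random_field(grid, mean, sill, rng_ * grid.cell_size, next(seeds))

    tmin_base = grf("tmin")
    tmax_base = grf("tmax")
    precip = grf("precip")
    precip = precip.with_values(np.maximum(precip.values, 0.0))
    elevation = grf("elevation")

    climate = RasterStack()
    for m in range(1, 13):
        cyc = _seasonal_cycle(m, truth.seasonal_amplitude)
        climate.add(f"tmin_{m:02d}", tmin_base.with_values(tmin_base.values + cyc))
        climate.add(f"tmax_{m:02d}", tmax_base.with_values(tmax_base.values + cyc))
    climate.add("precip", precip)

    # categorical cover from quantile bins of a latent field: empirical class
    # fractions match configured prevalences exactly
    latent = gaussian_random_field(grid, 0.0, 1.0, 18.0 * grid.cell_size, next(seeds))
    ranks = latent.values.ravel().argsort().argsort() / latent.values.size
    cum = np.cumsum(truth.cover_prevalence)
    cover = np.digitize(ranks, cum[:-1]).reshape(grid.shape).astype(float)
    cover_class = Raster(grid, cover)

    # a connected west-east road: one smoothly wandering row per column
    road_rng = np.random.default_rng(ss.spawn(1)[0].entropy + 7)
    row = grid.n_rows // 2
    road = np.zeros(grid.shape)
    for c in range(grid.n_cols):
        road[row, c] = 1.0
        row = int(np.clip(row + road_rng.integers(-1, 2), 0, grid.n_rows - 1))
        road[row, c] = 1.0
    road_mask = Raster(grid, road)

    return LandscapePack(climate, elevation, cover_class, road_mask, truth)


def landscape_covariates(
    pack: LandscapePack,
    radius: float | None = None,
    include_terrain: bool = True,
) -> RasterStack:
    """Derived predictor stack (cover fractions, road metrics, terrain).

    ``radius`` controls the smoothing window for cover fractions and road
    density; defaults to 3 cells.
    """
    grid = pack.grid
    radius = radius if radius is not None else 3 * grid.cell_size
    stack = RasterStack()
    fracs = class_fractions(pack.cover_class, pack.truth.cover_classes)
    for name in fracs.names:
        sm = focal_density(fracs[name], radius)
        stack.add(name, sm)
    stack.add("dist_major_road", distance_to_features(pack.road_mask))
    stack.add("road_density", focal_density(pack.road_mask, radius))
    if include_terrain:
        stack.add("elevation", pack.elevation)
        stack.add("slope", slope_from_elevation(pack.elevation))
        stack.add("tpi", tpi(pack.elevation, radius))
    return stack


def true_suitability(pack: LandscapePack, covariates: RasterStack | None = None) -> Raster:
    """logistic(b0 + sum b_i x_i) over the truth's beta_true covariates."""
    cov = covariates if covariates is not None else landscape_covariates(pack)
    beta = dict(pack.truth.beta_true)
    eta = np.full(pack.grid.shape, beta.pop("intercept", 0.0))
    for name, b in beta.items():
        if name not in cov:
            raise KeyError(f"beta_true covariate {name!r} not in covariate stack")
        eta = eta + b * cov[name].values
    return Raster(pack.grid, 1.0 / (1.0 + np.exp(-eta)))


def sample_occurrences(
    suitability: Raster,
    n: int,
    seed,
    year_range: tuple[int, int] = (1980, 2023),
    month_probs=None,
    precision_choices=(10.0, 100.0, 250.0),
    basis: str = "observation",
    subspecies: str = "nominate",
    source: str = "survey",
) -> pd.DataFrame:
    """Presence records with cell probability proportional to suitability."""
    if n < 0:
        raise ValueError("n must be >= 0")
    cols = ["lon", "lat", "year", "month", "precision_m", "basis", "subspecies", "source"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    rng = np.random.default_rng(seed)
    w = np.where(suitability.valid, suitability.values, 0.0).ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample occurrences")
    idx = rng.choice(w.size, size=n, p=w / total)
    row, col = np.unravel_index(idx, suitability.grid.shape)
    x, y = suitability.grid.cell_center(row, col)
    jit = (rng.random((2, n)) - 0.5) * suitability.grid.cell_size
    months = np.arange(1, 13)
    p = None if month_probs is None else np.asarray(month_probs) / np.sum(month_probs)
    return pd.DataFrame(
        {
            "lon": x + jit[0],
            "lat": y + jit[1],
            "year": rng.integers(year_range[0], year_range[1] + 1, n),
            "month": rng.choice(months, n, p=p),
            "precision_m": rng.choice(precision_choices, n),
            "basis": basis,
            "subspecies": subspecies,
            "source": source,
        }
    )


def simulate_tracks(
    pack: LandscapePack,
    n_individuals: int,
    n_steps: int,
    rate_hours: float,
    seed,
    covariates: RasterStack | None = None,
    k_candidates: int = 50,
    start_time: str = "2020-01-01",
) -> pd.DataFrame:
    """Movement tracks from a known step-selection rule.

    Each step draws ``k_candidates`` displacements (gamma length, von Mises
    turn relative to the previous bearing) and selects one with probability
    proportional to exp(beta_true . x) at the candidate endpoint.
    """
    if n_individuals < 1 or n_steps < 1:
        raise ValueError("need at least one individual and one step")
    cov = covariates if covariates is not None else landscape_covariates(pack)
    beta = dict(pack.truth.beta_true)
    beta.pop("intercept", None)
    names = [n for n in beta if n in cov]
    bvec = np.array([beta[n] for n in names])
    layers = cov.as_array(names) if names else np.zeros((0,) + pack.grid.shape)

    shape, scale, kappa = pack.truth.movement_params
    grid = pack.grid
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp(start_time)
    frames = []
    for ind in range(n_individuals):
        # start somewhere comfortably interior
        r0 = rng.integers(grid.n_rows // 4, 3 * grid.n_rows // 4)
        c0 = rng.integers(grid.n_cols // 4, 3 * grid.n_cols // 4)
        x, y = grid.cell_center(r0, c0)
        bearing = rng.uniform(-np.pi, np.pi)
        xs, ys = [x], [y]
        for _ in range(n_steps):
            for _attempt in range(20):
                lengths = rng.gamma(shape, scale, k_candidates)
                turns = rng.vonmises(0.0, kappa, k_candidates) if kappa > 0 else rng.uniform(
                    -np.pi, np.pi, k_candidates
                )
                headings = bearing + turns
                cx = x + lengths * np.cos(headings)
                cy = y + lengths * np.sin(headings)
                rr, cc = grid.index_of(cx, cy)
                ok = (rr >= 0) & (rr < grid.n_rows) & (cc >= 0) & (cc < grid.n_cols)
                if ok.any():
                    break
            else:
                raise RuntimeError("no valid candidate endpoints after retries")
            eta = np.full(k_candidates, -np.inf)
            if names:
                vals = layers[:, rr[ok], cc[ok]]  # (p, n_ok)
                eta[ok] = bvec @ np.nan_to_num(vals)
            else:
                eta[ok] = 0.0
            w = np.exp(eta - eta[ok].max())
            w[~ok] = 0.0
            pick = rng.choice(k_candidates, p=w / w.sum())
            x, y, bearing = cx[pick], cy[pick], headings[pick]
            xs.append(x)
            ys.append(y)
        times = t0 + pd.to_timedelta(np.arange(n_steps + 1) * rate_hours, unit="h")
        frames.append(
            pd.DataFrame({"individual": f"ind{ind:03d}", "timestamp": times, "lon": xs, "lat": ys})
        )
    return pd.concat(frames, ignore_index=True)


def make_future(pack: LandscapePack, n_gcm: int, seed=None) -> list[RasterStack]:
    """Pseudo-future climate stacks: contemporary + delta + smooth per-GCM noise."""
    if n_gcm < 1:
        raise ValueError("need at least one pseudo-GCM")
    truth = pack.truth
    base_seed = truth.master_seed + 1_000_003 if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    gcm_seeds = ss.spawn(n_gcm)
    out = []
    grid = pack.grid
    for g in range(n_gcm):
        stack = RasterStack()
        sub = gcm_seeds[g].spawn(len(pack.monthly_climate.names))
        for i, name in enumerate(pack.monthly_climate.names):
            var = name.split("_")[0]
            delta = truth.future_delta.get(var, 0.0)
            base = pack.monthly_climate[name].values
            if truth.gcm_noise_sd > 0:
                noise = gaussian_random_field(
                    grid, 0.0, truth.gcm_noise_sd**2, 10 * grid.cell_size, sub[i]
                ).values
            else:
                noise = 0.0
            stack.add(name, Raster(grid, base + delta + noise))
        out.append(stack)
    return out
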