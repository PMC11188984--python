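"""End-to-end orchestration on synthetic landscapes.

Stages: simulate -> filter/split occurrences -> seasonal + niche-reduction
climate models (regularization sweep, AIC selection) -> future-ensemble
projection + MOP -> three habitat models (ensemble RSF, SSF, expert HSI) ->
occurrence-percentile thresholds -> climate clip -> 0-3 consensus ->
conflict masking -> area accounting -> cross-source evaluation.

Every stage writes its raster/table artifacts and a log line with the
parameters and seeds that produced it, so a rerun with the same config and
seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as cl
from . import consensus as cs
from . import evaluation as ev
from . import expert as ex
from . import occurrences as oc
from . import rsf
from . import ssf as ss
from . import synth
from .grids import Grid, Raster, write_geotiff
from .synth import LandscapeTruth

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int = 7
    n_rows: int = 100
    n_cols: int = 100
    cell_size: float = 500.0  # meters
    n_occurrences: int = 900
    n_individuals: int = 8
    n_steps: int = 150
    rate_hours: float = 4.0
    n_gcm: int = 3
    k_random: int = 15
    min_track_points: int = 100
    reg_grid: tuple[float, ...] = cl.DEFAULT_REG_GRID
    retained_hss: float = 0.85
    retained_lss: float = 0.95
    habitat_retained: float = 0.95
    buffer_km: float = 10.0
    beta_true: dict = field(
        default_factory=lambda: {"intercept": -1.0, "frac_grass": 2.0, "frac_shrub": 1.0}
    )
    expert_config: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.reg_grid, list):
            cfg.reg_grid = tuple(cfg.reg_grid)
        return cfg


def _save(raster: Raster, out: Path, name: str) -> None:
    write_geotiff(raster, out / f"{name}.tif")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic-data pipeline; returns the artifact manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("habscape")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    ss_seed = np.random.SeedSequence(config.seed)
    seeds = {
        name: s
        for name, s in zip(
            ["occ", "hist", "background", "tracks", "steps", "gcm", "mop", "eval"],
            ss_seed.spawn(8),
        )
    }
    logger.info("run_pipeline: config=%s", json.dumps(asdict(config), default=str))

    # --- stage: landscape -------------------------------------------------
    grid = Grid(config.n_rows, config.n_cols, config.cell_size)
    truth = LandscapeTruth(beta_true=dict(config.beta_true), master_seed=config.seed)
    pack = synth.make_landscape(truth, grid)
    cov = synth.landscape_covariates(pack)
    suit = synth.true_suitability(pack, cov)
    _save(suit, out, "true_suitability")
    logger.info("landscape: grid=%dx%d cell=%gm", grid.n_rows, grid.n_cols, grid.cell_size)

    full_stack = cov
    clim_stack = pack.monthly_climate

    # --- stage: occurrences ----------------------------------------------
    occ = synth.sample_occurrences(suit, config.n_occurrences, seeds["occ"])
    occ = oc.filter_records(occ, min_year=1980, max_precision_m=500.0)
    winter, summer = oc.split_seasons(occ)
    occ.to_csv(out / "occurrences.csv", index=False)

    # historical records from a broadened (flattened) suitability surface
    broad = suit.with_values(suit.values**0.3)
    hist = synth.sample_occurrences(
        broad, max(60, config.n_occurrences // 6), seeds["hist"],
        year_range=(1900, 1960), subspecies="arid_subspecies",
    )

    # --- stage: climate models -------------------------------------------
    valid = np.ones(grid.shape, dtype=bool)
    season_months = {"winter": oc.WINTER_MONTHS, "summer": oc.SUMMER_MONTHS}
    climate_models = {}
    climate_surfaces = {}
    for season, records in (("winter", winter), ("summer", summer)):
        bg = oc.sample_background(
            records, grid, seeds["background"], buffer_km=config.buffer_km,
            valid=valid, months=season_months[season],
        )
        pres_t = oc.extract_covariates(records, clim_stack, "presence", month_matched=True)
        back_t = oc.extract_covariates(bg, clim_stack, "background", month_matched=True)
        table = oc.SampleTable(
            pd.concat([pres_t.data, back_t.data], ignore_index=True),
            pres_t.covariate_names, source_tag="occurrence",
        )
        sweep = cl.sweep_regularization(table, config.reg_grid)
        climate_models[season] = sweep
        logger.info(
            "climate[%s]: selected reg=%g aic=%.2f",
            season,
            sweep.candidates[sweep.selected]["reg_multiplier"],
            sweep.candidates[sweep.selected]["aic"],
        )
        monthly_mean = _seasonal_mean_stack(clim_stack, season_months[season])
        surf = cl.predict_surface(sweep.model, monthly_mean)
        climate_surfaces[season] = surf
        _save(surf, out, f"climate_{season}")
        (out / f"climate_{season}_model.json").write_text(sweep.model.to_json())

    # niche-reduction model: historical + tagged supplement, annual predictors
    nr_records = oc.assemble_niche_reduction(
        pd.concat([occ, hist], ignore_index=True), seed=seeds["hist"].entropy % (2**32)
    )
    nr_bg = oc.sample_background(
        nr_records, grid, seeds["background"], buffer_km=config.buffer_km, valid=valid
    )
    annual = _annual_stack(clim_stack)
    nr_pres = oc.extract_covariates(nr_records, annual, "presence")
    nr_back = oc.extract_covariates(nr_bg, annual, "background")
    nr_table = oc.SampleTable(
        pd.concat([nr_pres.data, nr_back.data], ignore_index=True),
        nr_pres.covariate_names, source_tag="occurrence",
    )
    nr_sweep = cl.sweep_regularization(nr_table, config.reg_grid)
    nr_surface = cl.predict_surface(nr_sweep.model, annual)
    _save(nr_surface, out, "climate_niche_reduction")

    # --- stage: climate thresholds (HSS / LSS) ---------------------------
    clim_binaries = {}
    for name, surf, records in (
        ("winter", climate_surfaces["winter"], winter),
        ("summer", climate_surfaces["summer"], summer),
        ("niche_reduction", nr_surface, nr_records),
    ):
        for label, frac in (("hss", config.retained_hss), ("lss", config.retained_lss)):
            thr, bmap = cs.threshold_at_occurrences(surf, records, frac)
            clim_binaries[f"{name}_{label}"] = bmap
            _save(bmap.raster, out, f"climate_{name}_{label}")
            logger.info("threshold climate[%s %s]: %.4f", name, label, thr)

    # contemporary climate clip: niche-reduction LSS (the favoured hypothesis)
    contemporary_clip = clim_binaries["niche_reduction_lss"]

    # --- stage: future projection + MOP ----------------------------------
    futures = synth.make_future(pack, config.n_gcm, seed=seeds["gcm"].entropy % (2**32))
    future_annual = [_annual_stack(f) for f in futures]
    nr_thr = clim_binaries["niche_reduction_lss"].provenance["threshold"]
    future_mean, future_count = cl.project_gcms(nr_sweep.model, future_annual, nr_thr)
    _save(future_mean, out, "future_mean")
    _save(future_count, out, "future_binary_sum")
    future_clip = cs.BinaryMap(
        future_mean.with_values(
            np.where(np.isnan(future_mean.values), np.nan,
                     (future_mean.values >= nr_thr).astype(float))
        ),
        {"threshold": nr_thr, "source": "future_mean"},
    )
    mop_surface = cl.mop(
        nr_table, future_annual[0], nr_sweep.model.covariate_names,
        seed=seeds["mop"].entropy % (2**32),
    )
    _save(mop_surface.similarity, out, "mop_similarity")
    _save(mop_surface.extrapolation_mask, out, "mop_extrapolation")

    # --- stage: habitat models -------------------------------------------
    tracks = synth.simulate_tracks(
        pack, config.n_individuals, config.n_steps, config.rate_hours,
        seeds["tracks"], covariates=cov,
    )
    tracks.to_csv(out / "tracks.csv", index=False)

    # ensemble RSF on thinned track fixes (GPS source), reduced predictors
    fixes = tracks.rename(columns={})[["lon", "lat"]].copy()
    thinned = oc.thin_to_cell(fixes, grid)
    rsf_bg = oc.sample_background(
        thinned, grid, seeds["background"], buffer_km=config.buffer_km, valid=valid
    )
    reduced = [n for n in rsf.REDUCED_PREDICTORS if n in full_stack]
    rsf_pres = oc.extract_covariates(thinned, full_stack.subset(reduced), "presence")
    rsf_back = oc.extract_covariates(rsf_bg, full_stack.subset(reduced), "background")
    rsf_table = oc.SampleTable(
        pd.concat([rsf_pres.data, rsf_back.data], ignore_index=True),
        rsf_pres.covariate_names, source_tag="gps",
    )
    ens = rsf.fit_ensemble(rsf_table, seed=config.seed)
    ens_surface = rsf.predict_ensemble(ens, full_stack)
    _save(ens_surface, out, "habitat_ensemble")

    # SSF with K random steps and full predictors
    steps = ss.make_steps(
        tracks, min_points=config.min_track_points, rate_tolerance=0.10
    )
    dists = {
        ind: ss.fit_step_distributions(g["length"], g["turn_angle"])
        for ind, g in steps.data.groupby("individual")
    }
    stepset = ss.generate_random_steps(
        steps, dists, grid, k=config.k_random, seed=seeds["steps"].entropy % (2**32)
    )
    stepset = ss.attach_covariates(stepset, full_stack)
    fit = ss.fit_clogit(stepset)
    fit.summary().to_csv(out / "ssf_coefficients.csv", index=False)
    ssf_sfc = ss.ssf_surface(fit, full_stack)
    _save(ssf_sfc, out, "habitat_ssf")
    logger.info("ssf: %d strata, beta=%s", fit.n_strata, fit.beta.round(3).tolist())

    # expert HSI
    expert_model = ex.default_curves(config.expert_config)
    expert_sfc = ex.expert_suitability(full_stack, expert_model)
    _save(expert_sfc, out, "habitat_expert")

    # --- stage: thresholds, clip, consensus ------------------------------
    habitat_binaries = {}
    for name, surf in (
        ("ensemble", ens_surface), ("ssf", ssf_sfc), ("expert", expert_sfc)
    ):
        thr, bmap = cs.threshold_at_occurrences(surf, occ, config.habitat_retained)
        habitat_binaries[name] = bmap
        logger.info("threshold habitat[%s]: %.4f", name, thr)

    manifests = {}
    conflict_vals = (
        np.nan_to_num(full_stack["frac_urban"].values)
        + np.nan_to_num(full_stack["frac_agriculture"].values)
    )
    conflict = cs.BinaryMap(
        Raster(grid, (conflict_vals > expert_model.zero_threshold).astype(float)),
        {"source": "urban+agriculture fractions"},
    )
    for era, clip in (("contemporary", contemporary_clip), ("future", future_clip)):
        clipped = [cs.clip_to_climate(habitat_binaries[n], clip) for n in habitat_binaries]
        cons = cs.consensus_sum(clipped)
        cons = cs.mask_conflict(cons, conflict)
        _save(cons.raster, out, f"consensus_{era}")
        area = cs.area_by_class(cons, grid.cell_area / 1e6)
        area.to_csv(out / f"area_{era}.csv", index=False)
        manifests[era] = {
            "consensus": f"consensus_{era}.tif",
            "area": area.to_dict(orient="records"),
        }
        logger.info("consensus[%s]: classes=%s", era, area["cell_count"].tolist())

    # --- stage: evaluation -------------------------------------------------
    eval_bg = oc.sample_background(
        occ, grid, seeds["eval"], buffer_km=config.buffer_km, valid=valid
    )
    reports = ev.cross_evaluate(
        models={
            "ensemble": (ens_surface, "gps"),
            "ssf": (ssf_sfc, "gps"),
            "expert": (expert_sfc, "expert"),
        },
        datasets={"occurrences": (occ, "occurrence"), "gps_fixes": (fixes, "gps")},
        pairing=[("ensemble", "occurrences"), ("ssf", "occurrences"), ("expert", "gps_fixes")],
        background=eval_bg,
        seed=config.seed,
    )
    eval_df = pd.DataFrame(
        [
            {
                "model": r.model_name,
                "dataset": r.dataset_name,
                "auc": r.auc,
                "boyce": r.boyce,
                "n_presence": r.n_presence,
                "n_background": r.n_background,
            }
            for r in reports
        ]
    )
    eval_df.to_csv(out / "evaluation.csv", index=False)
    logger.info("evaluation:\n%s", eval_df.to_string(index=False))

    manifest = {
        "config": asdict(config),
        "eras": manifests,
        "evaluation": eval_df.to_dict(orient="records"),
        "ssf_beta": dict(zip(fit.covariate_names, fit.beta.tolist())),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _seasonal_mean_stack(clim_stack, months):
    """Per-variable mean over the season's monthly layers, plus statics."""
    from .grids import Raster, RasterStack
    from .occurrences import _monthly_groups

    groups = _monthly_groups(clim_stack.names)
    out = RasterStack()
    monthly_members = {n for g in groups.values() for n in g.values()}
    for var, by_month in sorted(groups.items()):
        arr = np.mean([clim_stack[by_month[m]].values for m in sorted(months)], axis=0)
        out.add(var, Raster(clim_stack.grid, arr))
    for name in clim_stack.names:
        if name not in monthly_members:
            out.add(name, clim_stack[name])
    return out


def _annual_stack(clim_stack):
    """Annual mean per monthly variable, plus static layers."""
    return _seasonal_mean_stack(clim_stack, range(1, 13))
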