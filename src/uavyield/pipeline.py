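"""File-based pipeline stages and the run manifest.

Each stage reads its inputs from disk and writes its outputs into the run
directory, so running the stages individually (calibrate → features →
lodging → model) is byte-identical to one monolithic :func:`run_pipeline`
call. A manifest records the config hash, seed, package versions, per-stage
metrics and the bookkeeping counters (nodata pixels, clamped CHM pixels,
zero-denominator index pixels).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import apply_calibration, calibration_report, fit_all_bands, read_tarp_csv
from .canopy import (
    DEFAULT_CIVE_INTERVAL,
    aggregate_plot_features,
    compute_canopy_mask,
    compute_cc,
    compute_chm,
    compute_cive,
    compute_vegetation_indices,
    plot_canopy_height,
)
from .errors import ConfigError, UavYieldError
from .geo import (
    MULTISPECTRAL_BANDS,
    RGB_BANDS,
    clip_elevation,
    clip_to_plot,
    read_elevation,
    read_plots,
    read_raster,
    write_raster,
)
from .lodging import LodgingClassRaster, summarize_plots
from .model import (
    ModelConfig,
    compare_feature_sets,
    residual_vs_lodging,
)
from .texture import glcm_feature_maps, quantize

VALID_STAGES = ("VT", "R3", "R5")


@dataclass
class RunConfig:
    """Validated paths and per-module settings for one pipeline run."""

    seed: int
    output_dir: Path
    stages: list[str]
    plots_path: Path
    lodging_path: Path
    tarp_csv: Path
    yield_csv: Path
    dem_path: Path
    stage_inputs: dict[str, dict[str, Path]]  # stage -> {multispectral, rgb, dsm}
    nodata: dict[str, float] = field(
        default_factory=lambda: {"multispectral": 0.0, "rgb": 0.0, "lodging": 255.0}
    )
    cive_interval: tuple[float, float] = DEFAULT_CIVE_INTERVAL
    osavi_canonical: bool = False
    ch_statistic: str = "mean"
    plot_shrink: float = 0.0
    glcm_window: int = 7
    glcm_levels: int = 64
    glcm_offset: tuple[int, int] = (1, 1)
    glcm_bands: tuple[str, ...] = ("G",)
    lodging_codes: tuple[float, float, float] = (0.0, 1.0, 2.0)
    lodging_legend: dict[int, str] = field(
        default_factory=lambda: {0: "NL", 1: "LL", 2: "SL"}
    )
    model: ModelConfig = field(default_factory=ModelConfig)
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text())
        return cls.from_dict(raw, base=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        base = Path(base) if base else Path(".")

        def _path(key, d=raw):
            if key not in d:
                raise ConfigError(f"config missing required path {key!r}")
            p = Path(d[key])
            return p if p.is_absolute() else base / p

        stages = list(raw.get("stages", list(VALID_STAGES)))
        bad = [s for s in stages if s not in VALID_STAGES]
        if bad:
            raise ConfigError(f"unknown stages {bad}; valid: {list(VALID_STAGES)}")
        stage_inputs = {}
        inputs = raw.get("inputs", {})
        for s in stages:
            if s not in inputs:
                raise ConfigError(f"config lacks inputs for stage {s!r}")
            stage_inputs[s] = {
                k: _path(k, inputs[s]) for k in ("multispectral", "rgb", "dsm")
            }
        feats = raw.get("features", {})
        glcm = feats.get("glcm", {})
        lodg = raw.get("lodging", {})
        mdl = raw.get("model", {})
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "out"))
            if Path(raw.get("output_dir", "out")).is_absolute()
            else base / raw.get("output_dir", "out"),
            stages=stages,
            plots_path=_path("plots"),
            lodging_path=_path("lodging_raster"),
            tarp_csv=_path("tarp_csv"),
            yield_csv=_path("yield_csv"),
            dem_path=_path("dem"),
            stage_inputs=stage_inputs,
            nodata={**{"multispectral": 0.0, "rgb": 0.0, "lodging": 255.0}, **raw.get("nodata", {})},
            cive_interval=tuple(feats.get("cive_interval", DEFAULT_CIVE_INTERVAL)),
            osavi_canonical=bool(feats.get("osavi_canonical", False)),
            ch_statistic=feats.get("ch_statistic", "mean"),
            plot_shrink=float(feats.get("plot_shrink", 0.0)),
            glcm_window=int(glcm.get("window", 7)),
            glcm_levels=int(glcm.get("levels", 64)),
            glcm_offset=tuple(glcm.get("offset", (1, 1))),
            glcm_bands=tuple(glcm.get("bands", ("G",))),
            lodging_codes=tuple(lodg.get("codes", (0.0, 1.0, 2.0))),
            lodging_legend={int(k): v for k, v in lodg.get("legend", {0: "NL", 1: "LL", 2: "SL"}).items()},
            model=ModelConfig(
                n_trees=int(mdl.get("n_trees", 100)),
                rng_seed=int(mdl.get("rng_seed", 15)),
                train_fraction=float(mdl.get("train_fraction", 0.8)),
            ),
            raw=raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = []
        for p in [self.plots_path, self.lodging_path, self.tarp_csv, self.yield_csv, self.dem_path]:
            if not Path(p).exists():
                missing.append(str(p))
        for s, d in self.stage_inputs.items():
            for k, p in d.items():
                if not Path(p).exists():
                    missing.append(f"{s}:{k}:{p}")
        if missing:
            raise ConfigError(f"referenced input paths do not exist: {missing}")

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_plots(cfg: RunConfig):
    plots = read_plots(cfg.plots_path)
    if cfg.plot_shrink > 0:
        plots = [p.shrunk(cfg.plot_shrink) for p in plots]
    return plots


# ---------------------------------------------------------------------------
# Stages


def stage_calibrate(cfg: RunConfig) -> dict:
    """Fit per-band tarp calibrations per stage and write reflectance rasters."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs = read_tarp_csv(cfg.tarp_csv)
    reports, counters = [], {}
    for stage in cfg.stages:
        models = fit_all_bands(pairs, MULTISPECTRAL_BANDS, date=stage)
        stack = read_raster(
            cfg.stage_inputs[stage]["multispectral"],
            MULTISPECTRAL_BANDS,
            nodata=cfg.nodata.get("multispectral"),
        )
        refl = apply_calibration(stack, models)
        write_raster(out / f"reflectance_{stage}.tif", refl, dtype=np.float64)
        rep = calibration_report(models.values())
        rep.insert(0, "stage", stage)
        reports.append(rep)
        counters[f"nodata_pixels_{stage}"] = int(np.sum(~stack.mask))
    pd.concat(reports, ignore_index=True).to_csv(out / "calibration.csv", index=False)
    return {"counters": counters}


def _plot_features(cfg: RunConfig, stage: str, plot, refl, rgb, chm, rgb_vrange):
    row: dict = {"plot_id": plot.plot_id}
    refl_clip = clip_to_plot(refl, plot)
    vis = compute_vegetation_indices(refl_clip, cfg.osavi_canonical)
    row.update(aggregate_plot_features(vis.maps, vis.valid_mask, plot.plot_id))
    zero_den = sum(vis.zero_denominator_counts.values())

    rgb_clip = clip_to_plot(rgb, plot)
    cive = compute_cive(rgb_clip)
    canopy = compute_canopy_mask(cive, cfg.cive_interval, rgb_clip.mask)
    row["CC"] = compute_cc(canopy, plot.plot_id)

    for band in cfg.glcm_bands:
        q = quantize(rgb_clip.bands[band], cfg.glcm_levels, rgb_clip.mask, rgb_vrange[band])
        maps = glcm_feature_maps(
            q, cfg.glcm_window, cfg.glcm_levels, cfg.glcm_offset, rgb_clip.mask
        )
        agg = aggregate_plot_features(maps, rgb_clip.mask, plot.plot_id)
        row.update({f"GLCM_{k}_{band}": v for k, v in agg.items()})

    chm_clip = clip_elevation(chm, plot)
    canopy_chm = compute_canopy_mask(cive, cfg.cive_interval, chm_clip.mask)
    row["CH"] = plot_canopy_height(chm_clip, canopy_chm, cfg.ch_statistic, plot.plot_id)
    return row, zero_den


def stage_features(cfg: RunConfig) -> dict:
    """Per-plot spectral, structural and texture features for every stage."""
    out = Path(cfg.output_dir)
    plots = _load_plots(cfg)
    dem = read_elevation(cfg.dem_path, "DEM", nodata=-9999.0)
    counters = {}
    for stage in cfg.stages:
        refl_path = out / f"reflectance_{stage}.tif"
        if not refl_path.exists():
            raise ConfigError(f"missing {refl_path}; run the calibrate stage first")
        refl = read_raster(refl_path, MULTISPECTRAL_BANDS, nodata=-9999.0, is_reflectance=True)
        rgb = read_raster(
            cfg.stage_inputs[stage]["rgb"], RGB_BANDS, nodata=cfg.nodata.get("rgb")
        )
        dsm = read_elevation(cfg.stage_inputs[stage]["dsm"], "DSM", nodata=-9999.0)
        chm = compute_chm(dsm, dem)
        counters[f"chm_clamped_{stage}"] = chm.n_clamped
        rgb_vrange = {
            b: (float(rgb.bands[b][rgb.mask].min()), float(rgb.bands[b][rgb.mask].max()))
            for b in cfg.glcm_bands
        }
        rows, zero_total = [], 0
        for plot in plots:
            row, zd = _plot_features(cfg, stage, plot, refl, rgb, chm, rgb_vrange)
            rows.append(row)
            zero_total += zd
        counters[f"vi_zero_denominator_{stage}"] = zero_total
        pd.DataFrame(rows).to_csv(out / f"features_{stage}.csv", index=False)
    return {"counters": counters}


def stage_lodging(cfg: RunConfig) -> dict:
    """Per-plot lodging fractions and lodging index."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = read_raster(cfg.lodging_path, ["class"], nodata=cfg.nodata.get("lodging"))
    raster = LodgingClassRaster(
        stack.bands["class"].astype(int),
        cfg.lodging_legend,
        stack.transform,
        stack.crs,
        stack.mask,
    )
    plots = _load_plots(cfg)
    table = summarize_plots(raster, plots, cfg.lodging_codes)
    table.to_csv(out / "lodging.csv", index=False)
    return {"n_plots": len(table)}


def stage_model(cfg: RunConfig) -> dict:
    """Train and evaluate with/without-LI yield models for every stage."""
    out = Path(cfg.output_dir)
    lodging_table = pd.read_csv(out / "lodging.csv", dtype={"plot_id": str})
    yields = pd.read_csv(cfg.yield_csv, dtype={"plot_id": str})
    metrics: dict = {}
    for stage in cfg.stages:
        feats = pd.read_csv(out / f"features_{stage}.csv", dtype={"plot_id": str})
        table = (
            feats.merge(lodging_table[["plot_id", "LI"]], on="plot_id")
            .merge(yields, on="plot_id")
            .dropna()
        )
        reports = compare_feature_sets(table, cfg.model)
        metrics[stage] = {}
        for fs, rep in reports.items():
            trend = residual_vs_lodging(rep, lodging_table)
            metrics[stage][fs] = {**rep.metrics_dict(), "residual_li_slope": trend.slope}
            tag = f"{stage}_{fs}"
            rep.predictions.to_csv(out / f"predictions_{tag}.csv", index=False)
            rep.importances.to_csv(out / f"importance_{tag}.csv", index=False)
            trend.table.to_csv(out / f"residual_li_{tag}.csv", index=False)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
    return {"metrics": metrics}


def run_pipeline(cfg: RunConfig) -> dict:
    """calibrate → features → lodging → model, with a manifest at the end."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "versions": {"uavyield": __version__, "numpy": np.__version__},
        "stages": cfg.stages,
        "counters": {},
        "timings_s": {},
    }
    stage_fns = [
        ("calibrate", stage_calibrate),
        ("features", stage_features),
        ("lodging", stage_lodging),
        ("model", stage_model),
    ]
    for name, fn in stage_fns:
        t0 = time.perf_counter()
        try:
            result = fn(cfg)
        except Exception as exc:
            (out / "FAILED").write_text(f"stage {name}: {exc}\n")
            raise UavYieldError(f"stage {name!r} failed: {exc}") from exc
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        manifest["counters"].update(result.get("counters", {}))
        if "metrics" in result:
            manifest["metrics"] = result["metrics"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
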