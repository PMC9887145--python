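"""Synthetic field scenario generator for end-to-end testing of the pipeline.

Emulates the field layout the pipeline consumes: a rectangular grid of 132
maize plots with a per-plot latent vigor in [0, 1], multispectral DN rasters
obtained by inverting known per-band DN→reflectance transfer functions, an
RGB raster whose green dominance tracks vigor (so CIVE canopy segmentation is
exercised), a DSM/DEM pair with canopy height proportional to vigor, a
pixel-level lodging-class raster built from patches hitting per-plot target
area fractions, tarp calibration pairs, and measured yields generated as

    yield = base + vigor_gain·vigor − lodging_penalty·LI + Normal(0, noise_sd)

truncated below at a positive floor. The defaults give 132 plots with yields
spanning roughly 1,300–13,800 kg/ha. Everything is driven by one seed through
named sub-streams so individual artifacts can be regenerated independently.

The module also provides small integer test images with brute-force GLCM
oracle values (:func:`glcm_reference` enumerates every co-occurring pixel
pair directly and evaluates the texture formulas on the resulting
probability table, independently of the windowed implementation).
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import evaluate_family
from .errors import ConfigError
from .geo import (
    Affine,
    BandStack,
    ElevationRaster,
    MULTISPECTRAL_BANDS,
    PlotGeometry,
    RGB_BANDS,
    write_elevation,
    write_plots,
    write_raster,
)
from .lodging import LodgingClassRaster, lodging_index

from shapely.geometry import box

TARP_COLORS = ("gray", "red", "white", "green", "blue", "black")
TARP_REFLECTANCES = (0.24, 0.40, 0.75, 0.30, 0.12, 0.04)
STAGES = ("VT", "R3", "R5")

# canopy reflectance laws: intercept + slope·vigor, and flat soil background
_CANOPY_REFL = {
    "blue": (0.04, 0.01),
    "green": (0.08, 0.05),
    "red": (0.28, -0.22),
    "rededge": (0.15, 0.18),
    "nir": (0.22, 0.38),
}
_SOIL_REFL = {"blue": 0.10, "green": 0.16, "red": 0.22, "rededge": 0.26, "nir": 0.30}


def default_calibration_truth() -> dict[str, tuple[str, tuple[float, ...]]]:
    """One transfer-function family per band, exercising all five families."""
    return {
        "blue": ("exponential", (0.005, 1.0e-4)),
        "green": ("quadratic", (1.5e-10, 8.0e-6, 0.0)),
        "red": ("linear", (1.6e-5, 0.004)),
        "rededge": ("logarithmic", (0.25, -1.8)),
        "nir": ("power", (6.0e-4, 0.7)),
    }


def invert_calibration(family: str, coeffs, reflectance):
    """DN such that the family maps it back to the given reflectance."""
    r = np.asarray(reflectance, dtype=float)
    if family == "linear":
        a, b = coeffs
        return (r - b) / a
    if family == "quadratic":
        a, b, c = coeffs
        disc = b * b - 4 * a * (c - r)
        return (-b + np.sqrt(disc)) / (2 * a)
    if family == "exponential":
        a, b = coeffs
        return np.log(r / a) / b
    if family == "logarithmic":
        a, b = coeffs
        return np.exp((r - b) / a)
    if family == "power":
        a, b = coeffs
        return np.power(r / a, 1.0 / b)
    raise ConfigError(f"unknown family {family!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of the synthetic field experiment."""

    n_plots: int = 132
    grid_cols: int = 12
    plot_shape: tuple[int, int] = (8, 25)  # rows × cols of pixels per plot
    gap: int = 3  # soil pixels between plots
    resolution: float = 0.4  # m per pixel (plot ≈ 3.2 m × 10 m)
    origin: tuple[float, float] = (500000.0, 3900000.0)
    crs: str = "EPSG:32650"
    vigor_range: tuple[float, float] = (0.2, 1.0)
    lodged_fraction: float = 0.6  # fraction of plots with any lodging
    stage_scale: tuple[float, ...] = (0.85, 0.95, 1.0)  # vigor scaling per VT/R3/R5
    reflectance_noise_sd: float = 0.004
    rgb_noise_sd: float = 2.0  # DN
    elevation_noise_sd: float = 0.0  # m
    tarp_noise_frac: float = 0.0  # multiplicative noise on tarp DN
    base_yield: float = 2000.0  # kg/ha
    vigor_gain: float = 11000.0  # kg/ha per unit vigor
    lodging_penalty: float = 1500.0  # kg/ha per LI unit
    yield_noise_sd: float = 500.0  # kg/ha
    yield_floor: float = 500.0  # kg/ha
    lodging_codes: tuple[float, float, float] = (0.0, 1.0, 2.0)

    def __post_init__(self):
        pr, pc = self.plot_shape
        if pr < 2 or pc < 2:
            raise ConfigError("plot grid too small for lodging patches")
        if self.n_plots < 1:
            raise ConfigError("need at least one plot")


@dataclass
class StageRasters:
    multispectral: BandStack  # DN-valued
    rgb: BandStack
    dsm: ElevationRaster


@dataclass
class Scenario:
    config: ScenarioConfig
    seed: int
    plots: list[PlotGeometry]
    truth: pd.DataFrame
    stage_rasters: dict[str, StageRasters]
    dem: ElevationRaster
    lodging_raster: LodgingClassRaster
    tarp_pairs: pd.DataFrame
    yield_table: pd.DataFrame


def _rng(seed: int, stream: str) -> np.random.Generator:
    # stable stream key (zlib.crc32 is process-independent, unlike hash())
    key = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def canopy_height_truth(cfg: ScenarioConfig, vigor, stage: str = "R5"):
    scale = dict(zip(STAGES, cfg.stage_scale))[stage]
    return (0.4 + 2.4 * np.asarray(vigor)) * scale


def canopy_cover_target(vigor):
    return np.clip(0.45 + 0.5 * np.asarray(vigor), 0.0, 0.95)


def _plot_layout(cfg: ScenarioConfig):
    """Pixel windows and polygons of the plot grid."""
    pr, pc = cfg.plot_shape
    rows = math.ceil(cfg.n_plots / cfg.grid_cols)
    canvas = (
        cfg.gap + rows * (pr + cfg.gap),
        cfg.gap + cfg.grid_cols * (pc + cfg.gap),
    )
    x0, y0 = cfg.origin
    res = cfg.resolution
    transform = Affine(res, 0.0, x0, 0.0, -res, y0)
    windows, plots = [], []
    for k in range(cfg.n_plots):
        gr, gc = divmod(k, cfg.grid_cols)
        r0 = cfg.gap + gr * (pr + cfg.gap)
        c0 = cfg.gap + gc * (pc + cfg.gap)
        windows.append((r0, r0 + pr, c0, c0 + pc))
        poly = box(
            x0 + c0 * res,
            y0 - (r0 + pr) * res,
            x0 + (c0 + pc) * res,
            y0 - r0 * res,
        )
        group = "variety" if k < cfg.n_plots - 34 else "nitrogen"
        plots.append(PlotGeometry(f"P{k + 1:03d}", poly, group, cfg.crs))
    return canvas, transform, windows, plots


def _lodging_fields(cfg: ScenarioConfig, seed: int, windows):
    """Per-plot class patches grown from random seed pixels to target fractions."""
    rng = _rng(seed, "lodging")
    pr, pc = cfg.plot_shape
    npx = pr * pc
    frac_rows, patches = [], []
    for _ in windows:
        if rng.random() < cfg.lodged_fraction:
            s_sl = float(rng.beta(1.2, 3.0))
            s_ll = float((1.0 - s_sl) * rng.beta(1.5, 3.0))
        else:
            s_sl = s_ll = 0.0
        n_sl = int(round(s_sl * npx))
        n_ll = min(int(round(s_ll * npx)), npx - n_sl)
        classes = np.zeros((pr, pc), dtype=np.uint8)  # NL
        rr, cc = np.meshgrid(np.arange(pr), np.arange(pc), indexing="ij")
        if n_sl:
            sr, sc = rng.integers(0, pr), rng.integers(0, pc)
            d = np.maximum(np.abs(rr - sr), np.abs(cc - sc)).ravel().astype(float)
            d += rng.random(npx) * 0.5  # jitter breaks ties into irregular blobs
            classes.ravel()[np.argsort(d)[:n_sl]] = 2
        if n_ll:
            free = np.flatnonzero(classes.ravel() == 0)
            sr, sc = rng.integers(0, pr), rng.integers(0, pc)
            d = (np.maximum(np.abs(rr - sr), np.abs(cc - sc)).ravel().astype(float))[free]
            d += rng.random(free.size) * 0.5
            classes.ravel()[free[np.argsort(d)[:n_ll]]] = 1
        counts = np.bincount(classes.ravel(), minlength=3)
        frac_rows.append(tuple(counts / npx))
        patches.append(classes)
    return frac_rows, patches


def generate_scenario(cfg: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    """Build the full synthetic field: rasters, plots, tarps, lodging, yields."""
    cfg = cfg or ScenarioConfig()
    canvas, transform, windows, plots = _plot_layout(cfg)
    pr, pc = cfg.plot_shape
    truth_cal = default_calibration_truth()

    vigor = _rng(seed, "vigor").uniform(*cfg.vigor_range, size=cfg.n_plots)
    cc_target = canopy_cover_target(vigor)
    canopy_rng = _rng(seed, "canopy")
    canopy_masks = [canopy_rng.random((pr, pc)) < cc for cc in cc_target]
    cc_real = np.array([m.mean() for m in canopy_masks])

    fracs, patches = _lodging_fields(cfg, seed, windows)
    li = np.array([lodging_index(f, cfg.lodging_codes) for f in fracs])

    # lodging raster (background = 255 nodata)
    lodg = np.full(canvas, 255, dtype=np.uint8)
    for (r0, r1, c0, c1), classes in zip(windows, patches):
        lodg[r0:r1, c0:c1] = classes
    lodging_raster = LodgingClassRaster(
        lodg, {0: "NL", 1: "LL", 2: "SL"}, transform, cfg.crs, lodg != 255
    )

    # elevation: gentle bare-earth plane shared by all stages
    rows_ix, cols_ix = np.indices(canvas)
    dem_vals = 75.0 + 0.004 * cols_ix * cfg.resolution + 0.002 * rows_ix * cfg.resolution
    if cfg.elevation_noise_sd:
        dem_vals = dem_vals + _rng(seed, "dem").normal(0, cfg.elevation_noise_sd, canvas)
    dem = ElevationRaster(dem_vals, "DEM", transform, cfg.crs, -9999.0)

    stage_rasters: dict[str, StageRasters] = {}
    scales = dict(zip(STAGES, cfg.stage_scale))
    for stage in STAGES:
        sc = scales[stage]
        ms_rng = _rng(seed, f"ms-{stage}")
        rgb_rng = _rng(seed, f"rgb-{stage}")

        refl = {b: np.full(canvas, _SOIL_REFL[b]) for b in MULTISPECTRAL_BANDS}
        rgb = {
            "R": np.full(canvas, 150.0),
            "G": np.full(canvas, 128.0),
            "B": np.full(canvas, 108.0),
        }
        hgt = np.zeros(canvas)
        for (r0, r1, c0, c1), v, cmask in zip(windows, vigor, canopy_masks):
            v_eff = v * sc
            for b in MULTISPECTRAL_BANDS:
                a0, a1 = _CANOPY_REFL[b]
                block = refl[b][r0:r1, c0:c1]
                block[cmask] = a0 + a1 * v_eff
            rgb["R"][r0:r1, c0:c1][cmask] = 100.0
            rgb["G"][r0:r1, c0:c1][cmask] = 132.0 + 8.0 * v_eff
            rgb["B"][r0:r1, c0:c1][cmask] = 78.0
            hgt[r0:r1, c0:c1][cmask] = (0.4 + 2.4 * v) * sc

        dn_bands = {}
        for b in MULTISPECTRAL_BANDS:
            vals = refl[b]
            if cfg.reflectance_noise_sd:
                vals = vals + ms_rng.normal(0, cfg.reflectance_noise_sd, canvas)
            vals = np.clip(vals, 0.01, 0.93)
            family, coeffs = truth_cal[b]
            dn_bands[b] = np.round(invert_calibration(family, coeffs, vals))
        if cfg.rgb_noise_sd:
            for b in RGB_BANDS:
                rgb[b] = rgb[b] + rgb_rng.normal(0, cfg.rgb_noise_sd, canvas)
        rgb = {b: np.clip(np.round(v), 1, 255) for b, v in rgb.items()}

        dsm = ElevationRaster(dem_vals + hgt, "DSM", transform, cfg.crs, -9999.0)
        stage_rasters[stage] = StageRasters(
            BandStack(dn_bands, transform, cfg.crs, nodata=0.0),
            BandStack(rgb, transform, cfg.crs, nodata=0.0),
            dsm,
        )

    # tarp calibration pairs per stage and band, DN from the inverse truth law
    tarp_rng = _rng(seed, "tarps")
    tarp_rows = []
    for stage in STAGES:
        for b in MULTISPECTRAL_BANDS:
            family, coeffs = truth_cal[b]
            for tarp, refl_val in zip(TARP_COLORS, TARP_REFLECTANCES):
                dn = float(invert_calibration(family, coeffs, refl_val))
                if cfg.tarp_noise_frac:
                    dn *= 1.0 + tarp_rng.normal(0, cfg.tarp_noise_frac)
                tarp_rows.append(
                    {
                        "tarp_id": tarp,
                        "band": b,
                        "date": stage,
                        "dn": dn,
                        "reflectance": refl_val,
                    }
                )
    tarp_pairs = pd.DataFrame(tarp_rows)

    yields = (
        cfg.base_yield
        + cfg.vigor_gain * vigor
        - cfg.lodging_penalty * li
        + _rng(seed, "yield").normal(0, cfg.yield_noise_sd, cfg.n_plots)
    )
    yields = np.maximum(yields, cfg.yield_floor)

    truth = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "vigor": vigor,
            "cc_target": cc_target,
            "cc_true": cc_real,
            "ch_true": canopy_height_truth(cfg, vigor, "R5"),
            "S_NL": [f[0] for f in fracs],
            "S_LL": [f[1] for f in fracs],
            "S_SL": [f[2] for f in fracs],
            "LI": li,
            "yield_kg_ha": yields,
        }
    )
    yield_table = truth[["plot_id", "yield_kg_ha"]].copy()
    return Scenario(
        cfg, seed, plots, truth, stage_rasters, dem, lodging_raster, tarp_pairs, yield_table
    )


def write_scenario(scenario: Scenario, outdir) -> dict[str, str]:
    """Emit the scenario in the formats the pipeline consumes; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = scenario.config
    paths: dict[str, str] = {}

    def _p(name):
        paths[name] = str(outdir / name)
        return outdir / name

    write_plots(_p("plots.geojson"), scenario.plots, cfg.crs)
    lr = scenario.lodging_raster
    lodg_stack = BandStack(
        {"class": lr.values.astype(float)}, lr.transform, lr.crs, nodata=255.0, mask=lr.mask
    )
    write_raster(_p("lodging.tif"), lodg_stack, dtype=np.uint8)
    write_elevation(_p("dem.tif"), scenario.dem, dtype=np.float64)
    scenario.tarp_pairs.to_csv(_p("tarps.csv"), index=False)
    scenario.yield_table.to_csv(_p("yield.csv"), index=False)
    scenario.truth.to_csv(_p("truth.csv"), index=False)
    for stage, sr in scenario.stage_rasters.items():
        write_raster(_p(f"multispectral_{stage}.tif"), sr.multispectral, dtype=np.uint16)
        write_raster(_p(f"rgb_{stage}.tif"), sr.rgb, dtype=np.uint8)
        write_elevation(_p(f"dsm_{stage}.tif"), sr.dsm, dtype=np.float64)
    (outdir / "scenario.json").write_text(
        json.dumps(
            {"seed": scenario.seed, "config": dataclasses.asdict(cfg)},
            indent=1,
            default=list,
        )
    )
    paths["scenario.json"] = str(outdir / "scenario.json")
    return paths


def make_feature_table(
    cfg: ScenarioConfig | None = None, seed: int = 0, stage: str = "R5"
) -> pd.DataFrame:
    """Fast per-plot feature table drawn from the same generative laws.

    Band means are the canopy/soil reflectance mixture of each plot (plus the
    plot-mean sampling noise); spectral indices are evaluated on those means.
    Used where many model replicates are needed without rendering rasters.
    """
    from .canopy import VEGETATION_INDICES

    cfg = cfg or ScenarioConfig()
    scale = dict(zip(STAGES, cfg.stage_scale))[stage]
    n = cfg.n_plots
    npx = cfg.plot_shape[0] * cfg.plot_shape[1]

    vigor = _rng(seed, "vigor").uniform(*cfg.vigor_range, size=n)
    cc_target = canopy_cover_target(vigor)
    canopy_rng = _rng(seed, "canopy")
    cc_real = np.array(
        [(canopy_rng.random(cfg.plot_shape) < cc).mean() for cc in cc_target]
    )
    fracs, _ = _lodging_fields(cfg, seed, [None] * n)
    li = np.array([lodging_index(f, cfg.lodging_codes) for f in fracs])

    ms_rng = _rng(seed, f"ms-{stage}")
    v_eff = vigor * scale
    bands = {}
    for b in MULTISPECTRAL_BANDS:
        a0, a1 = _CANOPY_REFL[b]
        mean_refl = cc_real * (a0 + a1 * v_eff) + (1.0 - cc_real) * _SOIL_REFL[b]
        if cfg.reflectance_noise_sd:
            mean_refl = mean_refl + ms_rng.normal(
                0, cfg.reflectance_noise_sd / np.sqrt(npx), n
            )
        bands[b] = mean_refl
    args = tuple(bands[b] for b in ("blue", "green", "red", "rededge", "nir"))
    table = {"plot_id": [f"P{k + 1:03d}" for k in range(n)]}
    for name, func in VEGETATION_INDICES.items():
        table[name] = np.asarray(func(*args), dtype=float)
    table["CC"] = cc_real
    table["CH"] = canopy_height_truth(cfg, vigor, stage)
    table["LI"] = li
    yields = (
        cfg.base_yield
        + cfg.vigor_gain * vigor
        - cfg.lodging_penalty * li
        + _rng(seed, "yield").normal(0, cfg.yield_noise_sd, n)
    )
    table["yield_kg_ha"] = np.maximum(yields, cfg.yield_floor)
    return pd.DataFrame(table)


# ---------------------------------------------------------------------------
# GLCM oracle and test images


def glcm_reference(
    img: np.ndarray,
    levels: int,
    offset: tuple[int, int],
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """Brute-force GLCM statistics by direct pair enumeration (test oracle).

    Walks every pixel, counts the symmetric co-occurrences at the offset in a
    plain dictionary, and evaluates the texture formulas on the resulting
    probabilities. Deliberately independent of the windowed implementation.
    """
    img = np.asarray(img)
    R, C = img.shape
    dr, dc = offset
    counts: dict[tuple[int, int], int] = {}
    for r in range(R):
        for c in range(C):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < R and 0 <= c2 < C):
                continue
            if mask is not None and not (mask[r, c] and mask[r2, c2]):
                continue
            a, b = int(img[r, c]), int(img[r2, c2])
            counts[(a, b)] = counts.get((a, b), 0) + 1
            counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ConfigError("no co-occurring pairs at this offset")
    probs = {ij: v / total for ij, v in counts.items()}
    mu_i = sum(i * p for (i, _), p in probs.items())
    mu_j = sum(j * p for (_, j), p in probs.items())
    var_i = sum(p * (i - mu_i) ** 2 for (i, _), p in probs.items())
    var_j = sum(p * (j - mu_j) ** 2 for (_, j), p in probs.items())
    if var_i < 1e-12 or var_j < 1e-12:
        cor = 1.0
    else:
        cor = sum(
            p * (i - mu_i) * (j - mu_j) for (i, j), p in probs.items()
        ) / math.sqrt(var_i * var_j)
    return {
        "MEAN": mu_i,
        "VAR": var_i,
        "HOM": sum(p / (1 + (i - j) ** 2) for (i, j), p in probs.items()),
        "CON": sum(p * (i - j) ** 2 for (i, j), p in probs.items()),
        "DIS": sum(p * abs(i - j) for (i, j), p in probs.items()),
        "ENT": sum(-p * math.log(p) for p in probs.values()),
        "ASM": sum(p * p for p in probs.values()),
        "COR": cor,
    }


def generate_glcm_test_images(seed: int = 0, n_random: int = 10) -> list[dict]:
    """Constant, checkerboard, gradient and random images with oracle values."""
    rng = np.random.default_rng(seed)
    cases = []

    def add(name, image, levels, offset):
        cases.append(
            {
                "name": name,
                "image": image,
                "levels": levels,
                "offset": offset,
                "expected": glcm_reference(image, levels, offset),
            }
        )

    add("constant", np.full((6, 6), 3, dtype=int), 8, (0, 1))
    cb = np.indices((4, 4)).sum(axis=0) % 2
    add("checkerboard", cb, 2, (0, 1))
    add("gradient", np.tile(np.arange(8) % 8, (8, 1)), 8, (1, 0))
    offsets = [(0, 1), (1, 0), (1, 1)]
    for k in range(n_random):
        levels = int(rng.choice([2, 4, 8]))
        size = int(rng.integers(5, 13))
        img = rng.integers(0, levels, size=(size, size))
        add(f"random-{k}", img, levels, offsets[k % 3])
    return cases
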