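"""Canopy spectral indices and structural features (coverage and height).

Spectral vegetation indices are computed from calibrated multispectral
reflectance (bands blue, green, red, rededge, nir). Canopy coverage uses the
colour index of vegetation extraction (CIVE) on RGB digital numbers to
separate maize canopy from soil; canopy height comes from a crop height model
(CHM = DSM − DEM) averaged over canopy pixels.

The index registry holds the thirteen published formulas; additional indices
can be registered at run time via :func:`register_index`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import FeatureError, PlotClipError
from .geo import BandStack, ElevationRaster, MULTISPECTRAL_BANDS

OSAVI_L = 0.16
WDRVI_A = 0.12
DEFAULT_CIVE_INTERVAL = (-28.0, 5.0)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = den != 0
    np.divide(num, den, out=out, where=ok)
    return out


# Each entry maps reflectance bands (B, G, R, RE, NIR) to a per-pixel index.
VEGETATION_INDICES: dict[str, Callable] = {
    "NDVI": lambda B, G, R, RE, NIR: _safe_div(NIR - R, NIR + R),
    "RVI": lambda B, G, R, RE, NIR: _safe_div(NIR, R),
    "GRVI": lambda B, G, R, RE, NIR: _safe_div(G - R, G + R),
    # denominator exactly as published: NIR − R + L
    "OSAVI": lambda B, G, R, RE, NIR: _safe_div(NIR - R, NIR - R + OSAVI_L),
    "NDRE": lambda B, G, R, RE, NIR: _safe_div(NIR - RE, NIR + RE),
    "MCARI": lambda B, G, R, RE, NIR: ((RE - R) - 0.2 * (RE - G)) * _safe_div(RE, R),
    # RE/R multiplies only the second term, as published
    "TCARI": lambda B, G, R, RE, NIR: 3.0
    * ((RE - R) - 0.2 * (RE - G) * _safe_div(RE, R)),
    "GNDVI": lambda B, G, R, RE, NIR: _safe_div(NIR - G, NIR + G),
    "WDRVI": lambda B, G, R, RE, NIR: _safe_div(WDRVI_A * NIR - R, WDRVI_A * NIR + R),
    "GCI": lambda B, G, R, RE, NIR: _safe_div(NIR, G) - 1.0,
    "RECI": lambda B, G, R, RE, NIR: _safe_div(NIR, RE) - 1.0,
    "EVI2": lambda B, G, R, RE, NIR: 2.5 * _safe_div(NIR - R, NIR + 2.4 * R + 1.0),
    "NDREI": lambda B, G, R, RE, NIR: _safe_div(RE - G, RE + G),
}

OSAVI_CANONICAL = lambda B, G, R, RE, NIR: _safe_div(NIR - R, NIR + R + OSAVI_L)


def register_index(name: str, func: Callable) -> None:
    """Register an extra index computed as func(B, G, R, RE, NIR)."""
    VEGETATION_INDICES[name] = func


@dataclass
class VegetationIndexSet:
    """Per-pixel index maps plus bookkeeping of zero-denominator pixels."""

    maps: dict[str, np.ndarray]
    valid_mask: np.ndarray
    zero_denominator_counts: dict[str, int] = field(default_factory=dict)

    def plot_means(self) -> dict[str, float]:
        out = {}
        for name, vals in self.maps.items():
            sel = vals[self.valid_mask]
            sel = sel[np.isfinite(sel)]
            out[name] = float(np.mean(sel)) if sel.size else np.nan
        return out


def compute_vegetation_indices(
    stack: BandStack, osavi_canonical: bool = False
) -> VegetationIndexSet:
    """All registered indices, per pixel; zero-denominator pixels become NaN."""
    if not stack.is_reflectance:
        raise FeatureError("vegetation indices need a reflectance-valued stack (calibrate first)")
    missing = [b for b in MULTISPECTRAL_BANDS if b not in stack.bands]
    if missing:
        raise FeatureError(f"missing multispectral bands: {missing}")
    args = tuple(stack.bands[b] for b in ("blue", "green", "red", "rededge", "nir"))
    registry = dict(VEGETATION_INDICES)
    if osavi_canonical:
        registry["OSAVI"] = OSAVI_CANONICAL
    maps, counts = {}, {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, func in registry.items():
            vals = np.asarray(func(*args), dtype=np.float64)
            counts[name] = int(np.sum(~np.isfinite(vals) & stack.mask))
            maps[name] = vals
    return VegetationIndexSet(maps, stack.mask, counts)


# ---------------------------------------------------------------------------
# Canopy / soil segmentation and coverage


def compute_cive(rgb: BandStack | Mapping[str, np.ndarray]) -> np.ndarray:
    """CIVE = 0.441·R − 0.811·G + 0.385·B + 18.787 per pixel (RGB digital numbers)."""
    bands = rgb.bands if isinstance(rgb, BandStack) else rgb
    try:
        R, G, B = bands["R"], bands["G"], bands["B"]
    except KeyError as exc:
        raise FeatureError(f"missing RGB band {exc} for CIVE") from None
    return (
        0.441 * np.asarray(R, float)
        - 0.811 * np.asarray(G, float)
        + 0.385 * np.asarray(B, float)
        + 18.787
    )


@dataclass
class CanopyMask:
    """Boolean canopy map derived from CIVE thresholding (bounds inclusive)."""

    mask: np.ndarray
    cive: np.ndarray
    interval: tuple[float, float]
    valid_mask: np.ndarray


def compute_canopy_mask(
    cive: np.ndarray,
    interval: tuple[float, float] = DEFAULT_CIVE_INTERVAL,
    valid_mask: np.ndarray | None = None,
) -> CanopyMask:
    lo, hi = interval
    if lo > hi:
        raise FeatureError(f"CIVE interval lower bound {lo} exceeds upper bound {hi}")
    if valid_mask is None:
        valid_mask = np.ones(cive.shape, dtype=bool)
    mask = (cive >= lo) & (cive <= hi) & valid_mask
    return CanopyMask(mask, cive, (lo, hi), valid_mask)


def compute_cc(canopy: CanopyMask, plot_id: str = "?") -> float:
    """Canopy coverage: fraction of valid plot pixels classified as canopy."""
    total = int(np.sum(canopy.valid_mask))
    if total == 0:
        raise PlotClipError(plot_id, "no valid pixels for canopy coverage")
    return float(np.sum(canopy.mask)) / total


# ---------------------------------------------------------------------------
# Canopy height


def compute_chm(dsm: ElevationRaster, dem: ElevationRaster) -> ElevationRaster:
    """Crop height model = DSM − DEM, negatives clamped to zero.

    The clamp count (surface-reconstruction noise) is stored on the result as
    ``chm.n_clamped``.
    """
    if dsm.kind != "DSM" or dem.kind != "DEM":
        raise FeatureError(f"expected DSM and DEM, got {dsm.kind} and {dem.kind}")
    if dsm.shape != dem.shape or dsm.transform != dem.transform:
        raise FeatureError("DSM and DEM grids are not co-registered")
    values = dsm.values - dem.values
    mask = dsm.mask & dem.mask
    n_clamped = int(np.sum((values < 0) & mask))
    values = np.where(values < 0, 0.0, values)
    chm = ElevationRaster(values, "CHM", dsm.transform, dsm.crs, dsm.nodata, mask)
    chm.n_clamped = n_clamped
    return chm


def plot_canopy_height(
    chm: ElevationRaster,
    canopy: CanopyMask | None = None,
    statistic: str = "mean",
    plot_id: str = "?",
) -> float:
    """Aggregate CHM over canopy pixels (default mean; 'p95' or 'all_mean').

    With no canopy pixels the all-pixel mean is returned with a warning so a
    bare plot still yields a defined height.
    """
    valid = chm.mask
    sel = valid if canopy is None or statistic == "all_mean" else (canopy.mask & valid)
    if not np.any(sel):
        warnings.warn(
            f"plot {plot_id!r}: no canopy pixels, falling back to all-pixel mean CHM",
            stacklevel=2,
        )
        sel = valid
    if not np.any(sel):
        raise PlotClipError(plot_id, "no valid CHM pixels")
    vals = chm.values[sel]
    if statistic == "p95":
        return float(np.percentile(vals, 95))
    return float(np.mean(vals))


def aggregate_plot_features(
    maps: Mapping[str, np.ndarray], valid_mask: np.ndarray, plot_id: str = "?"
) -> dict[str, float]:
    """Mean of each per-pixel map over valid, finite plot pixels."""
    if not np.any(valid_mask):
        raise PlotClipError(plot_id, "no valid pixels to aggregate")
    out = {}
    for name, vals in maps.items():
        sel = vals[valid_mask]
        sel = sel[np.isfinite(sel)]
        if sel.size == 0:
            raise PlotClipError(plot_id, f"feature {name!r} has no finite pixels")
        out[name] = float(np.mean(sel))
    return out
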