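"""Plot-level lodging severity from a pixel-level lodging-class raster.

Pixels are classed as NL (no lodging: plant within ~30° of vertical), LL
(light lodging: 30–60°) or SL (severe: plant near or on the ground). The
lodging index of a plot is the class-code-weighted sum of per-class area
fractions, LI = Σ LDᵢ·Sᵢ, so with the default codes (NL=0, LL=1, SL=2) a
fully upright plot scores 0 and a fully flattened plot scores 2. The class
raster itself is an input (produced by an upstream classifier or by the
synthetic generator); area fractions are pixel-count fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import LodgingError
from .geo import Affine, PlotGeometry, _plot_window

CLASS_NAMES = ("NL", "LL", "SL")
DEFAULT_CODES = (0.0, 1.0, 2.0)
DEFAULT_LEGEND = {0: "NL", 1: "LL", 2: "SL"}
_FRACTION_TOL = 1e-9


@dataclass
class LodgingClassRaster:
    """Categorical raster of lodging classes with an integer→class legend."""

    values: np.ndarray
    legend: Mapping[int, str] = None
    transform: Affine = None
    crs: str | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.legend is None:
            self.legend = dict(DEFAULT_LEGEND)
        unknown = set(self.legend.values()) - set(CLASS_NAMES)
        if unknown:
            raise LodgingError(f"legend maps to unknown classes: {sorted(unknown)}")
        if self.mask is None:
            self.mask = np.isin(self.values, list(self.legend))


@dataclass(frozen=True)
class LodgingSummary:
    plot_id: str
    s_nl: float
    s_ll: float
    s_sl: float
    li: float

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.s_nl, self.s_ll, self.s_sl)


def lodging_fractions(
    values: np.ndarray,
    legend: Mapping[int, str] | None = None,
    valid_mask: np.ndarray | None = None,
    plot_id: str = "?",
) -> tuple[float, float, float]:
    """Per-class pixel-count fractions (S_NL, S_LL, S_SL) over valid pixels."""
    legend = dict(DEFAULT_LEGEND) if legend is None else dict(legend)
    values = np.asarray(values)
    if valid_mask is None:
        valid_mask = np.isin(values, list(legend))
    sel = values[valid_mask]
    total = sel.size
    if total == 0:
        raise LodgingError(f"plot {plot_id!r}: no valid lodging pixels")
    counts = {name: 0 for name in CLASS_NAMES}
    for code, name in legend.items():
        counts[name] += int(np.sum(sel == code))
    if sum(counts.values()) != total:
        raise LodgingError(f"plot {plot_id!r}: pixels with codes outside the legend")
    return tuple(counts[name] / total for name in CLASS_NAMES)


def lodging_index(
    fractions: Sequence[float], codes: Sequence[float] = DEFAULT_CODES
) -> float:
    """LI = Σ LDᵢ·Sᵢ for strictly increasing class codes LD."""
    s = np.asarray(fractions, dtype=float)
    ld = np.asarray(codes, dtype=float)
    if s.shape != (3,) or ld.shape != (3,):
        raise LodgingError("expected three fractions and three class codes")
    if abs(float(s.sum()) - 1.0) > 1e-6:
        raise LodgingError(f"fractions sum to {s.sum():.9f}, not 1")
    if not (ld[0] < ld[1] < ld[2]):
        raise LodgingError(f"class codes must be strictly increasing, got {tuple(ld)}")
    return float(np.dot(ld, s))


def summarize_plot(
    raster: LodgingClassRaster,
    plot: PlotGeometry,
    codes: Sequence[float] = DEFAULT_CODES,
) -> LodgingSummary:
    (r0, r1, c0, c1), inside = _plot_window(raster.transform, raster.values.shape, plot)
    vals = raster.values[r0:r1, c0:c1]
    valid = raster.mask[r0:r1, c0:c1] & inside
    s = lodging_fractions(vals, raster.legend, valid, plot.plot_id)
    return LodgingSummary(plot.plot_id, *s, lodging_index(s, codes))


def summarize_plots(
    raster: LodgingClassRaster,
    plots: Iterable[PlotGeometry],
    codes: Sequence[float] = DEFAULT_CODES,
) -> pd.DataFrame:
    summaries = [summarize_plot(raster, p, codes) for p in plots]
    return lodging_map_report(summaries)


def lodging_map_report(summaries: Iterable[LodgingSummary]) -> pd.DataFrame:
    """Per-plot table sorted by plot_id: S_NL, S_LL, S_SL, LI."""
    rows = [
        {
            "plot_id": s.plot_id,
            "S_NL": s.s_nl,
            "S_LL": s.s_ll,
            "S_SL": s.s_sl,
            "LI": s.li,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows, columns=["plot_id", "S_NL", "S_LL", "S_SL", "LI"])
    return df.sort_values("plot_id", kind="stable").reset_index(drop=True)


def lodging_choropleth(
    raster: LodgingClassRaster,
    plots: Sequence[PlotGeometry],
    summaries: pd.DataFrame,
    fill: float = np.nan,
) -> np.ndarray:
    """Paint each plot's LI over its footprint, for map-style visualisation."""
    out = np.full(raster.values.shape, fill)
    li = dict(zip(summaries["plot_id"], summaries["LI"]))
    for plot in plots:
        (r0, r1, c0, c1), inside = _plot_window(
            raster.transform, raster.values.shape, plot
        )
        block = out[r0:r1, c0:c1]
        block[inside] = li[plot.plot_id]
    return out
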