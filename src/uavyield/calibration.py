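"""Empirical-line radiometric calibration: per-band DN → reflectance.

Reference tarpaulins of known reflectance (measured in the field with a
spectroradiometer) provide (DN, reflectance) pairs per band. Five candidate
function families are fitted per band and the best by r² is kept:

    linear       r = a·DN + b
    quadratic    r = a·DN² + b·DN + c
    exponential  r = a·exp(b·DN)
    logarithmic  r = a·ln(DN) + b
    power        r = a·DN^b

Ties in r² break toward the family with fewer parameters, then toward the
fixed order above (so an exactly linear relation is reported as linear even
though the quadratic fits it equally well). Calibrations are per band and per
acquisition date; no coefficients are shared across dates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import CalibrationError
from .geo import BandStack

FAMILIES = ("linear", "quadratic", "exponential", "logarithmic", "power")
N_PARAMS = {"linear": 2, "quadratic": 3, "exponential": 2, "logarithmic": 2, "power": 2}
_R2_TIE_TOL = 1e-9


@dataclass(frozen=True)
class CalibrationPair:
    """One tarp observation: mean image DN vs field-measured reflectance."""

    tarp_id: str
    band: str
    dn: float
    reflectance: float
    date: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.reflectance <= 1.0:
            raise CalibrationError(
                f"tarp {self.tarp_id!r} band {self.band!r}: reflectance "
                f"{self.reflectance} outside [0, 1]"
            )
        if self.dn < 0:
            raise CalibrationError(f"tarp {self.tarp_id!r}: negative DN {self.dn}")


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted per-band transfer function with its goodness of fit."""

    band: str
    family: str
    coefficients: tuple[float, ...]
    r2: float
    date: str | None = None

    def __call__(self, dn):
        return evaluate_family(self.family, self.coefficients, np.asarray(dn, dtype=float))


def evaluate_family(family: str, coeffs: Sequence[float], x):
    x = np.asarray(x, dtype=float)
    if family == "linear":
        a, b = coeffs
        return a * x + b
    if family == "quadratic":
        a, b, c = coeffs
        return a * x**2 + b * x + c
    if family == "exponential":
        a, b = coeffs
        return a * np.exp(b * x)
    if family == "logarithmic":
        a, b = coeffs
        return a * np.log(x) + b
    if family == "power":
        a, b = coeffs
        return a * np.power(x, b)
    raise CalibrationError(f"unknown family {family!r}")


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _fit_one(family: str, x: np.ndarray, y: np.ndarray) -> tuple[float, ...] | None:
    """Least-squares fit of one family; None if the domain is violated or fit fails."""
    try:
        if family == "linear":
            return tuple(np.polyfit(x, y, 1))
        if family == "quadratic":
            return tuple(np.polyfit(x, y, 2))
        if family == "logarithmic":
            if np.any(x <= 0):
                return None
            a, b = np.polyfit(np.log(x), y, 1)
            return (a, b)
        if family == "exponential":
            if np.any(y <= 0):
                return None
            b, lna = np.polyfit(x, np.log(y), 1)
            p0 = (float(np.exp(lna)), float(b))
            try:  # refine the log-linearised estimate on the original scale
                popt, _ = curve_fit(
                    lambda t, a, b: a * np.exp(b * t), x, y, p0=p0, maxfev=10000
                )
                return tuple(float(v) for v in popt)
            except (RuntimeError, ValueError):
                return p0
        if family == "power":
            if np.any(x <= 0) or np.any(y <= 0):
                return None
            b, lna = np.polyfit(np.log(x), np.log(y), 1)
            p0 = (float(np.exp(lna)), float(b))
            try:
                popt, _ = curve_fit(
                    lambda t, a, b: a * np.power(t, b), x, y, p0=p0, maxfev=10000
                )
                return tuple(float(v) for v in popt)
            except (RuntimeError, ValueError):
                return p0
    except (np.linalg.LinAlgError, ValueError):
        return None
    raise CalibrationError(f"unknown family {family!r}")


def fit_calibration(
    pairs: Iterable[CalibrationPair], band: str, date: str | None = None
) -> CalibrationModel:
    """Fit all five families to one band's tarp pairs and keep the best by r²."""
    sel = [
        p
        for p in pairs
        if p.band == band and (date is None or p.date is None or p.date == date)
    ]
    if len(sel) < 3:
        raise CalibrationError(
            f"band {band!r}: {len(sel)} tarp pairs, need at least 3"
        )
    x = np.array([p.dn for p in sel], dtype=float)
    y = np.array([p.reflectance for p in sel], dtype=float)
    if np.ptp(x) == 0:
        raise CalibrationError(f"band {band!r}: all tarp DN values identical")

    candidates: list[CalibrationModel] = []
    for family in FAMILIES:
        coeffs = _fit_one(family, x, y)
        if coeffs is None:
            continue
        yhat = evaluate_family(family, coeffs, x)
        if not np.all(np.isfinite(yhat)):
            continue
        candidates.append(CalibrationModel(band, family, coeffs, _r2(y, yhat), date))
    if not candidates:
        raise CalibrationError(f"band {band!r}: no calibration family could be fitted")

    best_r2 = max(m.r2 for m in candidates)
    tied = [m for m in candidates if m.r2 >= best_r2 - _R2_TIE_TOL]
    tied.sort(key=lambda m: (N_PARAMS[m.family], FAMILIES.index(m.family)))
    return tied[0]


def fit_all_bands(
    pairs: Iterable[CalibrationPair], bands: Sequence[str], date: str | None = None
) -> dict[str, CalibrationModel]:
    pairs = list(pairs)
    return {b: fit_calibration(pairs, b, date) for b in bands}


def apply_calibration(
    stack: BandStack, models: Mapping[str, CalibrationModel]
) -> BandStack:
    """Convert a DN-valued stack to reflectance using per-band fitted models."""
    if stack.is_reflectance:
        raise CalibrationError("stack is already reflectance-valued")
    missing = [b for b in stack.band_names if b not in models]
    if missing:
        raise CalibrationError(f"no calibration model for bands: {missing}")
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for name in stack.band_names:
            out[name] = np.asarray(models[name](stack.bands[name]), dtype=np.float64)
    return BandStack(
        out,
        stack.transform,
        stack.crs,
        nodata=-9999.0,
        mask=stack.mask.copy(),
        is_reflectance=True,
    )


def read_tarp_csv(path) -> list[CalibrationPair]:
    """Load tarp pairs from CSV with columns tarp_id, band, dn, reflectance[, date]."""
    df = pd.read_csv(path)
    required = {"tarp_id", "band", "dn", "reflectance"}
    if not required.issubset(df.columns):
        raise CalibrationError(
            f"tarp CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    return [
        CalibrationPair(
            str(r.tarp_id),
            str(r.band),
            float(r.dn),
            float(r.reflectance),
            str(r.date) if "date" in df.columns and pd.notna(r.date) else None,
        )
        for r in df.itertuples()
    ]


def calibration_report(models: Iterable[CalibrationModel]) -> pd.DataFrame:
    """One row per fitted model: band, date, family, coefficients, r²."""
    rows = [
        {
            "band": m.band,
            "date": m.date,
            "family": m.family,
            "coefficients": ";".join(f"{c:.10g}" for c in m.coefficients),
            "r2": m.r2,
        }
        for m in models
    ]
    return pd.DataFrame(rows, columns=["band", "date", "family", "coefficients", "r2"])
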