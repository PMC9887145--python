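"""Exception hierarchy for the pipeline."""


class UavYieldError(Exception):
    """Base class for all package errors."""


class RasterFormatError(UavYieldError):
    """Raster file is missing, malformed, or inconsistent with the band map."""


class CRSMismatchError(UavYieldError):
    """Plot geometries and raster carry different coordinate reference systems."""


class PlotClipError(UavYieldError):
    """A plot polygon does not intersect the raster, or yields no valid pixels."""

    def __init__(self, plot_id: str, message: str):
        self.plot_id = plot_id
        super().__init__(f"plot {plot_id!r}: {message}")


class PlotGeometryError(UavYieldError):
    """Invalid plot polygons or duplicated plot identifiers."""


class CalibrationError(UavYieldError):
    """Radiometric calibration could not be fitted or applied."""


class FeatureError(UavYieldError):
    """Feature computation failed (missing band, wrong value scale, no valid pixels)."""


class LodgingError(UavYieldError):
    """Lodging raster summarisation failed."""


class ModelError(UavYieldError):
    """Yield-model training or evaluation failed."""


class ConfigError(UavYieldError):
    """Run configuration is invalid (missing paths, bad keys)."""
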