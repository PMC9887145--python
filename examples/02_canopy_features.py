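"""Spectral indices, canopy coverage and canopy height for one plot.

Builds a tiny reflectance stack, an RGB patch with a canopy/soil pattern,
and a DSM/DEM pair, then prints NDVI and friends, the CIVE-based canopy
coverage, and the mean canopy height.
"""

import numpy as np

from uavyield.canopy import (
    compute_canopy_mask,
    compute_cc,
    compute_chm,
    compute_cive,
    compute_vegetation_indices,
    plot_canopy_height,
)
from uavyield.geo import Affine, BandStack, ElevationRaster

T = Affine(0.4, 0, 0, 0, -0.4, 4.0)

refl = BandStack(
    {
        "blue": np.full((10, 10), 0.05),
        "green": np.full((10, 10), 0.12),
        "red": np.full((10, 10), 0.10),
        "rededge": np.full((10, 10), 0.30),
        "nir": np.full((10, 10), 0.50),
    },
    T,
    is_reflectance=True,
)
vis = compute_vegetation_indices(refl)
means = vis.plot_means()
print("Spectral indices (uniform canopy, NIR=0.50, R=0.10):")
for name in ("NDVI", "RVI", "OSAVI", "NDRE", "EVI2"):
    print(f"  {name:6s} = {means[name]:.4f}")

# RGB patch: left 60 columns canopy-coloured, right 40 columns soil-coloured
rgb = {
    "R": np.where(np.arange(100).reshape(10, 10) % 10 < 6, 100.0, 150.0),
    "G": np.where(np.arange(100).reshape(10, 10) % 10 < 6, 140.0, 128.0),
    "B": np.where(np.arange(100).reshape(10, 10) % 10 < 6, 78.0, 108.0),
}
canopy = compute_canopy_mask(compute_cive(rgb))
cc = compute_cc(canopy)
print(f"\nCanopy coverage: {cc:.2f} (fraction of plot pixels with CIVE in [-28, 5])")

dsm = ElevationRaster(np.where(canopy.mask, 77.2, 75.0), "DSM", T)
dem = ElevationRaster(np.full((10, 10), 75.0), "DEM", T)
ch = plot_canopy_height(compute_chm(dsm, dem), canopy)
print(f"Canopy height: {ch:.2f} m (mean of DSM-DEM over canopy pixels)")
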