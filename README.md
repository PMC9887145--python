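# uavyield

Plot-level maize yield estimation from UAV imagery, with an explicit account
of **lodging** — the storm-driven displacement of stems from vertical that
silently corrupts yield models built on canopy reflectance alone.

The package is aimed at crop-phenotyping and precision-agriculture work where
a field trial is observed by a low-altitude UAV carrying RGB and
multispectral cameras, plot boundaries are known polygons, and per-plot grain
yield is measured at harvest. It provides:

- **Radiometric calibration** — empirical-line DN→reflectance transfer
  functions per band fitted to tarpaulin targets of known reflectance; five
  candidate families (linear, quadratic, exponential, logarithmic, power)
  are fitted and the best by r² is kept.
- **Canopy features** — the 13 published spectral vegetation indices
  (NDVI, RVI, GRVI, OSAVI, NDRE, MCARI, TCARI, GNDVI, WDRVI, GCI, RECI,
  EVI2, NDREI); canopy coverage CC from CIVE segmentation
  (CIVE = 0.441·R − 0.811·G + 0.385·B + 18.787, canopy where CIVE ∈ [−28, 5]);
  canopy height CH from a crop height model CHM = DSM − DEM; and eight GLCM
  texture statistics (MEAN, VAR, HOM, CON, DIS, ENT, ASM, COR) over a 7×7
  sliding window.
- **Lodging index** — pixels classed as no (NL), light (LL) or severe (SL)
  lodging are summarised per plot into area fractions Sᵢ and the index
  **LI = Σ LDᵢ·Sᵢ** with class codes LD = (0, 1, 2), so LI = 0 is fully
  upright and LI = 2 fully flattened.
- **Yield model** — random-forest regression (100 trees, seeded, 80/20
  train/test split) fitted with and without the LI column, evaluated by
  R² = 1 − Σ(ŷᵢ−yᵢ)²/Σ(yᵢ−ȳ)², RMSE = √(Σ(ŷᵢ−yᵢ)²/n) and
  rRMSE = RMSE/ȳ × 100 %, plus impurity-based variable importances and the
  residual-versus-LI trend that exposes the overestimation of lodged plots.
- **Synthetic scenarios** — a seeded generator that emits the exact formats
  the pipeline consumes (GeoTIFF stacks, GeoJSON plots, CSV tables) with a
  known generative law, so everything is testable without field data.

## Worked example

`examples/05_yield_model.py` draws the default 132-plot scenario — yields
follow `base + gain·vigor − penalty·LI + noise` — and fits the model both
ways:

```
without_LI: R2=0.747  RMSE= 1175.0 kg/ha  rRMSE=14.23%  residual-vs-LI slope= 2083.0
with_LI   : R2=0.888  RMSE=  783.7 kg/ha  rRMSE= 9.49%  residual-vs-LI slope= 1025.6
```

Read: without the lodging index the model cannot see the yield lost to
lodging, so it overestimates flattened plots — residuals grow by ≈2,083 kg/ha
per LI unit, close to the generative penalty. Adding LI recovers most of that
(RMSE drops ~33 %, the residual slope shrinks by half). The other examples
cover calibration (`01`), canopy features (`02`), textures with their
brute-force cross-check (`03`), the lodging index (`04`) and the full
raster-to-metrics pipeline (`06`).

The same pipeline is available from the shell:

```bash
uavyield make-fixtures --out scene --seed 7
uavyield run --config run.yaml     # calibrate -> features -> lodging -> model
uavyield report --config run.yaml
```

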