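# brixmap

Near-infrared hyperspectral imaging (NIR-HSI) pipeline for mapping sugar
content (Brix, % soluble solids) across fruit flesh, built around the
white-strawberry use case: the fruit's colour carries no ripeness
information, so quality must be read from short-wave-infrared molecular
absorption (913–2166 nm) instead.

The pipeline covers the full path from raw push-broom camera counts to a
per-pixel sugar map:

1. **Reflectance calibration** — raw counts S are converted to relative
   reflectance with white/dark references, R = (S − D)/(W − D), per pixel and
   wavelength, then clipped to the 913–2166 nm analysis range.
2. **Spectral pretreatments** — Savitzky–Golay smoothing, the standard normal
   variate (SNV, per-spectrum centering/unit-SD scaling that removes
   multiplicative and additive scatter), SG second derivatives, and per-band
   autoscaling.
3. **Training-free segmentation** — background and resin tray are removed by
   thresholding reflectance at 1077 nm (> 1.205), sepals by thresholding the
   SNV value at 1940 nm (> −1.325); specular (Fresnel) saturated pixels are
   discarded; the remaining fruit pixels are decomposed by PCA fitted per
   surface, the PC1 score image is binarised with Otsu's method, and the
   smaller class is labelled achene (the seed-like true fruits covering
   ~9% of the surface). A bounding-box midpoint split yields six ROI masks:
   {fruit, flesh, achene} × {bottom, top}.
4. **Chemometrics** — PLS1 regression (SIMPLS, NIPALS available) between mean
   ROI spectra and Brix references; latent variables chosen by 10-fold
   cross-validation with the "global minimum + 1 SD" parsimony rule (cap 20);
   CARS (competitive adaptive reweighted sampling) wavelength selection: per
   Monte-Carlo run bands are ranked by |PLS coefficient|, an exponentially
   decaying schedule (retention pinned to 1 at run 1 and 2/p at the last run)
   enforces the retained count, coefficient-weighted sampling picks the
   survivors, and the subset with the lowest RMSECV wins. A 2×2×2×3 model
   grid (raw/SNV × second derivative or not × CARS or not × three ROIs)
   reports RMSECV/RMSEC/RMSEP and R²c/R²p, sorted ascending by R²p.
5. **Visualisation** — the calibration is applied to every flesh pixel,
   the map is denoised with mask-aware Gaussian smoothing, rendered as a
   heatmap, and summarised with violin statistics (KDE, median, IQR, mean)
   for the whole flesh and its bottom/top halves.

Because real hyperspectral fruit data are rarely public, the package ships a
first-class synthetic-scene module (`brixmap.synthetic`): endmember spectra
with the water/sugar absorption features at 970, 1165, 1420, 1780 and
1900 nm (plus the achene-only C–H₂ feature near 1710 nm), labelled
strawberry scenes with a spatially varying Brix field, per-pixel scatter and
noise, and flat spectra-vs-Brix tables — all with recorded ground truth, so
every pipeline stage can be validated against a known answer.

## Worked example

```python
import numpy as np
from brixmap.synthetic import generate_scene
from brixmap.segmentation import build_roi_set
from brixmap.chemometrics import plsr_fit
from brixmap.mapping import predict_map, smooth_map, violin_summary
from brixmap.preprocess import Pretreatment, SpectrumTable

# a labelled 128x128 scene with a 5 -> 10 Brix gradient along the fruit axis
cube, truth = generate_scene(shape=(128, 128), seed=7)

# calibrate on 800 randomly sampled flesh pixels with known Brix
rng = np.random.default_rng(7)
idx = np.argwhere(truth.labels == 3)
pick = idx[rng.choice(len(idx), 800, replace=False)]
cal = SpectrumTable(cube.data[pick[:, 0], pick[:, 1]], cube.axis,
                    truth.brix_field[pick[:, 0], pick[:, 1]])
model = plsr_fit(cal, pretreatment=Pretreatment(snv=True, smooth_window=7),
                 seed=7)

# segment a fresh scene and map its sugar content
cube2, truth2 = generate_scene(seed=8)
rois = build_roi_set(cube2)
flesh = rois.masks["flesh_bottom"] | rois.masks["flesh_top"]
bmap = smooth_map(predict_map(cube2, flesh, model), sigma=1.0)
summary = violin_summary(bmap, rois.masks["flesh_bottom"],
                         rois.masks["flesh_top"])
for name in ("whole", "bottom", "top"):
    s = summary.regions[name]
    print(f"{name:6s}: mean {s.mean:.2f}  median {s.median:.2f}  "
          f"IQR [{s.q1:.2f}, {s.q3:.2f}]  n={s.n_pixels}")
```

prints

```
whole : mean 7.40  median 7.44  IQR [6.81, 8.01]  n=3967
bottom: mean 6.77  median 6.81  IQR [6.42, 7.15]  n=1985
top   : mean 8.03  median 8.01  IQR [7.76, 8.30]  n=1982
```

The two-latent-variable calibration recovers the scene's sugar gradient: the
top half of the fruit (where the synthetic field places more sugar, as in
real strawberries, which sweeten toward the apex) averages 1.3 Brix% above
the bottom half, and the per-pixel map correlates with the true field at
r = 0.97. On flat calibration tables (n = 400, Brix noise 0.2), CARS
typically keeps ~30 of 200 bands — clustered on the 1420/1780/1900 nm
sugar- and water-related features — and the held-out fit reaches
R²p ≈ 0.97 at RMSEP ≈ 0.28 Brix%.

A command-line interface mirrors the library:

```bash
brixmap simulate scene --shape 128x128 --seed 7 --out scene/
brixmap segment --cube scene/cube.npz --out rois/
brixmap simulate dataset --n 400 --seed 7 --out table.csv
brixmap train --table table.csv --pretreat raw --cars --seed 7 --out model.json
brixmap predict-map --cube scene/cube.npz --model model.json --out maps/
```

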