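# anthoscan

Non-destructive quantification of leaf anthocyanin from hyperspectral and
RGB images, with genotype × environment (G×E) partitioning of the resulting
measurements.

Anthocyanins are the red–purple flavonoid pigments of leaves; their
accumulation responds strongly to light and temperature, which makes
non-destructive monitoring attractive for indoor farming and cultivar
selection. `anthoscan` implements the full analysis chain for a
leaf-on-white-panel imaging protocol:

1. **Reflectance calibration** — raw ENVI-style cubes (BIL/BIP/BSQ) are
   normalized band-by-band against the white reference panel in the scene:
   R(λ) = counts(λ) / panel_mean(λ).
2. **Leaf segmentation** — NDVI thresholding against the spectrally flat
   panel (hyperspectral) or near-white background removal (RGB).
3. **Anthocyanin reflectance indices** — per pixel, on discrete sensor bands:

   | index | formula |
   |---|---|
   | ARI  | 1/R₅₅₀.₁₄ − 1/R_redEdge |
   | mARI | R̄₇₅₉.₅–₇₉₇.₀₂ × (1/R₅₅₀.₁₄ − 1/R₇₀₁.₀₆) |
   | wavelength-corrected mARI (default) | R̄₇₅₉.₅–₇₉₇.₀₂ × (1/R₅₅₀.₁₄ − 1/R₇₀₆.₃₅) |
   | ACI  | R₅₅₀.₁₄ / R̄₇₅₉.₅–₇₉₇.₀₂ |

   The NIR term R̄ is the mean over all bands inside the closed window; the
   corrected red edge sits one 4.69 nm band above the original.
4. **Linear calibration to content** — leaf-mean index → mg anthocyanin per
   g dry weight via y = a·x + b. The built-in model `"bokchoy2021"`
   (a = 1.8123, b = 0.0962, R² = 0.9958, n = 20) was fitted on bok choy
   against wet-chemistry reference values; `fit_calibration` fits your own.
5. **RGB purple-area scoring** — percentage of leaf pixels within a
   per-channel ±20% band of a reference purple/red color.
6. **G×E statistics** — balanced two-way ANOVA (from raw replicates *or*
   published cell summaries), percentages of variation on a
   sum-of-squares or variance-component basis, F-tests against the residual
   or interaction mean square, and Fisher's LSD letter groupings.

A seeded synthetic-data module generates every input with known ground truth
(leaf cubes under a reciprocal-linear pigment absorption model, RGB leaves
with an exact purple fraction, replicated G×E tables, extract absorbance
spectra), so the entire pipeline is testable at desk scale.

## Worked example

Recover a known anthocyanin gradient end to end — simulate 20 leaf cubes at
0–12 mg/g with sensor noise, calibrate leaf reflectance against the in-scene
panel, segment, compute corrected mARI, and fit the index→content line:

```python
import numpy as np
from anthoscan import (LeafSimParams, apply_calibration, fit_calibration,
                       mari, segment_leaf_hsi, simulate_leaf_cube,
                       to_reflectance)

ta_grid = np.linspace(0, 12, 20)
means = []
for i, ta in enumerate(ta_grid):
    sim = simulate_leaf_cube(LeafSimParams(anthocyanin=float(ta),
                                           noise_sd=0.005, seed=100 + i))
    refl = to_reflectance(sim.cube, sim.panel)
    mask = segment_leaf_hsi(refl)
    means.append(mari(refl, mask).leaf_mean)

model = fit_calibration(means, ta_grid)
print(f"slope={model.slope:.4f} intercept={model.intercept:.4f} "
      f"R2={model.r_squared:.4f} RMSE={model.rmse:.4f}")

held = simulate_leaf_cube(LeafSimParams(anthocyanin=7.5, noise_sd=0.005, seed=999))
refl = to_reflectance(held.cube, held.panel)
est = apply_calibration(mari(refl, segment_leaf_hsi(refl)).leaf_mean, model)
print(f"held-out true 7.5 -> estimated {est:.3f} mg/g")
```

```
slope=10.1709 intercept=24.2370 R2=0.9999 RMSE=0.0343
held-out true 7.5 -> estimated 7.400 mg/g
```

The index is linear in pigment load (R² ≈ 1), and a held-out leaf's content
is recovered to ~0.1 mg/g — the calibrate→predict loop working as intended.

The package also ships the cell summaries (mean ± SD, n = 4) of a real
4-cultivar × 4-treatment bok choy trial. Reconstructing its variance
partition for the hyperspectral channel:

```python
from anthoscan.datasets import reconstruct_partition
print(reconstruct_partition("hyperspectral").to_frame().to_string(index=False))
```

```
     source    ss  df     ms     F         p stars  percentage
   genotype 331.5   3  110.5 9.657  0.003568    **       58.22
environment 90.25   3  30.08 2.629    0.1141             10.95
        gxe   103   9  11.44 20.52 1.297e-13   ***       25.59
   residual 26.77  48 0.5577   NaN       NaN             5.243
```

Cultivar identity dominates (≈58% of variation), the G×E interaction is
substantial and highly significant, and the environment main effect is not
significant when tested against the interaction — the pattern a breeder
reads as "pick the right cultivar, then match it to the environment".

## Command line

```sh
anthoscan simulate cube --ta 5 --seed 1 --out demo/
anthoscan indices demo/cube.hdr --panel 0:6,0:64 --index mari_corrected \
    --calibration bokchoy2021 --out results.csv
anthoscan color-area leaf.png --ref purple=0.45,0.20,0.45 --tol 0.20
anthoscan gxe cells.csv --from-summaries --percent-of variance_components \
    --test-against interaction
anthoscan run --config run.toml --seed 1 --out run_out/
```

`anthoscan run` executes the whole pipeline (simulate → measure → report)
and writes a manifest with the config hash; re-running the same config is
byte-identical.

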