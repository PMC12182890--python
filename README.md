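# adipo3d

3D morphometry of adipocytes in cleared adipose tissue imaged by
light-sheet fluorescence microscopy.

Adipocyte hypertrophy — the enlargement of lipid-storing fat cells — is a
structural hallmark of obesity, and classical 2D histology systematically
misrepresents it: a section through a sphere almost never passes through
its equator. This package implements the computational side of a 3D
workflow for whole-mount adipose tissue: lipid-stained adipocytes (Nile
Red-like channel) embedded in an extracellular-matrix shell (5-DTAF-like
channel) are segmented in 3D, measured per cell, and compared across
experimental groups. Because raw light-sheet volumes of this kind are
rarely shareable, the package ships a synthetic tissue-phantom generator
with exact ground truth, so every stage of the pipeline is verifiable.

It is intended for microscopists and image-analysis people who want a
tested, scriptable, fully classical (no GPU, no trained weights)
equivalent of the commercial "separate objects / circular open / measure"
pipelines, plus the statistics that usually follow them.

## What it computes

For each segmented cell with volume $V$ (voxel count × voxel volume) and
meshed surface area $A$:

- **equivalent diameter** $d_{eq} = (6V/\pi)^{1/3}$ — the diameter of the
  volume-matched sphere;
- **sphericity** $\Psi = \pi^{1/3}(6V)^{2/3} / A$ — the surface area of
  the volume-matched sphere over the cell's surface area, so a perfect
  sphere attains the maximum $\Psi = 1$;
- **nearest object distance (NOD)** — Euclidean distance from the cell's
  centroid (binary center of gravity) to the nearest other centroid;
- plus per-sample **object count** and **total object volume**.

Group comparisons report mean ± SEM (pooled per-cell $n$), two-sided
Mann–Whitney $U$ tests, percent differences between group means, and
binned class distributions compared bin-by-bin with multiple Mann–Whitney
tests under false-discovery-rate control at $Q = 5\%$ (two-stage step-up).

The segmentation chain is: intensity thresholding (Otsu or fixed, with
optional depth-attenuation correction) → morphological "circular open"
(ellipsoidal structuring element in physical µm) → "separate objects"
(watershed on the anisotropy-aware Euclidean distance transform with
h-maxima seed suppression) → object filtering (minimum volume,
border-touching exclusion). An optional trainable thresholding backend
(multi-scale logistic pixel classifier with a two-round training
schedule) is provided in `adipo3d.learning`.

## Worked example

Simulate one healthy and one obese sample (true mean volumes calibrated
to 248,754 and 299,242 µm³), segment, measure, and summarize:

```python
import pandas as pd
from adipo3d import (GeneratorParams, SegmentationConfig, generate_phantom,
                     group_summary, measure_all, percent_difference, segment)

frames = []
for group, mean, seed in (("healthy", 248_754.0, 1), ("obese", 299_242.0, 2)):
    params = GeneratorParams(
        n_cells=120, domain_size=(700.0, 700.0, 300.0),
        volume_mean=mean, volume_cv=0.4,
        voxel_size=(3.24, 3.24, 4.0), seed=seed,
    )
    phantom = generate_phantom(params)
    labels, log = segment(phantom.image, SegmentationConfig())
    frames.append(measure_all(labels.data, phantom.image.voxel_size,
                              sample_id=f"{group}_s1", group=group))

summary = group_summary(pd.concat(frames, ignore_index=True))
print(summary[["feature", "group", "n", "mean", "sem", "p_value"]]
      .round(4).to_string(index=False))
means = summary.set_index(["feature", "group"])["mean"]
pct = percent_difference(means[("volume_um3", "healthy")],
                         means[("volume_um3", "obese")])
print(f"\nmeasured volume increase with obesity: {pct:.2f}%")
```

prints

```
               feature   group   n        mean        sem  p_value
            volume_um3 healthy 120 245843.9942  9028.2077   0.0004
            volume_um3   obese 120 295790.5253 10844.6804   0.0004
                nod_um healthy 120     83.5490     0.6261   0.0000
                nod_um   obese 120     87.4915     0.5387   0.0000
equivalent_diameter_um healthy 120     76.4339     0.9108   0.0004
equivalent_diameter_um   obese 120     81.2960     0.9685   0.0004
            sphericity healthy 120      0.9870     0.0001   0.3266
            sphericity   obese 120      0.9868     0.0001   0.3266

measured volume increase with obesity: 20.32%
```

The measured group means sit within ~1.5% of the calibrated true means
(the residual bias comes from blur and thresholding at the cell surface),
and the recovered percent difference matches the 20.3% volume increase
built into the simulation. Sphericity is near 1 here because the phantom
cells are spheres; real adipocytes are deformed by packing and measure
lower. NOD reflects the spatial packing of the simulated cohort, not a
biological value.

The same stages are available from the shell:

```sh
adipo3d simulate --config config.yaml --out study/ --seed 1
adipo3d segment  --in study/healthy_s1_image.ome.tiff --out labels.tiff --log seg.json
adipo3d measure  --labels labels.tiff --out features.csv --group healthy --sample-id s1
adipo3d stats    --features features.csv ... --out stats/
adipo3d run-all  --config config.yaml --out run/ --seed 1
```

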