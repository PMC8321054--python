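# locseg3d

Coarse-to-fine localisation and segmentation of cardiac structures in
3D MR volumes: a small dilated-residual 3D U-Net first predicts a
coarse density map of the target structure on a downsampled volume; a
gradient-weighted class activation map (GCAM) derived from its features
places a fixed-size high-resolution region of interest; a second
network then segments inside that crop at native resolution. An
end-to-end variant trains both networks jointly with multiplicative
attention fusion.

The package is aimed at researchers working on volumetric medical-image
segmentation who want a dependency-light, fully testable implementation
of the localize-then-segment pattern: readers/writers for NIfTI and
NRRD, the preprocessing chain (slice-wise CLAHE, z-normalization,
spacing resampling, pad/center-crop with exact inverses), the network
builder, the training objectives, surface-distance evaluation metrics,
Bland–Altman volume agreement, and a seeded synthetic-phantom generator
so everything runs without data downloads. The neural-network core is a
compact numpy reverse-mode autodiff engine — no GPU framework required.

## The model in brief

For localizer feature maps `x` with channels `x_k` and a scalar class
score `S_c` (the sum of class-`c` logits over all voxels),

```
GCAM_c = ReLU( Σ_k x_k · ∂S_c/∂x_k )
```

The intensity-weighted centroid of `{GCAM ≥ 0.5·max}` is mapped to
full-resolution coordinates and a fixed-size box is placed around it
(clipped inside the volume). Training minimizes, for binary targets,

```
ζ = ζ_dice + ζ_bce ,   ζ_dice = 1 − (2 Σ y ŷ + s) / (Σ y + Σ ŷ + s)
```

and for multi-class targets the multi-class soft dice (mean of
per-class dice terms). Evaluation uses DSC = 2|G∩P|/(|G|+|P|),
the (symmetric, by default) Hausdorff distance, and the average
symmetric surface distance, all in millimetres with anisotropic voxel
spacing, plus Bland–Altman bias and ±1.96·SD limits of agreement on
per-case volumes.

## Worked example

```python
import numpy as np
from locseg3d import PhantomSpec, generate, MultiStageSegmenter3D, evaluate_cases

cases = generate(PhantomSpec(mode="blob", shape=(16, 32, 32), n_cases=24, seed=7))
X = [v for v, _ in cases]
y = [lv for _, lv in cases]

est = MultiStageSegmenter3D(max_epochs=15, patience=6, seed=3)
est.fit(X[:20], y[:20])                       # localizer, then segmenter on ROIs
print("derived crop:", est.crop_shape_)
print("held-out dice:", round(est.score(X[20:], y[20:]), 3))

preds = est.predict(X[20:])
report, ba = evaluate_cases(
    {f"c{i}": p for i, p in enumerate(preds)},
    {f"c{i}": t for i, t in enumerate(y[20:])},
)
print(report.aggregates.to_string(index=False))
print("blob volume bias (mm^3):", round(ba["blob"].bias, 2),
      "LoA:", (round(ba["blob"].loa_low, 2), round(ba["blob"].loa_high, 2)))
```

Output:

```
derived crop: (16, 32, 32)
held-out dice: 0.929
structure     dsc             hd_mm            asd_mm          vol_pred_mm3           vol_gt_mm3
             mean      std     mean      std     mean      std         mean       std       mean       std
     blob 0.92897 0.018655 0.933546 0.099324 0.148581 0.024743   242.248535 53.257502 212.158203 54.212414
blob volume bias (mm^3): -30.09 LoA: (-35.59, -24.59)
```

`est.score` is the mean dice between full-resolution predictions and
ground truth on the held-out phantoms (1.0 is perfect overlap); the
report adds boundary distances in mm (sub-voxel Hausdorff here: the
phantoms are 0.625 mm isotropic) and per-case volumes. The negative
Bland–Altman bias says this lightly trained model systematically
over-segments the blob by ~30 mm³; training the same estimator longer
(or on more cases, as the acceptance experiments do) drives dice toward
1 and the bias toward 0. This is a two-minute CPU run on 16×32×32 smoke
phantoms; the experiment sizes used by the acceptance script are
documented in `docs/methods.md`.

A command-line interface mirrors the library
(`locseg3d generate-phantoms / preprocess / train / localize / predict /
evaluate`), writing checkpoints, config echoes, split specifications and
per-epoch CSV logs into the run directory.

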