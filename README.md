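# rotphenex

Rotated-bounding-box detection and phenotypic trait extraction for wheat
seedling leaves.

Wheat seedling leaves are narrow, high-aspect-ratio blades that grow at
arbitrary orientations, so axis-aligned (horizontal) detection boxes enclose
mostly background and cannot express a leaf's posture. This package works
end to end with **oriented boxes**: the five-parameter long-side form
`(cx, cy, w, h, θ)` — `h` the long side, `w` the short side, `θ ∈ [−90°, 90°)`
the long side's screen-counterclockwise rotation — and its equivalent
eight-parameter four-vertex form used by DOTA files and by the trait
formulas.

It is aimed at plant-phenotyping researchers and engineers who need:

- exact rotated-box geometry (conversion, polygon-clipping IoU, rotated NMS);
- annotation I/O in the roLabelImg PASCAL-VOC-XML and DOTA-text dialects,
  plus 7:2:1 dataset splitting and label-aware augmentation;
- a synthetic scene generator that renders dark-background pot images of
  elongated blades with exact ground truth (no public dataset of this kind
  with rotated labels exists);
- a CPU-trainable rotated detector — MobileOne reparameterizable backbone,
  CSP/PAN neck with efficient channel attention (ECA), and an angle-aware
  head that classifies the box angle into one-degree bins with circular
  smooth labels (CSL) — trained with a composite BCE + objectness + CIoU +
  CSL loss;
- VOC-style rotated evaluation (precision, recall, F1, AP, mAP) and
  per-trait agreement statistics (R²);
- leaf trait extraction from the box vertices.

## The core quantities

With canonical vertices `v1..v4` (edge `v2→v3` spans the long side), each
detected leaf yields

| trait | formula |
|---|---|
| inclination θ | `arctan(|y2−y3| / |x2−x3|)` |
| length h | `√((x2−x3)² + (y2−y3)²)` |
| width w | `√((x4−x3)² + (y4−y3)²)` |
| aspect ratio | `h / w` |
| area S | `h · w` |

and the leaf count of a plant is the number of post-NMS detections.
Detection quality uses `Precision = TP/(TP+FP)`, `Recall = TP/(TP+FN)`,
`F1 = 2PR/(P+R)`, `AP = ∫ P(R) dR` (monotone-envelope interpolation) at a
rotated-IoU matching threshold of 0.5, and mAP as the class mean.

## Worked example

```python
from rotphenex import RotatedBox, ScaleCalibration, extract_plant

detections = [
    (RotatedBox(150, 200, w=12, h=85, theta=40), 0.95),
    (RotatedBox(260, 180, w=18, h=140, theta=-62), 0.91),
    (RotatedBox(210, 320, w=9, h=60, theta=12), 0.88),
]
summary, table = extract_plant(detections, scale=ScaleCalibration(0.5))
print(summary.leaf_count)
print(table[["inclination_deg", "length", "width", "aspect", "area"]].round(2))
```

prints

```
3
   inclination_deg  length  width  aspect   area
0             40.0    42.5    6.0    7.08  255.0
1             62.0    70.0    9.0    7.78  630.0
2             12.0    30.0    4.5    6.67  135.0
```

— three leaves; with the 0.5 mm/px calibration the first leaf is 42.5 mm
long and 6 mm wide, leaning 40° from horizontal, with 255 mm² of blade area.
More narrative scripts live in `examples/` (geometry, annotation dialects,
synthetic scenes and augmentation, desk-scale training, branch fusion).

## Command line

```bash
rotphenex synth --n 50 --seed 1 out/                 # synthetic dataset
rotphenex convert --from rolabelimg --to dota IN OUT # annotation dialects
rotphenex split --ratios 7 2 1 --seed 42 list.txt    # train/test/val
rotphenex train --config cfg.yaml --data out/ --out model.ckpt
rotphenex detect --ckpt model.ckpt.npz --out preds/ out/images
rotphenex eval --gt out/labels --pred preds/ --out report.json
rotphenex traits --pred preds/ --scale-mm-per-px 0.5 --out traits.csv
rotphenex pipeline --config run.yaml workdir/        # all stages
```

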