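# iispine

Iterative instance segmentation of the lumbar spine in sagittal MRI:
vertebrae, intervertebral discs (IVDs) and the spinal canal, one vertebral
level at a time.

Automated lumbar-spine segmentation is the first step toward quantitative
reading of low-back-pain MRI. The label space is awkward for one-shot
semantic segmentation: the number of visible vertebrae varies, the top
vertebra is often cut by the field of view, and anatomical naming (L1–L5) is
unreliable when transitional vertebrae are present. `iispine` implements the
iterative instance-segmentation (IIS) strategy instead: a 3D patch walks the
spine caudal→cranial, and binary *instance memory* volumes — one for
vertebrae, one for IVDs, one for the canal — are fed back to the network so
that each step segments exactly the lowest vertebra not yet in memory,
together with its inferior disc and the visible part of the canal. Instances
are labelled bottom-up (1 = most caudal vertebra), which is deliberate,
non-anatomical and robust.

The package is aimed at researchers developing or benchmarking spine
segmentation methods. It contains:

* `volume_io` — MetaImage (.mha) reading/writing on a fixed internal axis
  convention, the configurable label-encoding dialect, study manifests;
* `phantom` — a synthetic spine-phantom generator with exact ground truth
  (3–9 vertebrae, discs, canal, T1/T2-like contrast, optional truncated top
  vertebra), so everything is testable without downloading data;
* `preprocess` — working-grid resampling, robust z-score normalisation,
  joint image/mask augmentation;
* `iis` — the traversal engine: raster search, center-of-mass convergence,
  memory commits, canal stitching, plus an oracle backbone for testing;
* `model` — the trainable backbone (a compact numpy 3D U-net with
  completeness and label heads) and the composite
  segmentation/label/completeness loss;
* `evaluate` — the instance-matched protocol: largest-overlap matching, 3D
  Dice, symmetric average absolute surface distance (ASD) in mm, detection
  and completeness accuracy, aggregated per structure and per sequence.

A scikit-learn-style estimator ties it together:

```python
from iispine import IterativeInstanceSegmenter
from iispine.profiles import desk_cohort

cohort = desk_cohort(30, seed=1, splits=(24, 6))          # synthetic studies
studies = [(img, mask, split) for img, mask, split, _ in cohort]

est = IterativeInstanceSegmenter(
    patch_size=(16, 40, 40), widths=(6, 12, 24),
    working_spacing=(4.0, 1.5, 1.5), epochs=12, seed=0,
)
est.fit(studies)                                          # trains the backbone
result = est.predict(studies[-1][0])                      # -> SegmentationResult
print(len(result.instances), result.label_map.values.max())
```

## Worked example

With a *perfect* (oracle) backbone derived from a ground-truth mask, the
traversal must reproduce that mask exactly — this is the pipeline's key
self-check, and it runs in about a second:

```python
import numpy as np
from iispine import (PhantomConfig, generate_phantom, make_oracle_backbone,
                     segment_study, SegmentationConfig, WorkingGrid)

cfg = PhantomConfig(n_vertebrae=7, grid_shape=(32, 192, 96),
                    partial_top_fraction=0.5, seed=3)
volume, mask, meta = generate_phantom(cfg)
seg_cfg = SegmentationConfig(working_grid=WorkingGrid(cfg.spacing),
                             patch_size=(32, 96, 96))
result = segment_study(volume, make_oracle_backbone(mask), seg_cfg)

print(len(result.instances))                               # 7
print(np.array_equal(result.label_map.values, mask.values))  # True
print([i.complete for i in result.instances])
# [True, True, True, True, True, True, False]  <- truncated top vertebra
```

The seven instances come out caudal→cranial; the label map is voxel-identical
to the ground truth; the completeness flag is `False` exactly for the
vertebra cut by the field of view.

Training the small backbone on 24 synthetic phantoms and evaluating the full
iterative pipeline on 6 held-out phantoms (the `desk_experiment` in
`iispine.profiles`, ~12 min on one CPU) produces instance-matched mean Dice
around 0.95 for vertebrae, 0.96–0.99 for IVDs and 0.89–0.99 for the canal
(seed-dependent), with 100 % vertebra detection — numbers the acceptance
script (below) recomputes from scratch on every run.

Command-line equivalents:

```bash
iispine generate-phantoms --n 30 --seed 7 --out cohort/
iispine train --data cohort/ --config cfg.yaml --out run/ --seed 0
iispine segment --input cohort/images/1000_T2.mha --model run/backbone.npz \
                --out pred/1000_T2.mha --config cfg.yaml
iispine evaluate --ref-dir cohort/masks --pred-dir pred/ --out report/
```

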