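# Methods

## The segmentation model

`iispine` segments sagittal lumbar-spine MR volumes into vertebra instances,
their inferior intervertebral discs (IVDs) and the spinal canal, using an
iterative patch-based scheme driven by *instance memory*.

A 3D patch is moved through the volume. Three binary memory volumes record
progress: one for vertebrae, one for IVDs, one for the canal. The vertebra
and IVD memories are fed to the backbone as extra input channels, so the
network's task at every step is well-posed: *segment the lowest vertebra not
yet in memory*, its inferior disc, and any visible part of the canal. The
canal memory is never an input — the canal is an elongated structure no
single patch can cover, so the network always segments every canal voxel it
sees and the per-patch predictions are thresholded and unioned ("stitched")
over all evaluated patches.

One instance is produced per traversal round:

1. **Search.** Patches raster-scan the volume at 50 % stride per axis, with
   the cranio-caudal axis varying slowest and ascending, so the most caudal
   vertebra is found first. A patch "finds" a vertebra when the largest
   face-connected component of its thresholded, memory-excluded vertebra
   prediction exceeds the minimum fragment volume (100 mm³ by default).
2. **Convergence.** The patch re-centers on the fragment's center of mass
   and re-segments, until the fragment volume changes by ≤ 1 % between
   consecutive evaluations and the center moves by ≤ 1 working voxel, with a
   relocation cap of 10. If the cap is hit while consecutive fragments still
   overlap (intersection-over-union ≥ 0.5) the instance is accepted — the
   patch was tracking one jittering vertebra; if consecutive fragments are
   near-disjoint the round fails and is logged, which is the defence against
   a backbone that alternates between two candidates forever.
3. **Commit.** The vertebra fragment, the memory-excluded IVD prediction and
   the canal prediction are unioned into their memories. Memories only ever
   grow. A candidate overlapping the vertebra memory by more than 50 % of its
   own volume is refused (duplicate guard). The *same* patch is then
   re-segmented with the updated memory, which exposes a fragment of the next
   vertebra; when nothing is found the raster resumes where it left off, and
   the run ends when the raster reaches the top of the volume.

Finally the accepted instances are sorted by cranio-caudal centroid and
relabelled bottom-up — label 1 is the most caudal vertebra, deliberately
*not* an anatomical name, because lumbosacral transitional anatomy makes
anatomical labels unreliable without a larger field of view. The label map is
resampled back to the input grid (nearest neighbour).

### Backbone

The backbone contract is a callable mapping (image patch, vertebra-memory
patch, IVD-memory patch) to three probability maps (vertebra, IVD, canal) and
two scalars: a completeness probability (is the vertebra fully inside the
field of view?) and a label value. The label head is trained but never used
at inference; it is retained for parity with the loss definition.

Two implementations ship:

* **`make_oracle_backbone(ground_truth)`** — a perfect backbone derived from
  a reference mask. It emits the lowest vertebra whose in-patch voxels are
  not majority-covered by the vertebra memory, plus its inferior disc and all
  in-patch canal voxels, and completeness 1 iff the vertebra neither touches
  the cranial volume face nor extends beyond the patch. It isolates the
  traversal logic from model quality: with the oracle, the whole pipeline
  must reproduce the ground truth voxel-for-voxel, and the test suite asserts
  exactly that.
* **`SpineUNet`** — a compact three-level 3D U-net written in numpy
  (im2col convolutions + BLAS matmuls, manual backward pass, Adam). An
  additional small compression path branches off the bottleneck via global
  average pooling and predicts the completeness and label scalars. Running
  on plain numpy keeps the package dependency-light and bit-reproducible for
  a fixed seed and thread count; it is fast enough for the desk-scale
  profile below, and the architecture (not the speed) is the point.

### Loss

Per segmentation channel the loss is
`w_fp·FPfrac + w_fn·FNfrac + w_bce·BCE`, where the false-positive fraction is
the soft FP volume divided by the background volume and the false-negative
fraction is the soft FN volume divided by the foreground volume. This
normalisation keeps both terms in [0, 1], makes them insensitive to how much
empty background a patch contains, and gives small structures (discs) the
same gradient weight as large ones. An empty foreground (or background)
contributes 0. Cross-entropies clip probabilities to `[ε, 1−ε]` (ε = 1e-4);
the FP/FN fractions use raw probabilities, so a perfect hard prediction has
zero FP/FN terms and only the ε-floor cross-entropy remains. Added to this
are `w_label·|label_pred − label_true|` and `w_complete·BCE(completeness)`.
Defaults are `w_fp = w_fn = w_bce = 1` and `w_label = w_complete = 0.1`; the
label and completeness heads are auxiliary and down-weighted so they cannot
dominate the segmentation gradient.

### Training samples

For each vertebra `i` of a study (random order), one patch is cut centered on
the vertebra's centroid plus random jitter; the memory channels contain the
ground-truth vertebrae and discs `1..i−1`; the targets are vertebra `i`, disc
`i` and all canal voxels in the patch; the completeness target is 0 iff the
vertebra touches the cranial or caudal volume face. The jitter is deliberately
anisotropic (±2 slices, ±6 in-plane voxels by default in the desk profile) so
the network also sees the off-center patch placements that occur during the
raster search, not only perfectly centered vertebrae — this directly reduces
false-positive canal voxels in the stitched union. Augmentation applies one
spatial transform jointly to image and masks (random elastic deformation,
linear for the image and nearest for masks), plus image-only Gaussian noise
and smoothing, and a longitudinal field-of-view crop that is sampled so it
never removes the targeted vertebra.

## Preprocessing

All volumes are resampled to a fixed working resolution (default
2 × 0.6 × 0.6 mm — thick sagittal slices, fine in-plane grid) with linear
interpolation for images and nearest-neighbour for label masks; resampling is
center-aligned, preserves the physical extent to within one output voxel per
axis, and is an exact identity when the input is already at the working
resolution. Intensities are normalised by a robust z-score: clip to the
[0.5, 99.5] percentile window, subtract the median, divide by IQR/1.349. MR
intensities have no absolute scale, so a scheme of this kind is required for
a trainable network; the robust variant is insensitive to the long tails
that bright CSF produces.

## Synthetic phantoms

The phantom generator provides exact ground truth so every component is
testable without any data download. Each phantom is a stack of 3–9 vertebrae
(superellipsoid bodies, flat along the cranio-caudal axis) with one disc
inferior to each body, a spinal canal tube running the full cranio-caudal
extent with a lordosis-like anterior bow, and a posterior arch enclosing the
canal. The arch is a box-shaped annulus rather than a circular ring: a thin
circular ring fragments into disconnected voxel clusters at 4 mm slice
spacing, while the box annulus stays face-connected at every spacing used
here, and its anterior edge overlaps the body so each vertebra is a single
connected component. Contrast is piecewise-constant tissue values
(T2-like: canal and discs bright, bone dark; T1-like: disc contrast
reversed), blurred with a 0.7-voxel Gaussian to emulate partial-volume
averaging, plus additive Gaussian noise. An optional fraction of the top
vertebra is pushed beyond the cranial volume face, reproducing the common
partially-visible top vertebra, and the per-vertebra completeness flags in
the metadata record it.

What the phantoms do *not* emulate: soft-tissue anatomy outside the spine,
pathology (Modic changes, herniation, stenosis), bias fields, coil profiles,
motion artefacts, and the anatomical variability of real vertebrae. Passing
the desk-scale learning test therefore shows that the architecture, loss,
traversal and evaluation interlock correctly and that the backbone can learn
the task structure — it does not certify performance on clinical MRI.

Cohorts are reproducible: study `k` of a cohort with master seed `s` uses
`numpy.random.default_rng([s, k])` (SeedSequence key mixing), so a cohort can
be regenerated or extended without disturbing existing studies.

## Evaluation protocol

Predicted instances are matched to reference instances of the same structure
kind by largest voxel overlap, greedily and one-to-one, with ties broken on
the lower reference then predicted label. Matching makes every metric
invariant under relabelling of the prediction. Matched pairs are scored
with the 3D Dice coefficient and the average absolute surface distance (ASD):
surface voxels are foreground voxels with at least one 6-connected background
neighbour (the volume boundary counts as background); each surface voxel is
matched to the nearest surface voxel of the other mask in physical mm, and
the distances of both directions are pooled — the symmetric reading of ASD,
chosen because it is symmetric by construction. Degenerate cases are pinned
down: Dice of two empty masks is 1; ASD of an empty mask is undefined and
the instance is reported as undetected instead. Unmatched reference
instances are excluded from the Dice/ASD means and reported through the
separate detection percentage, so a missed instance cannot silently drag the
quality means. Completeness calls are scored per vertebra as accuracy plus
false-positive/false-negative counts. Aggregation (mean, SD, detection %,
completeness accuracy) is per structure and optionally per MRI sequence, and
is exactly recomputable from the per-instance rows.

## Desk-scale profile and problem sizes

The full-scale operating point (64 × 192 × 192 patches at 2 × 0.6 × 0.6 mm)
is what the defaults encode, but the bundled study profile is scaled to a
single CPU: phantoms of 3–5 vertebrae on a 20 × 80 × 56 grid at
4 × 1.5 × 1.5 mm, a 16 × 40 × 40 patch, backbone widths (6, 12, 24), 18
epochs of Adam at 3e-3 with one vertebra-centered sample per vertebra per
epoch (24 training studies ≈ 97 samples/epoch). The oracle-backbone checks
run at the standard working resolution (32 × 192 × 96 grid, 32 × 96 × 96
patch, 3–7 vertebrae). These sizes are the package's chosen study
conditions; everything structural — traversal, memory, loss, evaluation — is
identical to the full-scale path.

## Numerical and design choices

* Probability threshold 0.5 on all three channels; completeness threshold
  0.5. Incomplete instances are kept and flagged, since real studies contain
  partially visible vertebrae.
* Fragment = largest face-connected component of the memory-excluded
  prediction; minimum fragment volume 100 mm³; duplicate-overlap guard 50 %;
  relocation cap 10; volume-stabilisation tolerance 1 %.
* The inferior IVD of an instance is whatever the backbone's IVD channel
  emits in the accepted patch, minus the IVD memory — no geometric pairing
  heuristic is applied on top of the network.
* Canal stitching thresholds per patch and unions; overlapping predictions
  are not averaged.
* After a commit the same patch is re-segmented (rather than restarting the
  raster); the raster resumes only when that patch stops yielding fragments.
* MetaImage axis handling: files are permuted/flipped into the internal
  axis order (slice-normal, caudal→cranial, antero-posterior) using the
  nearest axis-aligned interpretation of the direction cosines; masks are
  written as unsigned 16-bit, images as 32-bit float.
* Label dialect: vertebrae `1..N`, canal 100, IVD of vertebra `i` as
  `200 + i`. The dialect is a configurable mapping, because public datasets
  may encode canal/disc labels differently; point the reader at the actual
  encoding rather than editing code.
* Orientation: "axial-slice orientation" of inputs is realised as the fixed
  internal axis permutation only; no resampling to true axial stacks is
  performed.

## Known limitations

* The numpy backbone trains on a single sample at a time (no batching) and
  a single CPU; it is not intended for full-resolution clinical volumes.
* Training determinism holds for a fixed seed and BLAS thread count; runs
  with different thread counts can differ in the last float digits.
* The greedy largest-overlap matching is the protocol's definition, not a
  globally optimal assignment; with heavily fragmented predictions greedy
  and optimal assignments can differ.
* The phantom's geometric simplicity means metrics on phantoms are far
  better than anything achievable on clinical data; they validate the
  machinery, not clinical accuracy.
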