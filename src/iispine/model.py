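"""Backbone contract, composite loss and the training loop.

The backbone consumes three channels — the image patch plus the vertebra and
IVD memory states — and produces three probability maps (vertebra, IVD,
canal) and two scalars (completeness probability, label value).  The loss has
three parts:

1. segmentation error per channel: a weighted sum of the *false-positive
   fraction* (soft FP volume / background volume) and *false-negative
   fraction* (soft FN volume / foreground volume) combined with binary
   cross-entropy;
2. labelling error: the absolute difference between predicted and true
   bottom-up label;
3. completeness error: binary cross-entropy on the completeness probability.

Normalising FP/FN by background/foreground volume keeps both terms in [0, 1]
and makes the loss insensitive to how much empty background a patch contains.
The label head is trained but never consumed at inference time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import IISpineError
from .iis import BackbonePrediction, PatchSpec, extract_patch
from .nnet import Adam, SpineUNet, sigmoid
from .preprocess import (
    AugmentationConfig,
    WorkingGrid,
    augment,
    normalize_intensity,
    resample_to_working,
)
from .volume_io import LabelVolume, StudyRecord, Volume, read_mha, split_structures

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneSpec",
    "LossWeights",
    "TrainingSample",
    "TrainSchedule",
    "TrainedBackbone",
    "composite_loss",
    "make_training_samples",
    "train",
]

SEG_CHANNELS = ("vertebra", "ivd", "canal")


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture of the trainable backbone.

    ``patch_size`` must be divisible by 4 per axis (two pooling levels).  The
    default mirrors the full-scale operating point; the desk-scale profile
    used in the tests shrinks both patch and widths.
    """

    patch_size: Tuple[int, int, int] = (64, 192, 192)
    widths: Tuple[int, int, int] = (8, 16, 32)
    in_channels: int = 3
    out_channels: int = 3

    def __post_init__(self) -> None:
        if any(s % 4 for s in self.patch_size):
            raise ValueError("patch_size must be divisible by 4 per axis")


@dataclass(frozen=True)
class LossWeights:
    w_fp: float = 1.0
    w_fn: float = 1.0
    w_bce: float = 1.0
    w_label: float = 0.1
    w_complete: float = 0.1
    epsilon: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.w_fp, self.w_fn, self.w_bce, self.w_label, self.w_complete) < 0:
            raise ValueError("loss weights must be non-negative")
        if not 0.0 < self.epsilon < 0.1:
            raise ValueError("epsilon must lie in (0, 0.1)")


@dataclass
class TrainingSample:
    """One supervised patch: inputs, targets and the two scalar labels."""

    image: np.ndarray
    vertebra_memory: np.ndarray
    ivd_memory: np.ndarray
    target_vertebra: np.ndarray
    target_ivd: np.ndarray
    target_canal: np.ndarray
    completeness: int
    label: int

    def input_stack(self) -> np.ndarray:
        return np.stack(
            [
                self.image.astype(np.float32),
                self.vertebra_memory.astype(np.float32),
                self.ivd_memory.astype(np.float32),
            ]
        )


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def _bce(p: np.ndarray, t: np.ndarray, eps: float) -> float:
    pc = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)))


def composite_loss(
    predictions: Dict, targets: Dict, w: LossWeights = LossWeights()
) -> Tuple[float, Dict[str, float]]:
    """Total loss and its per-term breakdown.

    ``predictions`` holds probability maps under the keys ``vertebra``,
    ``ivd``, ``canal`` plus scalars ``completeness`` and ``label``;
    ``targets`` the binary maps and true scalars.  Probabilities are clipped
    to ``[epsilon, 1-epsilon]`` inside the cross-entropy terms; the FP/FN
    fractions use the raw probabilities.  An empty foreground (or background)
    makes the corresponding fraction 0.  The breakdown values sum to the
    total.
    """
    breakdown: Dict[str, float] = {}
    for ch in SEG_CHANNELS:
        p = np.asarray(predictions[ch], dtype=np.float64)
        t = np.asarray(targets[ch], dtype=np.float64)
        if p.shape != t.shape:
            raise ValueError(f"{ch}: prediction shape {p.shape} != target shape {t.shape}")
        fg = float(t.sum())
        bg = float(t.size - fg)
        fp = float((p * (1.0 - t)).sum()) / bg if bg > 0 else 0.0
        fn = float(((1.0 - p) * t).sum()) / fg if fg > 0 else 0.0
        breakdown[f"{ch}_fp"] = w.w_fp * fp
        breakdown[f"{ch}_fn"] = w.w_fn * fn
        breakdown[f"{ch}_bce"] = w.w_bce * _bce(p, t, w.epsilon)
    breakdown["label"] = w.w_label * abs(
        float(predictions["label"]) - float(targets["label"])
    )
    pc = float(np.clip(predictions["completeness"], w.epsilon, 1.0 - w.epsilon))
    tc = float(targets["completeness"])
    breakdown["completeness"] = w.w_complete * float(
        -(tc * np.log(pc) + (1.0 - tc) * np.log(1.0 - pc))
    )
    return float(sum(breakdown.values())), breakdown


def _loss_grads_wrt_logits(
    seg_logits: np.ndarray,
    comp_logit: float,
    label_value: float,
    sample: TrainingSample,
    w: LossWeights,
) -> Tuple[np.ndarray, float, float, float, Dict[str, float]]:
    """Loss + gradients w.r.t. the network's raw outputs (for training)."""
    targets = {
        "vertebra": sample.target_vertebra,
        "ivd": sample.target_ivd,
        "canal": sample.target_canal,
        "completeness": sample.completeness,
        "label": sample.label,
    }
    probs = sigmoid(seg_logits)
    comp_prob = float(sigmoid(np.array([comp_logit]))[0])
    preds = {ch: probs[k] for k, ch in enumerate(SEG_CHANNELS)}
    preds["completeness"] = comp_prob
    preds["label"] = label_value
    total, breakdown = composite_loss(preds, targets, w)

    dseg = np.empty_like(probs)
    n = probs[0].size
    for k, ch in enumerate(SEG_CHANNELS):
        p = probs[k]
        t = np.asarray(targets[ch], dtype=np.float32)
        fg = float(t.sum())
        bg = float(n - fg)
        dp = np.zeros_like(p)
        if bg > 0:
            dp += w.w_fp * (1.0 - t) / bg
        if fg > 0:
            dp -= w.w_fn * t / fg
        dseg[k] = dp * p * (1.0 - p) + w.w_bce * (p - t) / n
    dcomp = w.w_complete * (comp_prob - float(sample.completeness))
    dlabel = w.w_label * float(np.sign(label_value - sample.label))
    return total, dseg, dcomp, dlabel, breakdown


# ---------------------------------------------------------------------------
# Training samples
# ---------------------------------------------------------------------------

def _prepare_study(
    image: Volume, mask: LabelVolume, grid: WorkingGrid
) -> Tuple[Volume, LabelVolume]:
    image = resample_to_working(image, grid)
    mask = resample_to_working(mask, grid)
    return normalize_intensity(image), mask


def make_training_samples(
    study: Tuple[Volume, LabelVolume],
    grid: WorkingGrid,
    patch_size: Tuple[int, int, int],
    aug: Optional[AugmentationConfig],
    rng: np.random.Generator,
    jitter_voxels: Union[int, Tuple[int, int, int]] = 2,
    preprocessed: bool = False,
) -> Iterator[TrainingSample]:
    """Emit one sample per vertebra of a study, in random order.

    The sample for vertebra ``i`` is a patch centered on its centroid (plus
    random jitter); the memory channels contain exactly the ground-truth
    vertebrae and discs caudal to it (1..i-1); the targets are vertebra ``i``,
    its inferior disc and every canal voxel in the patch.  The completeness
    target is 0 when the vertebra touches the cranial or caudal volume face.
    Augmentations are applied jointly; a longitudinal crop is sampled so that
    it never removes the targeted instance (the image outside the kept window
    is blanked, emulating a reduced field of view).
    """
    image, mask = study
    if not preprocessed:
        image, mask = _prepare_study(image, mask, grid)
    groups = split_structures(mask)
    vert = dict(groups["vertebra"])
    ivds = dict(groups["ivd"])
    canal = groups["canal"][0][1] if groups["canal"] else np.zeros(mask.shape, bool)
    n = len(vert)
    n1 = mask.shape[1]

    from scipy import ndimage as _ndi

    for i in (rng.permutation(n) + 1).tolist():
        target_v = vert[i]
        if not target_v.any():  # pragma: no cover - guarded by split_structures
            logger.warning("vertebra %d empty, sample skipped", i)
            continue
        centroid = np.array(_ndi.center_of_mass(target_v))
        j = np.broadcast_to(np.asarray(jitter_voxels, dtype=int), (3,))
        jitter = np.array([int(rng.integers(-a, a + 1)) for a in j])
        center = tuple(
            int(np.clip(round(c + j), 0, s - 1))
            for c, j, s in zip(centroid, jitter, mask.shape)
        )
        spec = PatchSpec(center, tuple(patch_size))
        vmem = np.zeros(mask.shape, dtype=bool)
        imem = np.zeros(mask.shape, dtype=bool)
        for j in range(1, i):
            vmem |= vert[j]
            if j in ivds:
                imem |= ivds[j]
        rows = np.where(target_v.any(axis=(0, 2)))[0]
        complete = int(rows[0] > 0 and rows[-1] < n1 - 1)

        img_p = extract_patch(image.values, spec, pad_value=0.0)
        arrays = [
            extract_patch(vmem, spec, pad_value=False),
            extract_patch(imem, spec, pad_value=False),
            extract_patch(target_v, spec, pad_value=False),
            extract_patch(ivds.get(i, np.zeros(mask.shape, bool)), spec, pad_value=False),
            extract_patch(canal, spec, pad_value=False),
        ]

        if aug is not None and not aug.identity:
            patch_vol = Volume(img_p, grid.spacing)
            mask_vols = [
                LabelVolume(a.astype(np.uint16), grid.spacing, dialect=mask.dialect)
                for a in arrays
            ]
            no_crop = replace(aug, crop_probability=0.0)
            patch_vol, mask_vols = augment(patch_vol, mask_vols, no_crop, rng)
            img_p = patch_vol.values
            arrays = [m.values.astype(bool) for m in mask_vols]
            if aug.crop_probability > 0 and rng.random() < aug.crop_probability:
                # Field-of-view crop that always keeps the targeted vertebra.
                t_rows = np.where(arrays[2].any(axis=(0, 2)))[0]
                if t_rows.size:
                    frac = rng.uniform(*aug.crop_fraction_range)
                    drop = int(frac * patch_size[1])
                    lo_max = min(int(t_rows[0]), drop)
                    lo = int(rng.integers(0, lo_max + 1))
                    hi_drop = min(drop - lo, patch_size[1] - 1 - int(t_rows[-1]))
                    hi = patch_size[1] - hi_drop
                    keep = np.zeros(patch_size[1], dtype=bool)
                    keep[lo:hi] = True
                    img_p = img_p * keep[None, :, None]
                    arrays = [a & keep[None, :, None] for a in arrays]

        yield TrainingSample(
            image=img_p.astype(np.float32),
            vertebra_memory=arrays[0],
            ivd_memory=arrays[1],
            target_vertebra=arrays[2],
            target_ivd=arrays[3],
            target_canal=arrays[4],
            completeness=complete,
            label=i,
        )


# ---------------------------------------------------------------------------
# Trained backbone adapter + training loop
# ---------------------------------------------------------------------------

class TrainedBackbone:
    """Adapter making a :class:`SpineUNet` usable by the traversal engine."""

    def __init__(self, net: SpineUNet, spec: BackboneSpec):
        self.net = net
        self.spec = spec

    def __call__(self, image_patch, vmem_patch, imem_patch, patch_spec=None
                 ) -> BackbonePrediction:
        x = np.stack(
            [
                image_patch.astype(np.float32),
                vmem_patch.astype(np.float32),
                imem_patch.astype(np.float32),
            ]
        )
        seg, comp_logit, label_value = self.net.forward(x)
        probs = sigmoid(seg)
        return BackbonePrediction(
            vertebra=probs[0],
            ivd=probs[1],
            canal=probs[2],
            completeness=float(sigmoid(np.array([comp_logit]))[0]),
            label_value=float(label_value),
        )

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(
            path,
            _spec=json.dumps(asdict(self.spec)),
            **self.net.state_dict(),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedBackbone":
        data = np.load(path, allow_pickle=False)
        spec_dict = json.loads(str(data["_spec"]))
        spec = BackboneSpec(
            patch_size=tuple(spec_dict["patch_size"]),
            widths=tuple(spec_dict["widths"]),
        )
        net = SpineUNet(in_channels=spec.in_channels, widths=spec.widths)
        net.load_state_dict({k: data[k] for k in data.files if k != "_spec"})
        return cls(net, spec)


@dataclass(frozen=True)
class TrainSchedule:
    """Optimisation settings; defaults are the desk-scale profile."""

    epochs: int = 12
    learning_rate: float = 3e-3
    augmentation: AugmentationConfig = AugmentationConfig()
    jitter_voxels: Union[int, Tuple[int, int, int]] = 2


StudyLike = Union[StudyRecord, Tuple[Volume, LabelVolume, str]]


def _load_study(item: StudyLike) -> Tuple[Volume, LabelVolume, str]:
    if isinstance(item, StudyRecord):
        image = read_mha(item.image_path)
        mask = read_mha(item.mask_path)
        return image, mask, item.split
    image, mask, split = item
    return image, mask, split


def _patch_dice(p: np.ndarray, t: np.ndarray) -> float:
    a = p >= 0.5
    b = t.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def train(
    cohort: Sequence[StudyLike],
    spec: BackboneSpec = BackboneSpec(),
    weights: LossWeights = LossWeights(),
    schedule: TrainSchedule = TrainSchedule(),
    seed: int = 0,
    grid: WorkingGrid = WorkingGrid(),
) -> Tuple[TrainedBackbone, List[Dict]]:
    """Train the backbone on a cohort with train/validation splits.

    One optimisation step per training sample (one vertebra-centered patch),
    Adam, fixed seed → deterministic run.  Per epoch the log records the mean
    loss breakdown and the validation Dice per channel (on patches centered on
    the ground-truth instances, without augmentation); the returned backbone
    carries the parameters of the epoch with the best validation vertebra
    Dice.
    """
    items = [_load_study(it) for it in cohort]
    train_set = [(im, mk) for im, mk, sp in items if sp == "train"]
    val_set = [(im, mk) for im, mk, sp in items if sp == "validation"]
    if not train_set:
        raise IISpineError("training split is empty")

    train_set = [_prepare_study(im, mk, grid) for im, mk in train_set]
    val_set = [_prepare_study(im, mk, grid) for im, mk in val_set]

    rng = np.random.default_rng(seed)
    net = SpineUNet(in_channels=spec.in_channels, widths=spec.widths,
                    seed=int(rng.integers(2**31 - 1)))
    opt = Adam(net.params, lr=schedule.learning_rate)

    log: List[Dict] = []
    best_state = net.state_dict()
    best_val = -1.0
    for epoch in range(schedule.epochs):
        order = rng.permutation(len(train_set))
        sums: Dict[str, float] = {}
        count = 0
        for si in order:
            for sample in make_training_samples(
                train_set[si], grid, spec.patch_size, schedule.augmentation, rng,
                jitter_voxels=schedule.jitter_voxels, preprocessed=True,
            ):
                cache: Dict = {}
                seg, comp, lab = net.forward(sample.input_stack(), cache)
                total, dseg, dcomp, dlabel, breakdown = _loss_grads_wrt_logits(
                    seg, comp, lab, sample, weights
                )
                grads = net.backward(dseg, dcomp, dlabel, cache)
                opt.step(grads)
                for k, v in breakdown.items():
                    sums[k] = sums.get(k, 0.0) + v
                sums["total"] = sums.get("total", 0.0) + total
                count += 1

        entry: Dict = {"epoch": epoch, "n_samples": count}
        entry.update({f"loss_{k}": v / max(count, 1) for k, v in sums.items()})

        if val_set:
            val_rng = np.random.default_rng(seed + 10_000 + epoch)
            dices = {ch: [] for ch in SEG_CHANNELS}
            for study in val_set:
                for sample in make_training_samples(
                    study, grid, spec.patch_size, None, val_rng,
                    jitter_voxels=0, preprocessed=True,
                ):
                    seg, _, _ = net.forward(sample.input_stack())
                    probs = sigmoid(seg)
                    dices["vertebra"].append(_patch_dice(probs[0], sample.target_vertebra))
                    dices["ivd"].append(_patch_dice(probs[1], sample.target_ivd))
                    dices["canal"].append(_patch_dice(probs[2], sample.target_canal))
            for ch in SEG_CHANNELS:
                entry[f"val_dice_{ch}"] = float(np.mean(dices[ch])) if dices[ch] else float("nan")
            if entry["val_dice_vertebra"] >= best_val:
                best_val = entry["val_dice_vertebra"]
                best_state = net.state_dict()
        else:
            best_state = net.state_dict()
        log.append(entry)
        logger.info("epoch %d: %s", epoch, {k: round(v, 4) for k, v in entry.items()
                                            if isinstance(v, float)})

    net.load_state_dict(best_state)
    return TrainedBackbone(net, spec), log
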