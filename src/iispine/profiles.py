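"""Desk-scale study profile: small phantoms, patch and backbone.

The full-scale operating point (patch 64 × 192 × 192 at 2 × 0.6 × 0.6 mm,
GPU-trained) is not something a laptop-class CPU run should attempt.  This
module pins a reduced but structurally faithful profile used by the test
suite and the reproduction script: coarser phantoms (4 × 1.5 × 1.5 mm),
a 16 × 40 × 40 patch and a narrow backbone.  Everything else — the traversal,
memory mechanics, loss and evaluation — is identical to the full-scale path.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Tuple

import numpy as np

from .iis import SegmentationConfig
from .model import BackboneSpec, TrainSchedule
from .phantom import PhantomConfig, generate_phantom
from .preprocess import AugmentationConfig, WorkingGrid
from .volume_io import LabelVolume, Volume

__all__ = [
    "DESK_SPACING",
    "DESK_PHANTOM",
    "DESK_BACKBONE",
    "DESK_SCHEDULE",
    "desk_segmentation_config",
    "desk_cohort",
    "ORACLE_PHANTOM",
    "oracle_cohort",
    "oracle_segmentation_config",
    "desk_experiment",
]

DESK_SPACING: Tuple[float, float, float] = (4.0, 1.5, 1.5)

#: Phantom geometry sized so 3–5 vertebrae fit the coarse grid.
DESK_PHANTOM = PhantomConfig(
    n_vertebrae=4,
    grid_shape=(20, 80, 56),
    spacing=DESK_SPACING,
    vertebra_size=14.0,
    disc_thickness=4.0,
    canal_radius=4.0,
    curvature=3.0,
    noise_sd=0.02,
)

DESK_BACKBONE = BackboneSpec(patch_size=(16, 40, 40), widths=(6, 12, 24))

#: Mild augmentation: geometry must remain a valid match to the ground truth.
#: The anisotropic jitter (±2 slices, ±6 in-plane voxels) exposes the backbone
#: to the off-center patch placements of the inference raster, which keeps the
#: stitched canal union free of out-of-distribution false positives.
DESK_SCHEDULE = TrainSchedule(
    epochs=18,
    learning_rate=3e-3,
    augmentation=AugmentationConfig(
        elastic_probability=0.3,
        elastic_sd_mm=1.5,
        noise_probability=0.5,
        smoothing_probability=0.3,
        crop_probability=0.25,
    ),
    jitter_voxels=(2, 6, 6),
)


def desk_segmentation_config() -> SegmentationConfig:
    return SegmentationConfig(
        working_grid=WorkingGrid(DESK_SPACING),
        patch_size=DESK_BACKBONE.patch_size,
    )


def desk_cohort(
    n_studies: int,
    seed: int,
    n_range: Tuple[int, int] = (3, 5),
    partial_top_probability: float = 0.5,
    splits: Tuple[int, int] = (0, 0),
) -> List[Tuple[Volume, LabelVolume, str, Dict]]:
    """In-memory phantom cohort at the desk profile.

    Returns ``(image, mask, split, metadata)`` per study (T2-like contrast).
    Per-study seeds mix the master seed with the study index through
    ``np.random.default_rng([seed, index])``, the same rule the on-disk cohort
    writer uses.  ``splits=(n_train, n_val)`` assigns splits in order.
    """
    out = []
    n_train, n_val = splits
    for idx in range(n_studies):
        rng = np.random.default_rng([seed, idx])
        study_seed = int(rng.integers(2**31 - 1))
        n_vert = int(rng.integers(n_range[0], n_range[1] + 1))
        f = float(rng.uniform(0.2, 0.6)) if rng.random() < partial_top_probability else 0.0
        cfg = replace(
            DESK_PHANTOM, n_vertebrae=n_vert, partial_top_fraction=f, seed=study_seed
        )
        image, mask, meta = generate_phantom(cfg)
        split = "train" if idx < n_train else "validation" if idx < n_train + n_val else "none"
        out.append((image, mask, split, meta))
    return out


# ---------------------------------------------------------------------------
# Working-resolution oracle profile
# ---------------------------------------------------------------------------

#: Phantom at the standard working resolution, tall enough for 7 vertebrae.
ORACLE_PHANTOM = PhantomConfig(
    n_vertebrae=5,
    grid_shape=(32, 192, 96),
    spacing=(2.0, 0.6, 0.6),
)


def oracle_segmentation_config() -> SegmentationConfig:
    return SegmentationConfig(
        working_grid=WorkingGrid(ORACLE_PHANTOM.spacing), patch_size=(32, 96, 96)
    )


def oracle_cohort(
    n_studies: int,
    seed: int,
    n_range: Tuple[int, int] = (3, 7),
    partial_top_probability: float = 0.5,
) -> List[Tuple[Volume, LabelVolume, Dict]]:
    """Phantoms at the standard working resolution for oracle-backbone runs."""
    out = []
    for idx in range(n_studies):
        rng = np.random.default_rng([seed, idx])
        study_seed = int(rng.integers(2**31 - 1))
        n_vert = int(rng.integers(n_range[0], n_range[1] + 1))
        f = float(rng.uniform(0.2, 0.6)) if rng.random() < partial_top_probability else 0.0
        cfg = replace(
            ORACLE_PHANTOM, n_vertebrae=n_vert, partial_top_fraction=f, seed=study_seed
        )
        out.append(generate_phantom(cfg))
    return out


def desk_experiment(seed: int = 1, train_seed: int = 0) -> Dict[str, float]:
    """The desk-scale learning study: train on 24 phantoms, validate on 6.

    Trains the small backbone on the desk cohort, then runs the full iterative
    traversal on the 6 held-out phantoms and scores it with the
    instance-matched protocol.  Returns the headline numbers (mean Dice per
    structure, vertebra detection %, completeness accuracy %).
    """
    from .evaluate import aggregate, evaluate_study
    from .iis import segment_study
    from .model import train

    cohort = desk_cohort(30, seed=seed, splits=(24, 6))
    studies = [(im, mk, sp) for im, mk, sp, _ in cohort]
    backbone, log = train(
        studies,
        spec=DESK_BACKBONE,
        schedule=DESK_SCHEDULE,
        seed=train_seed,
        grid=WorkingGrid(DESK_SPACING),
    )
    rows = []
    cfg = desk_segmentation_config()
    for image, mask, split, meta in cohort:
        if split != "validation":
            continue
        result = segment_study(image, backbone, cfg)
        comp = {i.label_index: i.complete for i in result.instances}
        rows.extend(
            evaluate_study(
                mask,
                result.label_map,
                sequence="T2",
                completeness_predictions=comp,
                reference_completeness=meta["complete"],
            )
        )
    table = aggregate(rows, "structure").set_index("structure")
    return {
        "vertebra_dice_mean": float(table.loc["vertebra", "dice_mean"]),
        "ivd_dice_mean": float(table.loc["ivd", "dice_mean"]),
        "canal_dice_mean": float(table.loc["canal", "dice_mean"]),
        "vertebra_detection_pct": float(table.loc["vertebra", "detection_pct"]),
        "ivd_detection_pct": float(table.loc["ivd", "detection_pct"]),
        "canal_detection_pct": float(table.loc["canal", "detection_pct"]),
        "completeness_accuracy_pct": float(
            table.loc["vertebra", "completeness_accuracy_pct"]
        ),
        "n_validation_studies": 6,
        "final_train_loss": float(log[-1]["loss_total"]),
    }
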