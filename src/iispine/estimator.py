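"""Scikit-learn style estimator wrapping training and iterative inference."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator

from .evaluate import aggregate, evaluate_study
from .iis import SegmentationConfig, segment_study
from .model import (
    BackboneSpec,
    LossWeights,
    StudyLike,
    TrainSchedule,
    _load_study,
    train,
)
from .preprocess import AugmentationConfig, WorkingGrid
from .volume_io import Volume

__all__ = ["IterativeInstanceSegmenter"]


class IterativeInstanceSegmenter(BaseEstimator):
    """Iterative patch-based instance segmenter for lumbar spine MRI.

    ``fit`` trains the backbone on a cohort of (image, mask) studies with
    train/validation splits; ``predict`` runs the memory-driven traversal on a
    raw volume and returns a :class:`SegmentationResult` whose label map uses
    the bottom-up instance convention.  All constructor arguments are plain
    hyperparameters in the scikit-learn sense (``get_params``/``set_params``
    compatible).

    Parameters
    ----------
    patch_size : per-axis patch extent in working-grid voxels (divisible by 4).
    widths : channel widths of the three U-net levels.
    working_spacing : voxel size (mm) of the working grid.
    epochs, learning_rate : optimisation schedule.
    loss_weights : :class:`LossWeights`, or None for the defaults.
    augmentation : :class:`AugmentationConfig`, or None for the defaults.
    threshold : probability threshold of the three segmentation channels.
    min_fragment_volume : minimum fragment volume (mm³) to accept a detection.
    relocation_cap : maximum patch relocations per instance.
    seed : seed for initialisation, sampling and augmentation.
    """

    def __init__(
        self,
        patch_size: Tuple[int, int, int] = (64, 192, 192),
        widths: Tuple[int, int, int] = (8, 16, 32),
        working_spacing: Tuple[float, float, float] = (2.0, 0.6, 0.6),
        epochs: int = 12,
        learning_rate: float = 3e-3,
        loss_weights: Optional[LossWeights] = None,
        augmentation: Optional[AugmentationConfig] = None,
        threshold: float = 0.5,
        volume_tolerance: float = 0.01,
        relocation_cap: int = 10,
        min_fragment_volume: float = 100.0,
        jitter_voxels: int = 2,
        seed: int = 0,
    ):
        self.patch_size = patch_size
        self.widths = widths
        self.working_spacing = working_spacing
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.loss_weights = loss_weights
        self.augmentation = augmentation
        self.threshold = threshold
        self.volume_tolerance = volume_tolerance
        self.relocation_cap = relocation_cap
        self.min_fragment_volume = min_fragment_volume
        self.jitter_voxels = jitter_voxels
        self.seed = seed

    # -- sklearn plumbing ---------------------------------------------------

    def _segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            working_grid=WorkingGrid(tuple(self.working_spacing)),
            patch_size=tuple(self.patch_size),
            threshold=self.threshold,
            volume_tolerance=self.volume_tolerance,
            relocation_cap=self.relocation_cap,
            min_fragment_volume_mm3=self.min_fragment_volume,
        )

    def fit(self, X: Sequence[StudyLike], y=None) -> "IterativeInstanceSegmenter":
        """Train on a cohort of studies (StudyRecords or (image, mask, split))."""
        spec = BackboneSpec(patch_size=tuple(self.patch_size), widths=tuple(self.widths))
        schedule = TrainSchedule(
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            augmentation=self.augmentation or AugmentationConfig(),
            jitter_voxels=self.jitter_voxels,
        )
        backbone, log = train(
            X,
            spec=spec,
            weights=self.loss_weights or LossWeights(),
            schedule=schedule,
            seed=self.seed,
            grid=WorkingGrid(tuple(self.working_spacing)),
        )
        self.backbone_ = backbone
        self.training_log_ = log
        self.n_studies_ = len(X)
        return self

    def predict(self, X: Union[Volume, Sequence[Volume]]):
        """Segment one volume (→ SegmentationResult) or a sequence of them."""
        if not hasattr(self, "backbone_"):
            raise AttributeError("this IterativeInstanceSegmenter is not fitted yet")
        cfg = self._segmentation_config()
        if isinstance(X, Volume):
            return segment_study(X, self.backbone_, cfg)
        return [segment_study(v, self.backbone_, cfg) for v in X]

    def score(self, X: Sequence[StudyLike], y=None) -> float:
        """Mean vertebra Dice over detected vertebrae of held-out studies."""
        rows = []
        for item in X:
            image, mask, _ = _load_study(item)
            result = self.predict(image)
            rows.extend(evaluate_study(mask, result.label_map))
        table = aggregate(rows, grouping="structure")
        vert = table[table["structure"] == "vertebra"]
        return float(vert["dice_mean"].iloc[0])
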