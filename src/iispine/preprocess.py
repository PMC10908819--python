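"""Resampling to the working grid, intensity normalisation, augmentation.

The working resolution is 2 × 0.6 × 0.6 mm by default: thick sagittal slices
along axis 0 and high in-plane resolution, matching the anisotropy of routine
lumbar MRI.  Images are interpolated linearly, label masks nearest-neighbour
(which can never invent label values).  Resampling is center-aligned, so the
physical extent is preserved to within one output voxel per axis, and it is an
exact identity on inputs already at the working resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, Volume

__all__ = [
    "WorkingGrid",
    "AugmentationConfig",
    "resample_to_working",
    "normalize_intensity",
    "augment",
]


@dataclass(frozen=True)
class WorkingGrid:
    """The fixed voxel grid all volumes are brought to before inference."""

    spacing: Tuple[float, float, float] = (2.0, 0.6, 0.6)

    def __post_init__(self) -> None:
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")


@dataclass(frozen=True)
class AugmentationConfig:
    """Training-time augmentation: one joint spatial transform per sample.

    ``elastic_*`` parameterise a smooth random displacement field (control
    grid spacing and per-control-point displacement SD, both mm); noise and
    smoothing apply to the image only; ``crop_fraction_range`` trims a random
    fraction off the longitudinal (cranio-caudal) axis, emulating a reduced
    field of view.  All magnitudes default mild so instance ground truth stays
    valid under the transform.
    """

    elastic_grid_mm: float = 32.0
    elastic_sd_mm: float = 2.0
    elastic_probability: float = 0.5
    noise_sd_range: Tuple[float, float] = (0.0, 0.1)
    smoothing_sigma_range_mm: Tuple[float, float] = (0.0, 1.0)
    crop_fraction_range: Tuple[float, float] = (0.0, 0.25)
    crop_probability: float = 0.0
    noise_probability: float = 0.5
    smoothing_probability: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.elastic_probability, self.crop_probability,
                  self.noise_probability, self.smoothing_probability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def identity(self) -> bool:
        return (
            self.elastic_probability == 0
            and self.crop_probability == 0
            and self.noise_probability == 0
            and self.smoothing_probability == 0
        )


def _resample_array(
    values: np.ndarray,
    in_spacing: Tuple[float, ...],
    out_spacing: Tuple[float, ...],
    order: int,
) -> np.ndarray:
    in_spacing = np.asarray(in_spacing, dtype=float)
    out_spacing = np.asarray(out_spacing, dtype=float)
    if np.allclose(in_spacing, out_spacing):
        return values.copy()
    in_shape = np.array(values.shape)
    out_shape = np.maximum(np.rint(in_shape * in_spacing / out_spacing).astype(int), 1)
    # Center-aligned sampling: output voxel j center -> input coordinate.
    coords = [
        (np.arange(n) + 0.5) * out_spacing[a] / in_spacing[a] - 0.5
        for a, n in enumerate(out_shape)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(
        values.astype(np.float32 if order > 0 else values.dtype),
        np.stack(grid),
        order=order,
        mode="nearest",
    )


def resample_to_working(
    v: Union[Volume, LabelVolume], grid: WorkingGrid = WorkingGrid()
) -> Union[Volume, LabelVolume]:
    """Resample to ``grid.spacing``: linear for images, nearest for labels."""
    if min(v.shape) < 2 and not np.allclose(v.spacing, grid.spacing):
        raise ValueError("cannot resample a volume with a single-voxel axis")
    if isinstance(v, LabelVolume):
        out = _resample_array(v.values, v.spacing, grid.spacing, order=0)
        return LabelVolume(out.astype(v.values.dtype), grid.spacing, v.origin, dialect=v.dialect)
    out = _resample_array(v.values, v.spacing, grid.spacing, order=1)
    return Volume(out.astype(np.float32), grid.spacing, v.origin)


def normalize_intensity(v: Volume) -> Volume:
    """Robust z-score: clip to the [0.5, 99.5] percentile window, subtract the
    median, divide by the IQR-derived scale (IQR/1.349 ≈ SD for a Gaussian).

    A constant volume maps to all zeros.  The output has median ≈ 0 and is a
    fixed point of the operation up to the percentile clipping.
    """
    x = v.values.astype(np.float32)
    lo, hi = np.percentile(x, [0.5, 99.5])
    x = np.clip(x, lo, hi)
    med = np.median(x)
    q1, q3 = np.percentile(x, [25, 75])
    scale = (q3 - q1) / 1.349
    if scale <= 0:
        scale = x.std()
    if scale <= 0:
        return Volume(np.zeros_like(x), v.spacing, v.origin)
    return Volume(((x - med) / scale).astype(np.float32), v.spacing, v.origin)


def _elastic_field(
    shape: Tuple[int, ...],
    spacing: Tuple[float, ...],
    grid_mm: float,
    sd_mm: float,
    rng: np.random.Generator,
) -> List[np.ndarray]:
    """Smooth per-axis displacement fields (in voxels) from a coarse grid."""
    fields = []
    ctrl_shape = [max(int(np.ceil(n * s / grid_mm)) + 1, 2) for n, s in zip(shape, spacing)]
    for axis in range(3):
        ctrl = rng.normal(0.0, sd_mm, size=ctrl_shape)
        zoom = [n / c for n, c in zip(shape, ctrl_shape)]
        disp_mm = ndimage.zoom(ctrl, zoom, order=3, mode="nearest", grid_mode=True)
        fields.append(disp_mm / spacing[axis])
    return fields


def augment(
    patch: Volume,
    masks: List[LabelVolume],
    cfg: AugmentationConfig,
    rng: np.random.Generator,
) -> Tuple[Volume, List[LabelVolume]]:
    """Apply one augmentation draw jointly to an image and its masks.

    The same spatial transform (elastic warp, longitudinal crop) is applied to
    the image (linear) and every mask (nearest); Gaussian noise and smoothing
    touch the image only.  With all probabilities zero the input is returned
    unchanged.  The ``rng`` state fully determines the output.
    """
    for m in masks:
        if m.shape != patch.shape:
            raise ValueError("image and masks must share a grid")
    if cfg.identity:
        return patch, masks

    image = patch.values.astype(np.float32)
    label_arrays = [m.values for m in masks]

    if cfg.elastic_probability > 0 and rng.random() < cfg.elastic_probability:
        disp = _elastic_field(image.shape, patch.spacing, cfg.elastic_grid_mm,
                              cfg.elastic_sd_mm, rng)
        base = np.meshgrid(*[np.arange(n, dtype=np.float32) for n in image.shape],
                           indexing="ij")
        coords = np.stack([b + d for b, d in zip(base, disp)])
        image = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
        label_arrays = [
            ndimage.map_coordinates(la, coords, order=0, mode="nearest")
            for la in label_arrays
        ]

    if cfg.crop_probability > 0 and rng.random() < cfg.crop_probability:
        frac = rng.uniform(*cfg.crop_fraction_range)
        n1 = image.shape[1]
        drop = int(frac * n1)
        if drop > 0:
            lo = int(rng.integers(0, drop + 1))
            hi = n1 - (drop - lo)
            image = image[:, lo:hi]
            label_arrays = [la[:, lo:hi] for la in label_arrays]

    if cfg.smoothing_probability > 0 and rng.random() < cfg.smoothing_probability:
        sigma_mm = rng.uniform(*cfg.smoothing_sigma_range_mm)
        if sigma_mm > 0:
            image = ndimage.gaussian_filter(
                image, sigma=[sigma_mm / s for s in patch.spacing]
            )

    if cfg.noise_probability > 0 and rng.random() < cfg.noise_probability:
        sd = rng.uniform(*cfg.noise_sd_range)
        if sd > 0:
            image = image + rng.normal(0.0, sd, size=image.shape).astype(np.float32)

    out_image = Volume(image.astype(np.float32), patch.spacing, patch.origin)
    out_masks = [
        LabelVolume(la.astype(m.values.dtype), patch.spacing, m.origin, dialect=m.dialect)
        for la, m in zip(label_arrays, masks)
    ]
    return out_image, out_masks
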