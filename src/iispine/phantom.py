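"""Synthetic sagittal lumbar-spine phantoms with exact instance ground truth.

The generator produces MR-like volumes containing a stack of vertebra bodies
with posterior arches, one intervertebral disc inferior to every vertebra, and
a single spinal canal running the full cranio-caudal extent.  Geometry is
deliberately simple — a superellipsoid body plus an annular arch segment — the
purpose is to exercise the iterative traversal and the evaluation protocol
with known ground truth, not anatomical realism.  The arch matters because the
canal must be enclosed posteriorly, so a patch sees vertebra and canal voxels
together, as in real sagittal lumbar MRI.

Contrast follows the two clinically familiar spin-echo appearances:

* ``T2-like`` — cerebrospinal fluid (canal) and healthy discs bright, bone dark;
* ``T1-like`` — bone brighter than discs, CSF dark (reversed disc contrast).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PhantomConfigError
from .volume_io import (
    DEFAULT_DIALECT,
    LabelDialect,
    LabelVolume,
    StudyRecord,
    Volume,
    write_mha,
)

logger = logging.getLogger(__name__)

__all__ = ["PhantomConfig", "generate_phantom", "generate_cohort"]

#: Piecewise-constant tissue intensities before smoothing/noise, by contrast.
TISSUE_VALUES = {
    "T2-like": {"background": 0.15, "vertebra": 0.35, "ivd": 0.75, "canal": 0.90},
    "T1-like": {"background": 0.15, "vertebra": 0.55, "ivd": 0.25, "canal": 0.30},
}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, contrast and noise settings of one phantom.

    Sizes are in mm on the internal axis convention (axis 0 slice-normal /
    left-right, axis 1 caudal→cranial, axis 2 antero-posterior).
    ``vertebra_size`` is the cranio-caudal height of a vertebral body;
    ``curvature`` the lordosis amplitude of the anterior bulge;
    ``partial_top_fraction`` the fraction of the most cranial vertebra pushed
    beyond the top of the field of view (0 = fully visible).
    """

    n_vertebrae: int = 5
    grid_shape: Tuple[int, int, int] = (64, 128, 128)
    spacing: Tuple[float, float, float] = (2.0, 0.6, 0.6)
    vertebra_size: float = 10.0
    disc_thickness: float = 3.0
    canal_radius: float = 4.0
    curvature: float = 3.0
    contrast: str = "T2-like"
    noise_sd: float = 0.02
    partial_top_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= self.n_vertebrae <= 9:
            raise PhantomConfigError(f"n_vertebrae must be in [3, 9], got {self.n_vertebrae}")
        if not 0.0 <= self.partial_top_fraction < 1.0:
            raise PhantomConfigError("partial_top_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise PhantomConfigError("noise_sd must be >= 0")
        if min(self.vertebra_size, self.disc_thickness, self.canal_radius) <= 0:
            raise PhantomConfigError("all sizes must be positive")
        if any(s <= 0 for s in self.spacing) or any(n < 1 for n in self.grid_shape):
            raise PhantomConfigError("invalid grid")
        if self.contrast not in TISSUE_VALUES:
            raise PhantomConfigError(f"contrast must be one of {sorted(TISSUE_VALUES)}")


def _vertebra_centers(cfg: PhantomConfig) -> np.ndarray:
    """Cranio-caudal body-center positions (mm), bottom-up, or raise if unfit."""
    vs, dt, n = cfg.vertebra_size, cfg.disc_thickness, cfg.n_vertebrae
    extent1 = cfg.grid_shape[1] * cfg.spacing[1]
    unit = vs + dt
    margin = 2.0
    if cfg.partial_top_fraction > 0:
        top_center = extent1 - vs / 2 + cfg.partial_top_fraction * vs
        centers = top_center - unit * np.arange(n - 1, -1, -1)
        if centers[0] - vs / 2 - dt < 0:
            raise PhantomConfigError(
                f"{n} vertebrae of {vs} mm (+{dt} mm discs) do not fit the "
                f"{extent1:.1f} mm cranio-caudal extent with the requested truncation"
            )
    else:
        first = margin + dt + vs / 2
        centers = first + unit * np.arange(n)
        if centers[-1] + vs / 2 + margin > extent1:
            raise PhantomConfigError(
                f"{n} vertebrae of {vs} mm (+{dt} mm discs) do not fit the "
                f"{extent1:.1f} mm cranio-caudal extent"
            )
    return centers


def generate_phantom(
    config: PhantomConfig,
    dialect: LabelDialect = DEFAULT_DIALECT,
) -> Tuple[Volume, LabelVolume, Dict]:
    """Generate one phantom → ``(image, ground-truth mask, metadata)``.

    The mask encodes vertebrae bottom-up as ``1..n``, the canal and the IVDs
    per ``dialect``.  Metadata records, per vertebra, whether it is complete
    (i.e. not cut by the cranial or caudal volume face).  Identical configs
    give bit-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n0, n1, n2 = cfg.grid_shape
    s0, s1, s2 = cfg.spacing
    vs = cfg.vertebra_size

    # Physical voxel-center coordinates, broadcastable to the full grid.
    x0 = ((np.arange(n0) + 0.5) * s0)[:, None, None]
    x1 = ((np.arange(n1) + 0.5) * s1)[None, :, None]
    x2 = ((np.arange(n2) + 0.5) * s2)[None, None, :]

    centers1 = _vertebra_centers(cfg)
    spine_lo = centers1[0] - vs / 2 - cfg.disc_thickness
    spine_hi = centers1[-1] + vs / 2
    u = np.clip((x1 - spine_lo) / max(spine_hi - spine_lo, 1e-6), 0.0, 1.0)

    # Body semi-axes and arch dimensions scale with the vertebra size.
    a0, a1, a2 = 1.3 * vs, vs / 2, 0.8 * vs
    wall = 0.25 * vs
    ring_gap = 0.5
    canal_offset = a2 + cfg.canal_radius + ring_gap + wall - 1.0
    c0 = n0 * s0 / 2
    c2_base = 2.0 + a2 + cfg.curvature
    c2 = c2_base + cfg.curvature * (1.0 - np.sin(np.pi * u))  # lordosis-like bow
    c2_canal = c2 + canal_offset

    extent2 = n2 * s2
    if c2_canal.max() + cfg.canal_radius + ring_gap + wall + 1.0 > extent2:
        raise PhantomConfigError(
            "antero-posterior grid extent too small for body + arch + canal"
        )
    if a0 + 1.0 > n0 * s0 / 2:
        raise PhantomConfigError("slice-normal grid extent too small for the vertebra width")

    labels = np.zeros(cfg.grid_shape, dtype=np.uint16)

    # Spinal canal: full-extent tube, painted first.
    r_canal = np.sqrt((x0 - c0) ** 2 + (x2 - c2_canal) ** 2)
    canal = r_canal <= cfg.canal_radius
    labels[canal] = dialect.canal

    # The arch is a box-shaped annulus around the canal (a square ring is
    # robustly face-connected at coarse slice spacing, where a thin circular
    # ring fragments); its anterior edge overlaps the body posteriorly, so
    # body and arch form one connected vertebra.
    r_out = cfg.canal_radius + ring_gap + wall
    arch_box = (
        (np.abs(x0 - c0) <= r_out)
        & (np.abs(x2 - c2_canal) <= r_out)
        & (r_canal >= cfg.canal_radius + ring_gap)
    )
    for i, cy in enumerate(centers1, start=1):
        d1 = x1 - cy
        body = ((x0 - c0) / a0) ** 2 + ((x2 - c2) / a2) ** 2 + (d1 / a1) ** 6 <= 1.0
        arch = arch_box & (np.abs(d1) <= 0.35 * vs)
        vert = (body | arch) & (labels == 0)
        labels[vert] = dialect.vertebra(i)

    for i, cy in enumerate(centers1, start=1):
        dlo = cy - vs / 2 - cfg.disc_thickness
        disc = (
            (((x0 - c0) / (0.85 * a0)) ** 2 + ((x2 - c2) / (0.85 * a2)) ** 2 <= 1.0)
            & (x1 >= dlo)
            & (x1 <= dlo + cfg.disc_thickness)
            & (labels == 0)
        )
        labels[disc] = dialect.ivd(i)

    complete: Dict[int, bool] = {}
    for i in range(1, cfg.n_vertebrae + 1):
        m = labels == dialect.vertebra(i)
        if not m.any():
            raise PhantomConfigError(
                f"vertebra {i} has no voxels on this grid (truncation too aggressive?)"
            )
        rows = np.where(m.any(axis=(0, 2)))[0]
        complete[i] = bool(rows[0] > 0 and rows[-1] < n1 - 1)

    tissues = TISSUE_VALUES[cfg.contrast]
    image = np.full(cfg.grid_shape, tissues["background"], dtype=np.float32)
    image[(labels >= 1) & (labels <= dialect.max_vertebrae)] = tissues["vertebra"]
    image[labels == dialect.canal] = tissues["canal"]
    image[labels > dialect.ivd_offset] = tissues["ivd"]
    image = ndimage.gaussian_filter(image, sigma=0.7)  # partial-volume blur
    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd, size=image.shape).astype(np.float32)

    volume = Volume(image.astype(np.float32), cfg.spacing)
    mask = LabelVolume(labels, cfg.spacing, dialect=dialect)
    metadata = {
        "n_vertebrae": cfg.n_vertebrae,
        "complete": complete,
        "contrast": cfg.contrast,
        "seed": cfg.seed,
    }
    return volume, mask, metadata


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def _draw_config(base: PhantomConfig, ranges: Dict, rng: np.random.Generator, seed: int) -> PhantomConfig:
    """Draw one config from ``ranges``; integers uniform inclusive, floats uniform."""
    kwargs = {"seed": seed}
    for name, rng_spec in ranges.items():
        if isinstance(rng_spec, (list, tuple)) and len(rng_spec) == 2 and all(
            isinstance(v, (int, float)) for v in rng_spec
        ):
            lo, hi = rng_spec
            if name == "n_vertebrae":
                kwargs[name] = int(rng.integers(int(lo), int(hi) + 1))
            else:
                kwargs[name] = float(rng.uniform(lo, hi))
        else:  # explicit list of choices (e.g. grid shapes)
            kwargs[name] = rng_spec[int(rng.integers(len(rng_spec)))]
    return replace(base, **kwargs)


def generate_cohort(
    out_dir: Union[str, Path],
    n_studies: int,
    config_ranges: Optional[Dict] = None,
    seed: int = 0,
    base_config: PhantomConfig = PhantomConfig(),
    sequences: Sequence[str] = ("T1", "T2"),
    split_counts: Optional[Tuple[int, int]] = None,
    partial_top_probability: float = 0.5,
    dialect: LabelDialect = DEFAULT_DIALECT,
) -> List[StudyRecord]:
    """Write a cohort of phantom studies in the dataset layout.

    Each study gets one mask and one image per requested sequence ("T1"/"T2"
    map to T1-like/T2-like contrast) sharing that mask, mirroring multi-series
    MRI studies.  Per-study randomness is seeded with
    ``np.random.default_rng([seed, study_index])`` (SeedSequence key mixing),
    so cohorts are reproducible and extensible study-by-study.  With
    probability ``partial_top_probability`` the top vertebra is truncated by a
    fraction drawn from U(0.2, 0.6).  ``split_counts=(n_train, n_val)`` assigns
    the first studies to the train split, the next to validation, the rest to
    test.  Returns the manifest records; also writes ``overview.csv``.
    """
    out_dir = Path(out_dir)
    image_dir, mask_dir = out_dir / "images", out_dir / "masks"
    image_dir.mkdir(parents=True, exist_ok=True)
    mask_dir.mkdir(parents=True, exist_ok=True)
    ranges = dict(config_ranges or {"n_vertebrae": (3, 5)})

    records: List[StudyRecord] = []
    rows = []
    for idx in range(n_studies):
        rng = np.random.default_rng([seed, idx])
        study_seed = int(rng.integers(2**31 - 1))
        cfg = _draw_config(base_config, ranges, rng, study_seed)
        if "partial_top_fraction" not in ranges:
            f = float(rng.uniform(0.2, 0.6)) if rng.random() < partial_top_probability else 0.0
            cfg = replace(cfg, partial_top_fraction=f)
        study_id = str(1000 + idx)
        if split_counts is None:
            split = "none"
        else:
            n_train, n_val = split_counts
            split = "train" if idx < n_train else "validation" if idx < n_train + n_val else "test"

        mask = None
        metadata = None
        for seq in sequences:
            contrast = "T1-like" if seq.upper().startswith("T1") else "T2-like"
            vol, mask, metadata = generate_phantom(replace(cfg, contrast=contrast), dialect)
            stem = f"{study_id}_{seq}"
            write_mha(vol, image_dir / f"{stem}.mha")
            write_mha(mask, mask_dir / f"{stem}.mha")
            records.append(
                StudyRecord(
                    study_id=study_id,
                    sequence=seq,
                    image_path=str(image_dir / f"{stem}.mha"),
                    mask_path=str(mask_dir / f"{stem}.mha"),
                    split=split,
                    metadata={"complete": dict(metadata["complete"]),
                              "n_vertebrae": metadata["n_vertebrae"]},
                )
            )
        flags = "".join("1" if metadata["complete"][i] else "0"
                        for i in range(1, metadata["n_vertebrae"] + 1))
        rows.append(
            {
                "study_id": study_id,
                "split": split,
                "n_vertebrae": metadata["n_vertebrae"],
                "complete_flags": flags,
                "partial_top_fraction": cfg.partial_top_fraction,
                "phantom_seed": cfg.seed,
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "overview.csv", index=False)
    return records
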