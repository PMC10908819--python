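"""MetaImage volume I/O, the label-encoding dialect, and the study manifest.

All volumes in this package live on a fixed internal axis convention:

* axis 0 — slice-normal direction (left-right for sagittal series),
* axis 1 — cranio-caudal, index increasing from caudal (bottom) to cranial (top),
* axis 2 — antero-posterior, in-plane.

``spacing`` is the per-axis voxel size in mm in that same order.  Files whose
direction cosines indicate another axis ordering are permuted/flipped into this
convention on read (nearest axis-aligned orientation).

Instance masks use the *bottom-up* convention: vertebra labels form the
consecutive run ``1..N`` with label 1 the most caudal vertebra.  The numeric
codes of the spinal canal and of the intervertebral discs (IVDs) are described
by a configurable :class:`LabelDialect`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import DialectError, FormatError, LabelConventionError, ManifestError

logger = logging.getLogger(__name__)

SEQUENCES = ("T1", "T2", "T2 SPACE")

__all__ = [
    "Volume",
    "LabelVolume",
    "LabelDialect",
    "StudyRecord",
    "read_mha",
    "write_mha",
    "build_manifest",
    "split_structures",
    "DEFAULT_DIALECT",
]


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing and physical origin (mm)."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(f"expected a non-empty 3D grid, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    def physical_extent(self) -> Tuple[float, float, float]:
        """Edge-to-edge extent of the grid in mm, per axis."""
        return tuple(n * s for n, s in zip(self.values.shape, self.spacing))


@dataclass(frozen=True)
class LabelDialect:
    """Numeric encoding of structures inside one integer mask.

    Vertebrae occupy ``1..max_vertebrae`` bottom-up; the spinal canal is a
    single code; IVD ``i`` (the disc inferior to vertebra ``i``) is encoded as
    ``ivd_offset + i``.  The dialect is configurable so the reader can be
    pointed at datasets that use different codes without code changes.
    """

    canal_label: int = 100
    ivd_offset: int = 200
    max_vertebrae: int = 99

    def kind_of(self, value: int) -> Tuple[str, int]:
        """Classify a non-zero label value → ``(kind, instance_index)``."""
        v = int(value)
        if 1 <= v <= self.max_vertebrae:
            return "vertebra", v
        if v == self.canal_label:
            return "canal", 1
        if v > self.ivd_offset:
            return "ivd", v - self.ivd_offset
        raise DialectError(f"label value {v} is outside the declared dialect")

    def vertebra(self, i: int) -> int:
        return int(i)

    def ivd(self, i: int) -> int:
        return self.ivd_offset + int(i)

    @property
    def canal(self) -> int:
        return self.canal_label


DEFAULT_DIALECT = LabelDialect()


@dataclass
class LabelVolume(Volume):
    """An integer instance/structure mask sharing a :class:`Volume` grid."""

    dialect: LabelDialect = field(default_factory=LabelDialect)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("LabelVolume requires an integer-typed grid")
        if self.values.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def labels(self) -> np.ndarray:
        return self.values


@dataclass
class StudyRecord:
    """One MRI series of one study, as listed in the manifest."""

    study_id: str
    sequence: str
    image_path: str
    mask_path: str = ""
    split: str = "none"
    metadata: dict = field(default_factory=dict)

    @property
    def stem(self) -> str:
        return f"{self.study_id}_{self.sequence}"


# ---------------------------------------------------------------------------
# MetaImage reading / writing
# ---------------------------------------------------------------------------

def _axis_permutation(direction: np.ndarray) -> Tuple[List[int], List[int]]:
    """Nearest axis-aligned interpretation of a 3x3 direction matrix.

    ``direction[:, j]`` is the physical direction of image axis ``j`` (ITK
    x/y/z order).  Returns, per ITK axis, the dominant physical axis and the
    sign of the alignment.
    """
    perm, signs = [], []
    for j in range(3):
        col = direction[:, j]
        k = int(np.argmax(np.abs(col)))
        perm.append(k)
        signs.append(1 if col[k] >= 0 else -1)
    if sorted(perm) != [0, 1, 2]:
        raise FormatError("TransformMatrix: direction cosines are not close to axis-aligned")
    return perm, signs


def read_mha(path: Union[str, Path], dialect: Optional[LabelDialect] = None) -> Union[Volume, LabelVolume]:
    """Read a MetaImage (.mha/.mhd) file into the internal axis convention.

    Integer-typed files yield a :class:`LabelVolume`; floating-point files a
    :class:`Volume`.  Voxels match the file exactly (after the axis-aligning
    permutation); spacing and origin come from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"cannot parse {path.name}: {exc}") from exc

    if img.GetDimension() != 3:
        raise FormatError(f"NDims: expected a 3D image, got {img.GetDimension()}D")

    spacing_xyz = img.GetSpacing()
    if any(s <= 0 for s in spacing_xyz):
        raise FormatError(f"ElementSpacing: non-positive entry in {spacing_xyz}")

    direction = np.array(img.GetDirection(), dtype=float).reshape(3, 3)
    perm, signs = _axis_permutation(direction)

    arr = sitk.GetArrayFromImage(img)  # numpy axes (z, y, x) == ITK axes (2, 1, 0)
    origin_xyz = np.array(img.GetOrigin(), dtype=float)

    # Physical axis k is sampled along ITK axis j where perm[j] == k.
    itk_for_phys = [perm.index(k) for k in range(3)]
    np_axis_for_phys = [2 - j for j in itk_for_phys]  # numpy axis of that ITK axis
    # Internal axis order (0,1,2) corresponds to physical (z, y, x) so that an
    # identity-direction file maps to the array untouched.
    internal_phys = [2, 1, 0]
    src_axes = [np_axis_for_phys[k] for k in internal_phys]
    arr = np.transpose(arr, src_axes)
    spacing = tuple(float(spacing_xyz[itk_for_phys[k]]) for k in internal_phys)
    origin = tuple(float(origin_xyz[k]) for k in internal_phys)
    for a, k in enumerate(internal_phys):  # internal axis a samples physical axis k
        if signs[itk_for_phys[k]] < 0:
            arr = np.flip(arr, axis=a)

    arr = np.ascontiguousarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return LabelVolume(arr.astype(np.uint16), spacing, origin,
                           dialect=dialect or DEFAULT_DIALECT)
    return Volume(arr.astype(np.float32), spacing, origin)


def write_mha(volume: Volume, path: Union[str, Path]) -> None:
    """Write a volume as MetaImage; label grids as uint16, images as float32."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(volume, LabelVolume):
        arr = volume.values.astype(np.uint16)
    else:
        arr = volume.values.astype(np.float32)
    img = sitk.GetImageFromArray(arr)  # numpy (z,y,x) -> ITK (x,y,z)
    img.SetSpacing(tuple(volume.spacing[::-1]))
    img.SetOrigin(tuple(volume.origin[::-1]))
    try:
        sitk.WriteImage(img, str(path), useCompression=False)
    except RuntimeError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

_SEQ_PATTERN = sorted(
    [s for s in SEQUENCES] + ["T2_SPACE"], key=len, reverse=True
)


def parse_stem(stem: str) -> Tuple[str, str]:
    """Split ``<study-id>_<sequence>`` into its parts.

    Sequences containing a space ("T2 SPACE") are accepted verbatim; the
    underscore variant ("T2_SPACE") is normalised to the canonical spelling.
    """
    for seq in _SEQ_PATTERN:
        suffix = "_" + seq
        if stem.endswith(suffix):
            study_id = stem[: -len(suffix)]
            if study_id:
                return study_id, "T2 SPACE" if seq == "T2_SPACE" else seq
    raise ValueError(f"filename stem {stem!r} does not follow '<study-id>_<sequence>'")


def build_manifest(
    image_dir: Union[str, Path],
    mask_dir: Union[str, Path],
    overview_table: Optional[Union[str, Path, pd.DataFrame]] = None,
) -> List[StudyRecord]:
    """Pair images with masks by filename stem and attach train/val splits.

    The optional overview table (CSV or DataFrame with at least ``study_id``
    and ``split`` columns) assigns every series of a study to that study's
    split; extra columns are carried along as per-record metadata.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    if not image_dir.is_dir():
        raise ManifestError(f"image directory {image_dir} does not exist")
    if not mask_dir.is_dir():
        raise ManifestError(f"mask directory {mask_dir} does not exist")

    overview: Optional[pd.DataFrame] = None
    if overview_table is not None:
        overview = (
            overview_table
            if isinstance(overview_table, pd.DataFrame)
            else pd.read_csv(overview_table, dtype={"study_id": str})
        )
        overview = overview.set_index(overview["study_id"].astype(str))

    records: List[StudyRecord] = []
    seen = set()
    for p in sorted(image_dir.glob("*.mh[ad]")):
        stem = p.stem
        try:
            study_id, sequence = parse_stem(stem)
        except ValueError as exc:
            logger.warning("skipping %s: %s", p.name, exc)
            continue
        if stem in seen:
            raise ManifestError(f"duplicate stem {stem!r} in {image_dir}")
        seen.add(stem)
        mask_path = mask_dir / p.name
        if not mask_path.exists():
            alt = mask_dir / (stem + (".mha" if p.suffix == ".mhd" else ".mhd"))
            mask_path = alt if alt.exists() else None
        if mask_path is None:
            logger.warning("no mask found for %s", p.name)
        split, metadata = "none", {}
        if overview is not None and study_id in overview.index:
            row = overview.loc[study_id]
            split = str(row.get("split", "none"))
            metadata = {
                k: row[k] for k in overview.columns if k not in ("study_id", "split")
            }
        records.append(
            StudyRecord(
                study_id=study_id,
                sequence=sequence,
                image_path=str(p),
                mask_path=str(mask_path) if mask_path else "",
                split=split,
                metadata=metadata,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Structure splitting
# ---------------------------------------------------------------------------

def split_structures(mask: LabelVolume) -> Dict[str, List[Tuple[int, np.ndarray]]]:
    """Decompose a mask into per-instance binary masks, grouped by kind.

    Returns ``{"vertebra": [(1, m1), ...], "ivd": [...], "canal": [...]}`` with
    vertebrae and IVDs ordered caudal→cranial (i.e. by bottom-up index).  The
    returned masks are pairwise disjoint and their union equals the mask
    foreground.  A gap in the vertebra label run raises
    :class:`LabelConventionError`; a label outside the dialect raises
    :class:`DialectError`.
    """
    out: Dict[str, List[Tuple[int, np.ndarray]]] = {"vertebra": [], "ivd": [], "canal": []}
    values = np.unique(mask.values)
    buckets: Dict[str, List[int]] = {"vertebra": [], "ivd": [], "canal": []}
    for v in values:
        if v == 0:
            continue
        kind, idx = mask.dialect.kind_of(int(v))
        buckets[kind].append(idx)
    vert = sorted(buckets["vertebra"])
    if vert and vert != list(range(1, len(vert) + 1)):
        raise LabelConventionError(
            f"vertebra labels {vert} do not form the consecutive bottom-up run 1..N"
        )
    for i in vert:
        out["vertebra"].append((i, mask.values == mask.dialect.vertebra(i)))
    for i in sorted(buckets["ivd"]):
        out["ivd"].append((i, mask.values == mask.dialect.ivd(i)))
    if buckets["canal"]:
        out["canal"].append((1, mask.values == mask.dialect.canal))
    return out
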