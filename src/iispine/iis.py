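"""The iterative instance segmentation engine.

A 3D patch walks along the spine, caudal to cranial.  Three binary *memory
states* (vertebrae, IVDs, spinal canal) record segmentation progress; the
vertebra and IVD memories are network inputs so the backbone always segments
the lowest vertebra not yet in memory, while the canal memory only accumulates
the stitched canal prediction.  The traversal is:

1. raster-scan patches (50% stride, caudal axis slowest) until a vertebra
   fragment above the minimum volume appears;
2. re-center the patch on the fragment's center of mass and re-segment until
   the predicted volume stabilises and the patch stops moving;
3. commit the vertebra, its inferior IVD and the canal patch to memory;
4. segment the same patch again with the updated memory — this exposes a
   fragment of the next vertebra — and repeat until no fragment is found and
   the raster reaches the top of the volume.

The backbone is any callable ``(image_patch, vertebra_memory_patch,
ivd_memory_patch, patch_spec) -> BackbonePrediction``; an oracle backbone
built from a ground-truth mask makes the whole traversal testable without any
training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import ConvergenceFailure, DuplicateInstanceError
from .preprocess import WorkingGrid, normalize_intensity, resample_to_working
from .volume_io import DEFAULT_DIALECT, LabelDialect, LabelVolume, Volume, split_structures

logger = logging.getLogger(__name__)

__all__ = [
    "PatchSpec",
    "BackbonePrediction",
    "MemoryState",
    "InstanceResult",
    "SegmentationResult",
    "SegmentationConfig",
    "search_first_fragment",
    "converge_on_instance",
    "commit_instance",
    "segment_study",
    "make_oracle_backbone",
]

_FACE = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class PatchSpec:
    """A patch location: center voxel (working grid) and even per-axis size."""

    center: Tuple[int, int, int]
    size: Tuple[int, int, int] = (64, 192, 192)

    def __post_init__(self) -> None:
        if any(s % 2 for s in self.size):
            raise ValueError(f"patch size must be even per axis, got {self.size}")

    def bounds(self) -> List[Tuple[int, int]]:
        return [(c - s // 2, c + s // 2) for c, s in zip(self.center, self.size)]


@dataclass
class BackbonePrediction:
    """Per-patch backbone output: three probability maps plus two scalars."""

    vertebra: np.ndarray
    ivd: np.ndarray
    canal: np.ndarray
    completeness: float
    label_value: float


@dataclass
class MemoryState:
    """The three binary progress volumes on the working grid.

    The vertebra and IVD memories are backbone inputs and only ever grow; the
    canal memory stores the stitched canal but is never fed to the backbone.
    """

    vertebra_memory: np.ndarray
    ivd_memory: np.ndarray
    canal_memory: np.ndarray

    @classmethod
    def empty(cls, shape: Tuple[int, int, int]) -> "MemoryState":
        return cls(
            np.zeros(shape, dtype=bool),
            np.zeros(shape, dtype=bool),
            np.zeros(shape, dtype=bool),
        )


@dataclass
class InstanceResult:
    """One accepted vertebra with its inferior IVD and completeness call."""

    label_index: int
    vertebra_mask: np.ndarray
    ivd_mask: np.ndarray
    completeness_probability: float
    complete: bool
    label_head_value: float


@dataclass
class SegmentationResult:
    label_map: LabelVolume
    instances: List[InstanceResult]
    canal_mask: np.ndarray
    trace: List[Dict]


@dataclass(frozen=True)
class SegmentationConfig:
    """Inference settings; the defaults are the standard operating point."""

    working_grid: WorkingGrid = WorkingGrid()
    patch_size: Tuple[int, int, int] = (64, 192, 192)
    threshold: float = 0.5
    volume_tolerance: float = 0.01
    relocation_cap: int = 10
    min_fragment_volume_mm3: float = 100.0
    duplicate_overlap: float = 0.5
    completeness_threshold: float = 0.5
    stride_fraction: float = 0.5
    normalize: bool = True
    dialect: LabelDialect = DEFAULT_DIALECT


# ---------------------------------------------------------------------------
# Patch plumbing
# ---------------------------------------------------------------------------

def extract_patch(arr: np.ndarray, spec: PatchSpec, pad_value=0) -> np.ndarray:
    """Clip ``spec`` to the array bounds, pad the outside with ``pad_value``."""
    out = np.full(spec.size, pad_value, dtype=arr.dtype)
    src, dst = [], []
    for (lo, hi), n in zip(spec.bounds(), arr.shape):
        s_lo, s_hi = max(lo, 0), min(hi, n)
        if s_lo >= s_hi:
            return out
        src.append(slice(s_lo, s_hi))
        dst.append(slice(s_lo - lo, s_hi - lo))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def paste_patch(full_shape: Tuple[int, int, int], patch: np.ndarray, spec: PatchSpec) -> np.ndarray:
    """Place a patch-sized boolean mask back onto an empty full-size grid."""
    out = np.zeros(full_shape, dtype=bool)
    src, dst = [], []
    for (lo, hi), n in zip(spec.bounds(), full_shape):
        s_lo, s_hi = max(lo, 0), min(hi, n)
        if s_lo >= s_hi:
            return out
        dst.append(slice(s_lo, s_hi))
        src.append(slice(s_lo - lo, s_hi - lo))
    out[tuple(dst)] = patch[tuple(src)]
    return out


def _axis_centers(n: int, size: int, stride: int) -> List[int]:
    if size >= n:
        return [n // 2]
    first, last = size // 2, n - size // 2
    centers = list(range(first, last, stride))
    if centers[-1] != last:
        centers.append(last)
    return centers


def raster_centers(shape: Tuple[int, int, int], patch_size: Tuple[int, int, int],
                   stride_fraction: float = 0.5) -> List[Tuple[int, int, int]]:
    """Patch centers tiling the volume; the cranio-caudal axis (1) varies
    slowest and ascends, so the most caudal row of patches is visited first."""
    per_axis = [
        _axis_centers(n, s, max(int(s * stride_fraction), 1))
        for n, s in zip(shape, patch_size)
    ]
    return [
        (c0, c1, c2)
        for c1 in per_axis[1]
        for c0 in per_axis[0]
        for c2 in per_axis[2]
    ]


def _fragment(pred_vertebra: np.ndarray, memory_patch: np.ndarray, threshold: float
              ) -> np.ndarray:
    """Largest face-connected component of the memory-excluded prediction."""
    cand = (pred_vertebra >= threshold) & ~memory_patch
    if not cand.any():
        return cand
    lab, n = ndimage.label(cand, structure=_FACE)
    if n == 1:
        return cand
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == int(np.argmax(counts))


def _evaluate(volume: Volume, memory: MemoryState, backbone: Callable,
              spec: PatchSpec, config: SegmentationConfig,
              trace: Optional[List[Dict]] = None) -> BackbonePrediction:
    img = extract_patch(volume.values, spec, pad_value=0.0)
    vmem = extract_patch(memory.vertebra_memory, spec, pad_value=False)
    imem = extract_patch(memory.ivd_memory, spec, pad_value=False)
    pred = backbone(img, vmem, imem, spec)
    canal_patch = paste_patch(volume.shape, pred.canal >= config.threshold, spec)
    memory.canal_memory |= canal_patch
    if trace is not None:
        trace.append(
            {
                "event": "evaluate",
                "center": list(spec.center),
                "vertebra_memory_voxels": int(memory.vertebra_memory.sum()),
                "ivd_memory_voxels": int(memory.ivd_memory.sum()),
            }
        )
    return pred


# ---------------------------------------------------------------------------
# Traversal primitives
# ---------------------------------------------------------------------------

def search_first_fragment(
    volume: Volume,
    memory: MemoryState,
    backbone: Callable,
    patch_size: Tuple[int, int, int],
    config: SegmentationConfig = SegmentationConfig(),
    centers: Optional[Sequence[Tuple[int, int, int]]] = None,
    trace: Optional[List[Dict]] = None,
) -> Optional[PatchSpec]:
    """Raster-scan until a memory-excluded vertebra fragment exceeds the
    minimum fragment volume; ``None`` when the scan tops out empty-handed."""
    voxel_mm3 = float(np.prod(config.working_grid.spacing))
    if centers is None:
        centers = raster_centers(volume.shape, patch_size, config.stride_fraction)
    for c in centers:
        spec = PatchSpec(tuple(c), tuple(patch_size))
        pred = _evaluate(volume, memory, backbone, spec, config, trace)
        vmem = extract_patch(memory.vertebra_memory, spec, pad_value=False)
        frag = _fragment(pred.vertebra, vmem, config.threshold)
        if frag.sum() * voxel_mm3 > config.min_fragment_volume_mm3:
            return spec
    return None


def converge_on_instance(
    volume: Volume,
    memory: MemoryState,
    backbone: Callable,
    start: PatchSpec,
    config: SegmentationConfig = SegmentationConfig(),
    trace: Optional[List[Dict]] = None,
) -> Tuple[InstanceResult, PatchSpec]:
    """Re-center the patch on the fragment's center of mass until the volume
    stabilises (relative change ≤ tolerance) and the center stops moving
    (≤ 1 voxel), or fail at the relocation cap / when the fragment vanishes.
    """
    voxel_mm3 = float(np.prod(config.working_grid.spacing))
    center = tuple(int(c) for c in start.center)
    size = tuple(start.size)
    prev_vol: Optional[int] = None
    prev_frag_full: Optional[np.ndarray] = None
    for k in range(config.relocation_cap):
        spec = PatchSpec(center, size)
        pred = _evaluate(volume, memory, backbone, spec, config, trace)
        vmem = extract_patch(memory.vertebra_memory, spec, pad_value=False)
        frag = _fragment(pred.vertebra, vmem, config.threshold)
        vol = int(frag.sum())
        if vol * voxel_mm3 <= config.min_fragment_volume_mm3:
            raise ConvergenceFailure(
                f"fragment shrank below the minimum volume at patch {center}"
            )
        com_patch = ndimage.center_of_mass(frag)
        com = [
            int(round(cp + lo)) for cp, (lo, _) in zip(com_patch, spec.bounds())
        ]
        com = [min(max(c, 0), n - 1) for c, n in zip(com, volume.shape)]
        disp = max(abs(a - b) for a, b in zip(com, center))
        stabilised = (
            prev_vol is not None
            and abs(vol - prev_vol) <= config.volume_tolerance * prev_vol
            and disp <= 1
        ) or disp == 0
        if stabilised or k == config.relocation_cap - 1:
            vertebra_full = paste_patch(volume.shape, frag, spec)
            if not stabilised and prev_frag_full is not None:
                # At the cap: a patch tracking one slightly jittering vertebra
                # is acceptable, but alternation between (near-)disjoint
                # fragments means the backbone never settled on an instance.
                inter = int((vertebra_full & prev_frag_full).sum())
                union = int((vertebra_full | prev_frag_full).sum())
                if union == 0 or inter / union < 0.5:
                    raise ConvergenceFailure(
                        f"relocation cap {config.relocation_cap} reached while "
                        f"alternating between disjoint fragments (moved {disp} voxels)"
                    )
            imem = extract_patch(memory.ivd_memory, spec, pad_value=False)
            ivd_patch = (pred.ivd >= config.threshold) & ~imem
            ivd_full = paste_patch(volume.shape, ivd_patch, spec)
            prob = float(pred.completeness)
            inst = InstanceResult(
                label_index=0,  # assigned on commit
                vertebra_mask=vertebra_full,
                ivd_mask=ivd_full,
                completeness_probability=prob,
                complete=prob >= config.completeness_threshold,
                label_head_value=float(pred.label_value),
            )
            return inst, spec
        prev_vol = vol
        prev_frag_full = paste_patch(volume.shape, frag, spec)
        center = tuple(com)
    raise ConvergenceFailure("unreachable")  # pragma: no cover


def commit_instance(
    memory: MemoryState,
    inst: InstanceResult,
    canal_patch: Optional[np.ndarray] = None,
    duplicate_overlap: float = 0.5,
) -> MemoryState:
    """Union the instance masks (and optionally a canal patch) into memory.

    Voxels are only ever added.  If the vertebra overlaps the existing
    vertebra memory by more than ``duplicate_overlap`` of its own volume the
    commit is refused with :class:`DuplicateInstanceError` — the guard against
    a defective backbone re-emitting a segmented vertebra forever.
    """
    n_inst = int(inst.vertebra_mask.sum())
    if n_inst:
        overlap = int((inst.vertebra_mask & memory.vertebra_memory).sum())
        if overlap / n_inst > duplicate_overlap:
            raise DuplicateInstanceError(
                f"candidate vertebra overlaps memory by {overlap / n_inst:.0%}"
            )
    return MemoryState(
        vertebra_memory=memory.vertebra_memory | inst.vertebra_mask,
        ivd_memory=memory.ivd_memory | inst.ivd_mask,
        canal_memory=(
            memory.canal_memory | canal_patch
            if canal_patch is not None
            else memory.canal_memory.copy()
        ),
    )


# ---------------------------------------------------------------------------
# Whole-study traversal
# ---------------------------------------------------------------------------

def _resample_labels_to(labels: np.ndarray, from_spacing, to_spacing, to_shape) -> np.ndarray:
    coords = [
        ((np.arange(n) + 0.5) * to_spacing[a] / from_spacing[a] - 0.5)
        for a, n in enumerate(to_shape)
    ]
    grid = np.meshgrid(*coords, indexing="ij")
    return ndimage.map_coordinates(labels, np.stack(grid), order=0, mode="nearest")


def segment_study(
    volume: Volume,
    backbone: Callable,
    config: SegmentationConfig = SegmentationConfig(),
) -> SegmentationResult:
    """Segment a raw volume end-to-end.

    The volume is resampled to the working grid and normalised; the iterative
    traversal then alternates raster search, center-of-mass convergence and
    memory commits, re-segmenting the just-committed patch to expose the next
    vertebra.  The canal is the union of all thresholded per-patch canal
    predictions.  Instances are relabelled bottom-up 1..N by cranio-caudal
    centroid and the label map is resampled back to the input grid.
    """
    work = resample_to_working(volume, config.working_grid)
    if config.normalize:
        work = normalize_intensity(work)

    memory = MemoryState.empty(work.shape)
    trace: List[Dict] = []
    instances: List[InstanceResult] = []
    centers = raster_centers(work.shape, config.patch_size, config.stride_fraction)
    raster_idx = 0
    current: Optional[PatchSpec] = None
    voxel_mm3 = float(np.prod(config.working_grid.spacing))

    while True:
        found: Optional[PatchSpec] = None
        if current is not None:
            spec, current = current, None
            pred = _evaluate(work, memory, backbone, spec, config, trace)
            vmem = extract_patch(memory.vertebra_memory, spec, pad_value=False)
            frag = _fragment(pred.vertebra, vmem, config.threshold)
            if frag.sum() * voxel_mm3 > config.min_fragment_volume_mm3:
                found = spec
        if found is None:
            while raster_idx < len(centers):
                spec = PatchSpec(centers[raster_idx], tuple(config.patch_size))
                raster_idx += 1
                pred = _evaluate(work, memory, backbone, spec, config, trace)
                vmem = extract_patch(memory.vertebra_memory, spec, pad_value=False)
                frag = _fragment(pred.vertebra, vmem, config.threshold)
                if frag.sum() * voxel_mm3 > config.min_fragment_volume_mm3:
                    found = spec
                    break
            if found is None:
                break  # top of the volume reached, no fragments left
        try:
            inst, final_patch = converge_on_instance(
                work, memory, backbone, found, config, trace
            )
            memory = commit_instance(
                memory, inst, None, duplicate_overlap=config.duplicate_overlap
            )
        except ConvergenceFailure as exc:
            logger.warning("instance skipped: %s", exc)
            trace.append({"event": "convergence_failure", "center": list(found.center)})
            continue
        except DuplicateInstanceError as exc:
            logger.warning("duplicate instance refused: %s", exc)
            trace.append({"event": "duplicate_refused", "center": list(found.center)})
            continue
        instances.append(inst)
        trace.append(
            {
                "event": "commit",
                "center": list(final_patch.center),
                "vertebra_memory_voxels": int(memory.vertebra_memory.sum()),
                "ivd_memory_voxels": int(memory.ivd_memory.sum()),
            }
        )
        current = final_patch  # re-segment the same patch with updated memory

    # Bottom-up relabelling by cranio-caudal centroid.
    def _centroid1(inst: InstanceResult) -> float:
        return float(ndimage.center_of_mass(inst.vertebra_mask)[1])

    instances.sort(key=_centroid1)
    dialect = config.dialect
    labels = np.zeros(work.shape, dtype=np.uint16)
    labels[memory.canal_memory] = dialect.canal
    for i, inst in enumerate(instances, start=1):
        inst.label_index = i
        labels[inst.ivd_mask] = dialect.ivd(i)
    for i, inst in enumerate(instances, start=1):
        labels[inst.vertebra_mask] = dialect.vertebra(i)

    if np.allclose(volume.spacing, config.working_grid.spacing):
        out_labels = labels
    else:
        out_labels = _resample_labels_to(
            labels, config.working_grid.spacing, volume.spacing, volume.shape
        )
    label_map = LabelVolume(
        out_labels.astype(np.uint16), volume.spacing, volume.origin, dialect=dialect
    )
    return SegmentationResult(
        label_map=label_map,
        instances=instances,
        canal_mask=memory.canal_memory,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# Oracle backbone
# ---------------------------------------------------------------------------

def make_oracle_backbone(ground_truth: LabelVolume) -> Callable:
    """A perfect backbone built from a ground-truth mask on the working grid.

    For a given patch and memory it emits the lowest ground-truth vertebra not
    yet (majority-)covered by the vertebra memory, restricted to the patch,
    together with its inferior disc and all canal voxels in the patch.  The
    completeness output is 1 exactly when that vertebra neither touches the
    cranial volume face nor extends beyond the patch; the label head returns
    the bottom-up ground-truth index.  This realises the backbone contract
    without any training and makes the traversal logic testable in isolation.
    """
    groups = split_structures(ground_truth)
    vert = groups["vertebra"]
    ivds = dict(groups["ivd"])
    canal = groups["canal"][0][1] if groups["canal"] else np.zeros(ground_truth.shape, bool)
    n1 = ground_truth.shape[1]
    touches_top = {
        i: bool(m[:, n1 - 1, :].any()) for i, m in vert
    }
    totals = {i: int(m.sum()) for i, m in vert}

    def backbone(image_patch: np.ndarray, vmem_patch: np.ndarray, imem_patch: np.ndarray,
                 spec: PatchSpec) -> BackbonePrediction:
        shape = image_patch.shape
        zeros = np.zeros(shape, dtype=np.float32)
        canal_patch = extract_patch(canal, spec, pad_value=False).astype(np.float32)
        for i, mask in vert:
            m_patch = extract_patch(mask, spec, pad_value=False)
            in_patch = int(m_patch.sum())
            if in_patch == 0:
                continue
            covered = int((m_patch & vmem_patch).sum())
            if covered / in_patch >= 0.5:
                continue  # already segmented
            ivd_mask = ivds.get(i)
            ivd_patch = (
                extract_patch(ivd_mask, spec, pad_value=False).astype(np.float32)
                if ivd_mask is not None
                else zeros
            )
            complete = (not touches_top[i]) and in_patch == totals[i]
            return BackbonePrediction(
                vertebra=m_patch.astype(np.float32),
                ivd=ivd_patch,
                canal=canal_patch,
                completeness=1.0 if complete else 0.0,
                label_value=float(i),
            )
        return BackbonePrediction(
            vertebra=zeros, ivd=zeros, canal=canal_patch,
            completeness=0.0, label_value=0.0,
        )

    return backbone
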