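from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from iispine import (
    BackbonePrediction,
    MemoryState,
    PatchSpec,
    SegmentationConfig,
    Volume,
    WorkingGrid,
    commit_instance,
    converge_on_instance,
    make_oracle_backbone,
    search_first_fragment,
    segment_study,
    split_structures,
)
from iispine.errors import ConvergenceFailure, DuplicateInstanceError
from iispine.iis import extract_patch, raster_centers
from tests.conftest import SMALL_CONFIG

PATCH = (8, 24, 24)
CFG = SegmentationConfig(
    working_grid=WorkingGrid(SMALL_CONFIG.spacing), patch_size=PATCH
)


@pytest.fixture(scope="module")
def oracle_setup(request):
    from iispine import generate_phantom

    vol, mask, meta = generate_phantom(SMALL_CONFIG)
    return vol, mask, meta, make_oracle_backbone(mask)


class TestPatchPlumbing:
    def test_patch_is_clipped_and_zero_padded(self):
        arr = np.arange(4 * 4 * 4).reshape(4, 4, 4).astype(np.float32)
        patch = extract_patch(arr, PatchSpec((0, 0, 0), (4, 4, 4)))
        assert patch.shape == (4, 4, 4)
        assert patch[0, 0, 0] == 0  # out-of-volume corner padded
        assert patch[2, 2, 2] == arr[0, 0, 0]

    def test_odd_patch_size_rejected(self):
        with pytest.raises(ValueError):
            PatchSpec((0, 0, 0), (5, 4, 4))

    def test_raster_covers_volume_with_half_stride(self):
        shape, size = (12, 48, 32), PATCH
        centers = raster_centers(shape, size)
        covered = np.zeros(shape, bool)
        for c in centers:
            spec = PatchSpec(c, size)
            sl = tuple(slice(max(lo, 0), min(hi, n))
                       for (lo, hi), n in zip(spec.bounds(), shape))
            covered[sl] = True
        assert covered.all()
        # caudal axis sweeps slowest and ascends
        axis1 = [c[1] for c in centers]
        assert axis1 == sorted(axis1)


class TestSearch:
    def test_finds_most_caudal_vertebra_first(self, oracle_setup):
        vol, mask, _, oracle = oracle_setup
        memory = MemoryState.empty(vol.shape)
        spec = search_first_fragment(vol, memory, oracle, PATCH, CFG)
        assert spec is not None
        v1 = split_structures(mask)["vertebra"][0][1]
        assert extract_patch(v1, spec).any()  # patch overlaps vertebra 1

    def test_memory_prefilled_with_all_vertebrae_returns_none(self, oracle_setup):
        vol, mask, _, oracle = oracle_setup
        memory = MemoryState.empty(vol.shape)
        for _, m in split_structures(mask)["vertebra"]:
            memory.vertebra_memory |= m
        assert search_first_fragment(vol, memory, oracle, PATCH, CFG) is None

    def test_background_volume_returns_none(self, oracle_setup):
        vol = Volume(np.zeros((12, 48, 32), np.float32), SMALL_CONFIG.spacing)
        from iispine import LabelVolume

        empty_gt = LabelVolume(np.zeros(vol.shape, np.uint16), vol.spacing)
        oracle = make_oracle_backbone(empty_gt)
        memory = MemoryState.empty(vol.shape)
        assert search_first_fragment(vol, memory, oracle, PATCH, CFG) is None


class TestConvergence:
    def test_start_at_centroid_converges_without_moving(self, oracle_setup):
        vol, mask, _, oracle = oracle_setup
        v1 = split_structures(mask)["vertebra"][0][1]
        center = tuple(int(round(c)) for c in ndimage.center_of_mass(v1))
        memory = MemoryState.empty(vol.shape)
        trace = []
        inst, final = converge_on_instance(
            vol, memory, oracle, PatchSpec(center, PATCH), CFG, trace
        )
        assert final.center == center
        assert sum(1 for t in trace if t["event"] == "evaluate") == 1
        assert np.array_equal(inst.vertebra_mask, v1)

    def test_offset_start_converges_in_few_relocations(self, oracle_setup):
        vol, mask, _, oracle = oracle_setup
        v1 = split_structures(mask)["vertebra"][0][1]
        center = tuple(int(round(c)) for c in ndimage.center_of_mass(v1))
        start = (center[0], max(center[1] - 4, 0), center[2])
        memory = MemoryState.empty(vol.shape)
        trace = []
        inst, _ = converge_on_instance(
            vol, memory, oracle, PatchSpec(start, PATCH), CFG, trace
        )
        assert sum(1 for t in trace if t["event"] == "evaluate") <= 3
        assert np.array_equal(inst.vertebra_mask, v1)

    def test_alternating_fragments_fail_at_relocation_cap(self):
        shape = (8, 40, 24)
        vol = Volume(np.zeros(shape, np.float32), SMALL_CONFIG.spacing)
        frag_a = np.zeros(PATCH, np.float32)
        frag_a[2:6, 2:8, 8:16] = 1.0
        frag_b = np.zeros(PATCH, np.float32)
        frag_b[2:6, 16:22, 8:16] = 1.0
        calls = {"n": 0}

        def adversary(img, vm, im, spec):
            calls["n"] += 1
            frag = frag_a if calls["n"] % 2 else frag_b
            zeros = np.zeros(PATCH, np.float32)
            return BackbonePrediction(frag, zeros, zeros, 0.0, 0.0)

        memory = MemoryState.empty(shape)
        with pytest.raises(ConvergenceFailure):
            converge_on_instance(
                vol, memory, adversary, PatchSpec((4, 20, 12), PATCH), CFG
            )
        assert calls["n"] == CFG.relocation_cap

    def test_vanishing_fragment_fails(self):
        shape = (8, 40, 24)
        vol = Volume(np.zeros(shape, np.float32), SMALL_CONFIG.spacing)

        def silent(img, vm, im, spec):
            zeros = np.zeros(PATCH, np.float32)
            return BackbonePrediction(zeros, zeros, zeros, 0.0, 0.0)

        with pytest.raises(ConvergenceFailure):
            converge_on_instance(
                vol, MemoryState.empty(shape), silent, PatchSpec((4, 20, 12), PATCH), CFG
            )


class TestCommit:
    @staticmethod
    def _instance(shape=(6, 10, 10)):
        from iispine.iis import InstanceResult

        v = np.zeros(shape, bool)
        v[2:4, 2:5, 2:5] = True
        d = np.zeros(shape, bool)
        d[2:4, 0:2, 2:5] = True
        return InstanceResult(1, v, d, 1.0, True, 1.0)

    def test_commit_to_empty_memory_equals_instance(self):
        inst = self._instance()
        memory = commit_instance(MemoryState.empty(inst.vertebra_mask.shape), inst)
        assert np.array_equal(memory.vertebra_memory, inst.vertebra_mask)
        assert np.array_equal(memory.ivd_memory, inst.ivd_mask)

    def test_union_is_idempotent_when_guard_disabled(self):
        inst = self._instance()
        m1 = commit_instance(MemoryState.empty(inst.vertebra_mask.shape), inst)
        m2 = commit_instance(m1, inst, duplicate_overlap=1.0)
        assert np.array_equal(m1.vertebra_memory, m2.vertebra_memory)
        assert np.array_equal(m1.ivd_memory, m2.ivd_memory)

    def test_majority_overlap_raises_duplicate_signal(self):
        inst = self._instance()
        m1 = commit_instance(MemoryState.empty(inst.vertebra_mask.shape), inst)
        with pytest.raises(DuplicateInstanceError):
            commit_instance(m1, inst)

    def test_commit_never_removes_voxels(self):
        inst = self._instance()
        m0 = MemoryState.empty(inst.vertebra_mask.shape)
        m0.vertebra_memory[0, 0, 0] = True
        m1 = commit_instance(m0, inst)
        assert m1.vertebra_memory[0, 0, 0]
        assert m1.vertebra_memory.sum() >= m0.vertebra_memory.sum()


class TestSegmentStudy:
    def test_oracle_identity_on_phantom(self, oracle_setup):
        vol, mask, _, oracle = oracle_setup
        result = segment_study(vol, oracle, CFG)
        assert len(result.instances) == 3
        assert np.array_equal(result.label_map.values, mask.values)
        assert [i.label_index for i in result.instances] == [1, 2, 3]
        assert all(i.complete for i in result.instances)

    def test_truncated_top_vertebra_flagged_incomplete(self, truncated_phantom):
        vol, mask, meta = truncated_phantom
        result = segment_study(vol, make_oracle_backbone(mask), CFG)
        flags = {i.label_index: i.complete for i in result.instances}
        assert flags == meta["complete"]

    def test_background_volume_yields_empty_result(self):
        from iispine import LabelVolume

        shape = (12, 48, 32)
        vol = Volume(np.zeros(shape, np.float32), SMALL_CONFIG.spacing)
        oracle = make_oracle_backbone(LabelVolume(np.zeros(shape, np.uint16), vol.spacing))
        result = segment_study(vol, oracle, CFG)
        assert result.instances == []
        assert not result.canal_mask.any()
        assert not result.label_map.values.any()

    def test_memory_monotone_and_eval_budget(self, oracle_setup):
        vol, mask, _, oracle = oracle_setup
        result = segment_study(vol, oracle, CFG)
        counts = [
            (t["vertebra_memory_voxels"], t["ivd_memory_voxels"])
            for t in result.trace
            if "vertebra_memory_voxels" in t
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        evals = sum(1 for t in result.trace if t["event"] == "evaluate")
        n_raster = len(raster_centers(vol.shape, PATCH, CFG.stride_fraction))
        assert evals <= n_raster + CFG.relocation_cap * (len(result.instances) + 1)

    def test_instance_centroids_strictly_bottom_up(self, oracle_setup):
        vol, _, _, oracle = oracle_setup
        result = segment_study(vol, oracle, CFG)
        cys = [ndimage.center_of_mass(i.vertebra_mask)[1] for i in result.instances]
        assert all(b > a for a, b in zip(cys, cys[1:]))

    def test_deterministic_given_backbone_and_config(self, oracle_setup):
        vol, _, _, oracle = oracle_setup
        a = segment_study(vol, oracle, CFG)
        b = segment_study(vol, oracle, CFG)
        assert np.array_equal(a.label_map.values, b.label_map.values)

    def test_label_map_resampled_back_to_input_grid(self, oracle_setup):
        vol, mask, _, oracle = oracle_setup
        coarse = Volume(vol.values.copy(), vol.spacing)
        cfg = replace(CFG, working_grid=WorkingGrid((2.0, 1.5, 1.5)))
        result = segment_study(coarse, oracle_from_resampled(mask, cfg), cfg)
        assert result.label_map.shape == coarse.shape
        assert result.label_map.spacing == pytest.approx(coarse.spacing)


def oracle_from_resampled(mask, cfg):
    from iispine import resample_to_working

    return make_oracle_backbone(resample_to_working(mask, cfg.working_grid))


class TestOracleBackbone:
    def test_emits_lowest_unsegmented_vertebra(self, oracle_setup):
        vol, mask, _, oracle = oracle_setup
        groups = split_structures(mask)
        v1, v2 = groups["vertebra"][0][1], groups["vertebra"][1][1]
        center = tuple(int(round(c)) for c in ndimage.center_of_mass(v1 | v2))
        spec = PatchSpec(center, (12, 48, 32))
        img = extract_patch(vol.values, spec)
        empty = np.zeros(spec.size, bool)
        pred = oracle(img, empty, empty, spec)
        assert np.array_equal(pred.vertebra > 0.5, extract_patch(v1, spec))
        # with vertebra 1 in memory, vertebra 2 comes out
        pred2 = oracle(img, extract_patch(v1, spec), empty, spec)
        assert np.array_equal(pred2.vertebra > 0.5, extract_patch(v2, spec))

    def test_completeness_zero_for_cropped_top(self, truncated_phantom):
        vol, mask, _ = truncated_phantom
        oracle = make_oracle_backbone(mask)
        groups = split_structures(mask)
        top = groups["vertebra"][-1][1]
        center = tuple(int(round(c)) for c in ndimage.center_of_mass(top))
        spec = PatchSpec(center, (12, 48, 32))
        memory = np.zeros(spec.size, bool)
        for _, m in groups["vertebra"][:-1]:
            memory |= extract_patch(m, spec)
        pred = oracle(extract_patch(vol.values, spec), memory, memory, spec)
        assert pred.completeness == 0.0
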