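import math

import numpy as np
import pytest

from iispine import (
    AugmentationConfig,
    BackboneSpec,
    LossWeights,
    TrainSchedule,
    TrainedBackbone,
    WorkingGrid,
    composite_loss,
    make_training_samples,
    train,
)
from iispine.model import SEG_CHANNELS
from iispine.nnet import SpineUNet
from tests.conftest import SMALL_CONFIG

GRID = WorkingGrid(SMALL_CONFIG.spacing)
PATCH = (8, 24, 24)


def _random_case(rng, shape=(4, 4, 4)):
    predictions = {ch: rng.random(shape) for ch in SEG_CHANNELS}
    predictions["completeness"] = float(rng.random())
    predictions["label"] = float(rng.uniform(0, 6))
    targets = {ch: (rng.random(shape) > 0.6) for ch in SEG_CHANNELS}
    targets["completeness"] = int(rng.integers(2))
    targets["label"] = int(rng.integers(1, 6))
    return predictions, targets


def brute_force_loss(predictions, targets, w):
    """Voxel-by-voxel recomputation, independent of the vectorised code."""
    total = 0.0
    for ch in SEG_CHANNELS:
        p = np.asarray(predictions[ch], float)
        t = np.asarray(targets[ch], float)
        fp = fn = bce = 0.0
        n_fg = n_bg = 0
        for idx in np.ndindex(p.shape):
            pi, ti = float(p[idx]), float(t[idx])
            pc = min(max(pi, w.epsilon), 1 - w.epsilon)
            bce += -(ti * math.log(pc) + (1 - ti) * math.log(1 - pc))
            if ti > 0:
                n_fg += 1
                fn += 1 - pi
            else:
                n_bg += 1
                fp += pi
        total += w.w_fp * (fp / n_bg if n_bg else 0.0)
        total += w.w_fn * (fn / n_fg if n_fg else 0.0)
        total += w.w_bce * bce / p.size
    total += w.w_label * abs(float(predictions["label"]) - float(targets["label"]))
    pc = min(max(float(predictions["completeness"]), w.epsilon), 1 - w.epsilon)
    tc = float(targets["completeness"])
    total += w.w_complete * -(tc * math.log(pc) + (1 - tc) * math.log(1 - pc))
    return total


class TestCompositeLoss:
    def test_perfect_prediction_is_near_zero(self, rng):
        w = LossWeights()
        t = {ch: (rng.random((4, 4, 4)) > 0.5) for ch in SEG_CHANNELS}
        t["completeness"] = 1
        t["label"] = 3
        p = {ch: t[ch].astype(float) for ch in SEG_CHANNELS}
        p["completeness"] = 1.0
        p["label"] = 3.0
        total, _ = composite_loss(p, t, w)
        assert total <= 5 * -math.log(1 - w.epsilon)

    def test_inverted_prediction_saturates_fp_fn(self, rng):
        w = LossWeights()
        t = {ch: (rng.random((4, 4, 4)) > 0.5) for ch in SEG_CHANNELS}
        t["completeness"] = 1
        t["label"] = 2
        p = {ch: 1.0 - t[ch].astype(float) for ch in SEG_CHANNELS}
        p["completeness"] = 0.0
        p["label"] = 2.0
        _, breakdown = composite_loss(p, t, w)
        for ch in SEG_CHANNELS:
            assert breakdown[f"{ch}_fp"] == pytest.approx(w.w_fp)
            assert breakdown[f"{ch}_fn"] == pytest.approx(w.w_fn)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        w = LossWeights(w_fp=0.7, w_fn=1.3, w_bce=0.9, w_label=0.2, w_complete=0.3)
        p, t = _random_case(rng)
        total, breakdown = composite_loss(p, t, w)
        assert total == pytest.approx(brute_force_loss(p, t, w), abs=1e-9)
        assert total == pytest.approx(sum(breakdown.values()), abs=1e-12)

    def test_empty_foreground_and_background_conventions(self):
        w = LossWeights()
        shape = (3, 3, 3)
        t = {ch: np.zeros(shape, bool) for ch in SEG_CHANNELS}
        t["completeness"] = 0
        t["label"] = 1
        p = {ch: np.zeros(shape) for ch in SEG_CHANNELS}
        p["completeness"] = 0.0
        p["label"] = 1.0
        _, breakdown = composite_loss(p, t, w)
        assert all(breakdown[f"{ch}_fn"] == 0.0 for ch in SEG_CHANNELS)
        t_full = {ch: np.ones(shape, bool) for ch in SEG_CHANNELS}
        t_full["completeness"] = 1
        t_full["label"] = 1
        p_full = {ch: np.ones(shape) for ch in SEG_CHANNELS}
        p_full["completeness"] = 1.0
        p_full["label"] = 1.0
        _, breakdown = composite_loss(p_full, t_full, w)
        assert all(breakdown[f"{ch}_fp"] == 0.0 for ch in SEG_CHANNELS)

    def test_shape_mismatch_rejected(self, rng):
        p, t = _random_case(rng)
        t["ivd"] = np.zeros((2, 2, 2), bool)
        with pytest.raises(ValueError):
            composite_loss(p, t, LossWeights())


class TestTrainingSamples:
    @staticmethod
    def _samples(study, aug=None, seed=0):
        return list(
            make_training_samples(
                (study[0], study[1]), GRID, PATCH, aug, np.random.default_rng(seed)
            )
        )

    def test_one_sample_per_vertebra(self, small_phantom):
        samples = self._samples(small_phantom)
        assert len(samples) == 3
        assert sorted(s.label for s in samples) == [1, 2, 3]

    def test_memory_contains_exactly_caudal_instances(self, small_phantom):
        from scipy import ndimage

        from iispine import split_structures
        from iispine.iis import PatchSpec, extract_patch
        from iispine.model import _prepare_study

        _, mask_w = _prepare_study(small_phantom[0], small_phantom[1], GRID)
        vert = dict(split_structures(mask_w)["vertebra"])
        ivds = dict(split_structures(mask_w)["ivd"])
        samples = list(
            make_training_samples(
                (small_phantom[0], small_phantom[1]), GRID, PATCH, None,
                np.random.default_rng(0), jitter_voxels=0,
            )
        )
        for s in samples:
            i = s.label
            center = tuple(
                int(np.clip(round(c), 0, n - 1))
                for c, n in zip(ndimage.center_of_mass(vert[i]), mask_w.shape)
            )
            spec = PatchSpec(center, PATCH)
            expected_v = np.zeros(mask_w.shape, bool)
            expected_d = np.zeros(mask_w.shape, bool)
            for j in range(1, i):
                expected_v |= vert[j]
                expected_d |= ivds[j]
            assert np.array_equal(s.vertebra_memory, extract_patch(expected_v, spec))
            assert np.array_equal(s.ivd_memory, extract_patch(expected_d, spec))
            assert np.array_equal(s.target_vertebra, extract_patch(vert[i], spec))

    def test_targets_disjoint_from_memory_under_augmentation(self, small_phantom):
        aug = AugmentationConfig(elastic_probability=1.0, noise_probability=1.0,
                                 smoothing_probability=1.0, crop_probability=0.5)
        for seed in range(3):
            for s in self._samples(small_phantom, aug=aug, seed=seed):
                assert not (s.target_vertebra & s.vertebra_memory).any()
                assert not (s.target_ivd & s.ivd_memory).any()
                assert s.target_vertebra.any()  # crop never removes the target

    def test_completeness_target_tracks_truncation(self, truncated_phantom):
        samples = self._samples(truncated_phantom)
        by_label = {s.label: s.completeness for s in samples}
        assert by_label == {1: 1, 2: 1, 3: 0}


class TestTraining:
    @pytest.fixture(scope="class")
    def tiny_cohort(self):
        from iispine.profiles import desk_cohort

        cohort = desk_cohort(6, seed=3, splits=(4, 2))
        return [(im, mk, sp) for im, mk, sp, _ in cohort]

    @pytest.fixture(scope="class")
    def smoke_run(self, tiny_cohort):
        from iispine.profiles import DESK_SPACING

        spec = BackboneSpec(patch_size=(16, 40, 40), widths=(4, 8, 16))
        schedule = TrainSchedule(epochs=2, learning_rate=3e-3)
        return train(tiny_cohort, spec=spec, schedule=schedule, seed=0,
                     grid=WorkingGrid(DESK_SPACING))

    def test_two_epoch_smoke_loss_decreases(self, smoke_run):
        _, log = smoke_run
        assert log[1]["loss_total"] < log[0]["loss_total"]

    def test_validation_dice_logged(self, smoke_run):
        _, log = smoke_run
        assert all(0.0 <= e["val_dice_vertebra"] <= 1.0 for e in log)

    def test_fixed_seed_reproduces_first_epoch(self, tiny_cohort):
        from iispine.profiles import DESK_SPACING

        spec = BackboneSpec(patch_size=(16, 40, 40), widths=(4, 8, 16))
        schedule = TrainSchedule(epochs=1, learning_rate=3e-3)
        _, log_a = train(tiny_cohort, spec=spec, schedule=schedule, seed=5,
                         grid=WorkingGrid(DESK_SPACING))
        _, log_b = train(tiny_cohort, spec=spec, schedule=schedule, seed=5,
                         grid=WorkingGrid(DESK_SPACING))
        assert log_a[0]["loss_total"] == log_b[0]["loss_total"]

    def test_empty_training_split_rejected(self):
        from iispine.errors import IISpineError
        from iispine import generate_phantom

        vol, mask, _ = generate_phantom(SMALL_CONFIG)
        with pytest.raises(IISpineError):
            train([(vol, mask, "validation")])

    def test_checkpoint_roundtrip(self, smoke_run, tmp_path, rng):
        backbone, _ = smoke_run
        backbone.save(tmp_path / "bb.npz")
        loaded = TrainedBackbone.load(tmp_path / "bb.npz")
        x = rng.normal(size=(16, 40, 40)).astype(np.float32)
        m = np.zeros((16, 40, 40), bool)
        a = backbone(x, m, m)
        b = loaded(x, m, m)
        assert np.array_equal(a.vertebra, b.vertebra)
        assert a.completeness == b.completeness


class TestBackboneContract:
    def test_outputs_are_probabilities_on_patch_grid(self, rng):
        net = SpineUNet(widths=(4, 8, 16), seed=0)
        bb = TrainedBackbone(net, BackboneSpec(patch_size=(8, 24, 24), widths=(4, 8, 16)))
        x = rng.normal(size=(8, 24, 24)).astype(np.float32)
        m = np.zeros((8, 24, 24), bool)
        pred = bb(x, m, m)
        for out in (pred.vertebra, pred.ivd, pred.canal):
            assert out.shape == x.shape
            assert np.all((out >= 0) & (out <= 1))
        assert 0.0 <= pred.completeness <= 1.0

    def test_patch_size_must_be_divisible_by_four(self):
        with pytest.raises(ValueError):
            BackboneSpec(patch_size=(10, 24, 24))
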