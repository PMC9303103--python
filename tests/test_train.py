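"""Training orchestration: schedule, augmentation, distillation plumbing."""

from dataclasses import replace

import numpy as np
import pytest

from vesselkd.losses import LossWeights
from vesselkd.model import ModelConfig, load_checkpoint
from vesselkd.phantom import ImageSample
from vesselkd.roi import EmptyMaskError, extract_roi
from vesselkd.train import (
    AugmentConfig,
    StageConfig,
    StudentModel,
    TeacherModel,
    augment,
    default_student_stages,
    default_teacher_stages,
    distill_targets,
    lr_schedule,
)


class TestLrSchedule:
    def test_epoch_one_is_lr_init(self):
        assert lr_schedule(0.0005, 0.92, 1) == 0.0005

    def test_decay_step_value(self):
        assert lr_schedule(0.0005, 0.92, 2) == pytest.approx(0.00046)

    def test_monotone_nonincreasing(self):
        lrs = [lr_schedule(0.0005, 0.92, e) for e in range(1, 51)]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_epoch_below_one_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(0.0005, 0.92, 0)


class TestAugment:
    def test_identity_config_unchanged(self, tiny_samples, rng):
        s = tiny_samples[0]
        out = augment(s, AugmentConfig(), rng)
        assert np.array_equal(out.image, s.image)
        assert np.array_equal(out.mask, s.mask)

    def test_flip_is_involution(self, tiny_samples):
        s = tiny_samples[1]
        cfg = AugmentConfig(flip_prob=1.0)
        once = augment(s, cfg, np.random.default_rng(0))
        twice = augment(once, cfg, np.random.default_rng(0))
        assert np.array_equal(twice.image, s.image)
        assert np.array_equal(twice.mask, s.mask)

    @pytest.mark.parametrize("seed", range(8))
    def test_never_invents_classes(self, tiny_samples, seed):
        s = tiny_samples[2]
        cfg = AugmentConfig.default(64)
        out = augment(s, cfg, np.random.default_rng(seed))
        assert set(np.unique(out.mask)) <= set(np.unique(s.mask))
        assert out.mask.dtype == s.mask.dtype
        assert out.image.min() >= 0.0 and out.image.max() <= 1.0

    def test_geometry_applied_jointly(self, tiny_samples):
        """A pure shift moves image and mask by the same offset."""
        s = tiny_samples[3]
        cfg = AugmentConfig(shift_range=(5.0, 5.0))
        out = augment(s, cfg, np.random.default_rng(0))
        # output(o) = input(o − 5): content moves down-right by 5 px
        assert np.array_equal(out.mask[5:, 5:], s.mask[:-5, :-5])
        assert np.allclose(out.image[5:, 5:], s.image[:-5, :-5], atol=1e-12)


def _fast_stages(defaults, epochs=2, bs=8):
    return tuple(
        replace(s, max_epochs=epochs, patience=epochs, batch_size=bs,
                lr_init=1e-3 if s.stage == 1 else 3e-4)
        for s in defaults
    )


@pytest.fixture(scope="module")
def tiny_teacher(request):
    samples = request.getfixturevalue("tiny_samples")
    cfg = request.getfixturevalue("tiny_model_cfg")
    stages = _fast_stages(default_teacher_stages(seed=0), epochs=3)
    return TeacherModel(
        samples[:16], samples[16:], model_config=cfg, stages=stages, roi_pad=6
    ).fit()


class TestTeacherTraining:
    def test_smoke_and_checkpoint(self, tmp_path, tiny_teacher):
        assert len(tiny_teacher.history) == 6
        path = tiny_teacher.save(tmp_path / "teacher.npz")
        net, meta = load_checkpoint(path)
        assert meta["role"] == "teacher"
        assert meta["stages"][0]["weights"]["gamma"] == 0.0
        assert net.config == tiny_teacher.model_config

    def test_history_and_summary(self, tiny_teacher):
        df = tiny_teacher.history_frame()
        assert {"stage", "epoch", "lr", "train_total", "val_total"} <= set(df.columns)
        assert df["lr"].iloc[0] == pytest.approx(1e-3)
        assert df["lr"].iloc[1] == pytest.approx(1e-3 * 0.92)
        assert "best val loss" in tiny_teacher.summary()

    def test_determinism_identical_logs(self, tiny_samples, tiny_model_cfg):
        stages = _fast_stages(default_teacher_stages(seed=3), epochs=2)
        aug = AugmentConfig.default(64)

        def run():
            return TeacherModel(
                tiny_samples[:8], tiny_samples[16:18], model_config=tiny_model_cfg,
                stages=stages, augment_config=aug, roi_pad=6,
            ).fit().history

        assert run() == run()

    def test_overfit_single_sample(self, tiny_samples):
        """Teacher training drives the loss down on one repeated phantom."""
        s = tiny_samples[0]
        cfg = ModelConfig(base_width=8, depth=2, aspp_rates=(2,), seed=0)
        stages = default_teacher_stages(seed=1)
        stages = (replace(stages[0], lr_init=5e-3, batch_size=1, max_epochs=30,
                          patience=30, decay=1.0, freeze_backbone=False),
                  replace(stages[1], lr_init=1e-3, batch_size=1, max_epochs=1,
                          patience=1))
        res = TeacherModel([s] * 4, [s], model_config=cfg,
                           stages=stages, roi_pad=6).fit()
        first = res.history[0]["train_total"]
        assert res.best_val_loss < first
        assert res.best_val_loss < 0.15

    def test_empty_mask_samples_skipped(self, tiny_samples, tiny_model_cfg, caplog):
        empty = ImageSample(np.zeros((64, 64)), np.zeros((64, 64), np.uint8), "empty")
        stages = _fast_stages(default_teacher_stages(seed=0), epochs=1)
        res = TeacherModel(
            [tiny_samples[0], empty], tiny_samples[16:17],
            model_config=tiny_model_cfg, stages=stages, roi_pad=6,
        ).fit()
        assert len(res.history) == 2  # ran despite the empty sample


class TestDistillTargets:
    def test_validity_area_and_unit_scale(self, tiny_teacher, tiny_samples):
        s = tiny_samples[5]
        logits, validity = distill_targets(tiny_teacher.network, s, pad=6)
        box = extract_roi(s.mask, 6)
        assert validity.sum() == box.height * box.width
        assert logits.shape == (64, 64, 4)
        assert (logits[validity == 0] == 0.0).all()

    def test_deterministic(self, tiny_teacher, tiny_samples):
        a = distill_targets(tiny_teacher.network, tiny_samples[6], pad=6)
        b = distill_targets(tiny_teacher.network, tiny_samples[6], pad=6)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_empty_mask_rejected(self, tiny_teacher):
        empty = ImageSample(np.zeros((64, 64)), np.zeros((64, 64), np.uint8), "e")
        with pytest.raises(EmptyMaskError):
            distill_targets(tiny_teacher.network, empty, pad=6)


class TestStudentTraining:
    def test_smoke_with_kd_components_logged(self, tiny_samples, tiny_model_cfg,
                                             tiny_teacher):
        stages = _fast_stages(default_student_stages(seed=0), epochs=2)
        res = StudentModel(
            tiny_samples[:8], tiny_samples[16:18], teacher=tiny_teacher.network,
            model_config=tiny_model_cfg, stages=stages, roi_pad=6,
        ).fit()
        stage2 = [h for h in res.history if h["stage"] == 2]
        assert stage2 and all("train_kd" in h for h in res.history)
        assert any(h["train_kd"] > 0 for h in stage2)
        assert all(h["train_kd"] == 0.0 for h in res.history if h["stage"] == 1)

    def test_gamma_zero_requires_no_teacher(self, tiny_samples, tiny_model_cfg):
        stages = tuple(
            replace(s, weights=replace(s.weights, gamma=0.0))
            for s in _fast_stages(default_student_stages(seed=0), epochs=1)
        )
        res = StudentModel(
            tiny_samples[:4], tiny_samples[16:17], teacher=None,
            model_config=tiny_model_cfg, stages=stages, roi_pad=6,
        ).fit()
        assert all(h["train_kd"] == 0.0 for h in res.history)

    def test_missing_teacher_with_gamma_rejected(self, tiny_samples, tiny_model_cfg):
        stages = _fast_stages(default_student_stages(seed=0), epochs=1)
        with pytest.raises(ValueError, match="teacher"):
            StudentModel(tiny_samples[:4], tiny_samples[16:17], teacher=None,
                         model_config=tiny_model_cfg, stages=stages, roi_pad=6)

    def test_teacher_parameters_never_change(self, tiny_samples, tiny_model_cfg,
                                             tiny_teacher):
        before = [p.value.copy() for p in tiny_teacher.network.parameters()]
        stages = _fast_stages(default_student_stages(seed=0), epochs=1)
        StudentModel(
            tiny_samples[:4], tiny_samples[16:17], teacher=tiny_teacher.network,
            model_config=tiny_model_cfg, stages=stages, roi_pad=6,
        ).fit()
        after = [p.value for p in tiny_teacher.network.parameters()]
        assert all(np.array_equal(a, b) for a, b in zip(before, after))


class TestEarlyStopping:
    def test_halts_within_patience_and_keeps_best(self, tiny_samples, tiny_model_cfg):
        # a huge lr makes validation loss erratic, triggering early stop
        stages = (
            StageConfig(1, lr_init=0.5, batch_size=8, max_epochs=30, patience=2,
                        weights=LossWeights(1.0, 1.0, 0.0), freeze_backbone=True, seed=0),
            StageConfig(2, lr_init=1e-4, batch_size=8, max_epochs=1, patience=1,
                        weights=LossWeights(1.0, 1.0, 0.0), freeze_backbone=False, seed=0),
        )
        res = TeacherModel(tiny_samples[:8], tiny_samples[16:18],
                           model_config=tiny_model_cfg, stages=stages, roi_pad=6).fit()
        stage1 = [h for h in res.history if h["stage"] == 1]
        assert len(stage1) < 30
        best = min(h["val_total"] for h in stage1)
        improvements = [h for h in stage1 if h["val_total"] == best]
        last_improve_epoch = improvements[0]["epoch"]
        assert len(stage1) <= last_improve_epoch + 2


def test_stage_config_validation():
    w = LossWeights()
    with pytest.raises(ValueError):
        StageConfig(3, 1e-3, 8, w, True)
    with pytest.raises(ValueError):
        StageConfig(1, -1e-3, 8, w, True)
    with pytest.raises(ValueError):
        StageConfig(1, 1e-3, 8, w, True, decay=1.5)
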