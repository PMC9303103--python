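"""Canned desk-scale experiments: the KD student vs. the γ=0 baseline.

The full-scale study (512×512 clinical images, ~1300 samples, a large
pretrained backbone) is out of reach on a workstation; this module fixes a
scaled-down replicate of the same design on synthetic phantoms: 200 training
phantoms at 64×64, a small encoder–decoder, and identical training budgets
for the distilled student and the no-distillation baseline.  The
distillation hyperparameters stay at the reference operating point
(γ=3, τ=4); learning rates are larger than the full-scale defaults because
no stage starts from a pretrained backbone here.  All randomness derives
from a single integer seed per replicate.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .metrics import MetricsReport, report_from_pairs
from .model import ModelConfig
from .phantom import ImageSample, PhantomConfig, generate_sample
from .roi import crop_resize, extract_roi
from .train import (
    AugmentConfig,
    StudentModel,
    TeacherModel,
    TrainingResults,
    default_student_stages,
    default_teacher_stages,
)

__all__ = ["scaled_dataset", "run_kd_comparison", "SCALED"]

#: Frozen desk-scale study conditions.
SCALED = {
    "image_size": 64,
    "n_train": 200,
    "n_val": 20,
    "n_test": 30,
    "base_width": 8,
    "depth": 2,
    "aspp_rates": (2, 4),
    "roi_pad": 6,  # 50 px at 512 scale, rounded to the 64 px grid
    "lr_stage1": 2e-3,
    "lr_stage2": 5e-4,
    "batch_size": 8,
    "epochs_teacher": (6, 5),
    "epochs_student": (6, 12),
}


def scaled_dataset(
    seed: int,
    n_train: int | None = None,
    n_val: int | None = None,
    n_test: int | None = None,
    image_size: int | None = None,
) -> tuple[list[ImageSample], list[ImageSample], list[ImageSample]]:
    """Generate the in-memory train/val/test phantom splits for one replicate."""
    n_train = n_train or SCALED["n_train"]
    n_val = n_val or SCALED["n_val"]
    n_test = n_test or SCALED["n_test"]
    cfg = PhantomConfig.default(image_size or SCALED["image_size"], seed=seed)
    idx = iter(range(n_train + n_val + n_test))
    train = [generate_sample(cfg, next(idx)) for _ in range(n_train)]
    val = [generate_sample(cfg, next(idx)) for _ in range(n_val)]
    test = [generate_sample(cfg, next(idx)) for _ in range(n_test)]
    return train, val, test


def _stage_pair(defaults, lr1, lr2, e1, e2, bs):
    s1, s2 = defaults
    s1 = replace(s1, lr_init=lr1, batch_size=bs, max_epochs=e1, patience=e1)
    s2 = replace(s2, lr_init=lr2, batch_size=bs, max_epochs=e2, patience=e2)
    return (s1, s2)


def run_kd_comparison(
    seed: int,
    n_train: int | None = None,
    n_val: int | None = None,
    n_test: int | None = None,
    verbose: bool = False,
) -> dict:
    """One full replicate: teacher → KD student and γ=0 baseline → test metrics.

    Returns a dict with the three :class:`MetricsReport` objects
    (``teacher_roi`` is the teacher scored on ROI crops of the test set,
    ``student``/``baseline`` on full-size test images) and the three
    :class:`TrainingResults`.
    """
    c = SCALED
    train, val, test = scaled_dataset(seed, n_train, n_val, n_test)
    size = train[0].image.shape[0]
    model_cfg = ModelConfig(
        base_width=c["base_width"], depth=c["depth"], aspp_rates=c["aspp_rates"],
        seed=seed + 1,
    )
    aug = AugmentConfig.default(size)
    pad = c["roi_pad"]

    t_stages = _stage_pair(
        default_teacher_stages(seed=seed + 2),
        c["lr_stage1"], c["lr_stage2"], *c["epochs_teacher"], c["batch_size"],
    )
    teacher = TeacherModel(
        train, val, model_config=model_cfg, stages=t_stages, augment_config=aug, roi_pad=pad
    ).fit(verbose=verbose)

    def student_run(gamma: float) -> TrainingResults:
        stages = _stage_pair(
            default_student_stages(seed=seed + 2, gamma=gamma),
            c["lr_stage1"], c["lr_stage2"], *c["epochs_student"], c["batch_size"],
        )
        return StudentModel(
            train, val, teacher=(teacher.network if gamma > 0 else None),
            model_config=model_cfg, stages=stages, augment_config=aug, roi_pad=pad,
        ).fit(verbose=verbose)

    baseline = student_run(0.0)
    student = student_run(3.0)

    def full_report(res: TrainingResults) -> MetricsReport:
        return report_from_pairs(
            [(res.network.predict_mask(s.image), s.mask) for s in test]
        )

    roi_pairs = []
    for s in test:
        box = extract_roi(s.mask, pad)
        crop_img = crop_resize(s.image, box, size, "bilinear")
        crop_mask = crop_resize(s.mask, box, size, "nearest")
        roi_pairs.append((teacher.network.predict_mask(crop_img), crop_mask))

    return {
        "teacher_roi": report_from_pairs(roi_pairs),
        "baseline": full_report(baseline),
        "student": full_report(student),
        "results": {"teacher": teacher, "baseline": baseline, "student": student},
    }
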