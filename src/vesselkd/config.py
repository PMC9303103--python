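"""YAML experiment configuration.

One document describes a full experiment: phantom dataset, model, the two
teacher and student stages, augmentation, ROI handling and evaluation.
Unknown keys are rejected (typos must not silently change an experiment)
and every random choice flows from explicit seeds in the file — there is no
wall-clock seeding anywhere.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .losses import LossWeights
from .model import ModelConfig
from .phantom import PhantomConfig
from .train import (
    AugmentConfig,
    StageConfig,
    default_student_stages,
    default_teacher_stages,
)

__all__ = ["ExperimentConfig", "load_experiment_config"]

_TOP_KEYS = {"phantom", "model", "teacher_stages", "student_stages", "augment", "roi",
             "eval", "paths", "seeds"}
_PHANTOM_KEYS = {"image_size", "n_train", "n_val", "n_test", "speckle_scale", "blur_sigma",
                 "placement_jitter", "background_level", "rim_fraction"}
_MODEL_KEYS = {"in_channels", "num_classes", "base_width", "depth", "use_aspp", "aspp_rates",
               "dtype"}
_STAGE_KEYS = {"lr_init", "decay", "batch_size", "max_epochs", "patience", "freeze_backbone",
               "decay_unit", "alpha", "beta", "gamma", "tau"}
_AUG_KEYS = {"scale_range", "shift_range", "flip_prob", "rotate_range", "intensity_jitter",
             "enabled"}
_ROI_KEYS = {"pad", "kd_support"}
_EVAL_KEYS = {"split", "aggregation"}
_PATH_KEYS = {"data_dir", "out_dir"}
_SEED_KEYS = {"phantom", "model", "stage"}


def _check_keys(section: dict, allowed: set, where: str) -> dict:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{where}' section: {sorted(unknown)}")
    return section


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig
    n_train: int
    n_val: int
    n_test: int
    model: ModelConfig
    teacher_stages: tuple[StageConfig, StageConfig]
    student_stages: tuple[StageConfig, StageConfig]
    augment: AugmentConfig | None
    roi_pad: int
    kd_support: str
    eval_split: str
    eval_aggregation: str
    data_dir: Path
    out_dir: Path
    config_hash: str


def _stage_overrides(raw: dict, base: StageConfig, where: str) -> StageConfig:
    _check_keys(raw, _STAGE_KEYS, where)
    raw = dict(raw)
    w = base.weights
    w = LossWeights(
        alpha=raw.pop("alpha", w.alpha),
        beta=raw.pop("beta", w.beta),
        gamma=raw.pop("gamma", w.gamma),
        tau=raw.pop("tau", w.tau),
    )
    return replace(base, weights=w, **raw)


def load_experiment_config(path: str | Path) -> ExperimentConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"experiment config not found: {path}")
    text = path.read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    _check_keys(doc, _TOP_KEYS, "top-level")

    seeds = _check_keys(doc.get("seeds", {}) or {}, _SEED_KEYS, "seeds")
    phantom_seed = int(seeds.get("phantom", 0))
    model_seed = int(seeds.get("model", 0))
    stage_seed = int(seeds.get("stage", 0))

    ph = dict(_check_keys(doc.get("phantom", {}) or {}, _PHANTOM_KEYS, "phantom"))
    image_size = int(ph.pop("image_size", 512))
    n_train = int(ph.pop("n_train", 1040))
    n_val = int(ph.pop("n_val", 130))
    n_test = int(ph.pop("n_test", 130))
    phantom = PhantomConfig.default(image_size=image_size, seed=phantom_seed, **ph)

    md = dict(_check_keys(doc.get("model", {}) or {}, _MODEL_KEYS, "model"))
    if "aspp_rates" in md:
        md["aspp_rates"] = tuple(md["aspp_rates"])
    model = ModelConfig(seed=model_seed, **md)

    def stages(key: str, defaults):
        raw = doc.get(key, []) or []
        if len(raw) > 2:
            raise ValueError(f"'{key}' takes at most 2 stage entries")
        out = list(defaults)
        for i, entry in enumerate(raw):
            out[i] = _stage_overrides(entry or {}, out[i], f"{key}[{i}]")
        return tuple(out)

    teacher_stages = stages("teacher_stages", default_teacher_stages(seed=stage_seed))
    student_stages = stages("student_stages", default_student_stages(seed=stage_seed))

    aug_raw = dict(_check_keys(doc.get("augment", {}) or {}, _AUG_KEYS, "augment"))
    enabled = aug_raw.pop("enabled", True)
    for k in ("scale_range", "shift_range", "rotate_range", "intensity_jitter"):
        if k in aug_raw:
            aug_raw[k] = tuple(aug_raw[k])
    if aug_raw:
        aug = AugmentConfig(**aug_raw)
    else:
        aug = AugmentConfig.default(image_size)
    augment = aug if enabled else None

    roi = _check_keys(doc.get("roi", {}) or {}, _ROI_KEYS, "roi")
    # the 50 px padding is native to the 512×512 scale; rescale proportionally
    default_pad = max(1, round(50 * image_size / 512))
    roi_pad = int(roi.get("pad", default_pad))
    kd_support = str(roi.get("kd_support", "roi"))

    ev = _check_keys(doc.get("eval", {}) or {}, _EVAL_KEYS, "eval")
    paths = _check_keys(doc.get("paths", {}) or {}, _PATH_KEYS, "paths")

    return ExperimentConfig(
        phantom=phantom,
        n_train=n_train,
        n_val=n_val,
        n_test=n_test,
        model=model,
        teacher_stages=teacher_stages,
        student_stages=student_stages,
        augment=augment,
        roi_pad=roi_pad,
        kd_support=kd_support,
        eval_split=str(ev.get("split", "test")),
        eval_aggregation=str(ev.get("aggregation", "micro")),
        data_dir=Path(paths.get("data_dir", "data")),
        out_dir=Path(paths.get("out_dir", "runs")),
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
    )
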