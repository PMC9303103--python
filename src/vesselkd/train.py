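"""Two-stage teacher/student training with channel-wise distillation.

The teacher trains on ROI crops of the ground-truth vessel region (γ=0:
cross-entropy + Dice only).  The student trains on full-size images; in its
second stage the frozen teacher's crop-space logits are restored into
full-image coordinates per augmented sample and aligned channel-wise via the
distillation loss (γ=3, τ=4 by default).  Both follow the same two-stage
recipe: stage 1 with a frozen encoder and a larger learning rate, stage 2
end-to-end with a smaller one; the learning rate decays as
lr_init · 0.92^(epoch−1), and early stopping on the validation loss keeps
the best (not last) weights of each stage.

The orchestration is exposed statsmodels-style: :class:`TeacherModel` /
:class:`StudentModel` are built from data and ``fit()`` returns a
:class:`TrainingResults` carrying the trained network, the epoch history,
a ``summary()`` and evaluation/plotting helpers.  The ``train_teacher`` /
``train_student`` functions are thin checkpoint-writing wrappers used by the
command line.

A student run with γ=0 in every stage never touches the teacher and is
code-path identical to baseline (no-distillation) training — given the same
seeds it produces byte-identical epoch logs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._nn import Adam
from .losses import LossWeights, combined_loss_grad
from .model import (
    ModelConfig,
    Segmenter,
    build_segmenter,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
    set_backbone_frozen,
)
from .phantom import ImageSample, load_split
from .roi import EmptyMaskError, crop_resize, extract_roi, restore_logits

__all__ = [
    "StageConfig",
    "AugmentConfig",
    "lr_schedule",
    "augment",
    "distill_targets",
    "TeacherModel",
    "StudentModel",
    "TrainingResults",
    "train_teacher",
    "train_student",
    "default_teacher_stages",
    "default_student_stages",
]

logger = logging.getLogger("vesselkd")


def lr_schedule(lr_init: float, decay: float, epoch: int) -> float:
    """Exponentially decayed learning rate lr_init · decay^(epoch−1)."""
    if epoch < 1:
        raise ValueError("epoch is 1-based and must be ≥ 1")
    if lr_init <= 0 or not (0.0 < decay <= 1.0):
        raise ValueError("require lr_init > 0 and 0 < decay ≤ 1")
    return lr_init * decay ** (epoch - 1)


@dataclass(frozen=True)
class StageConfig:
    """One training stage: optimiser schedule, loss weights, freezing."""

    stage: int
    lr_init: float
    batch_size: int
    weights: LossWeights
    freeze_backbone: bool
    decay: float = 0.92
    max_epochs: int = 50
    patience: int = 5
    seed: int = 0
    decay_unit: str = "epoch"

    def __post_init__(self):
        if self.stage not in (1, 2):
            raise ValueError("stage must be 1 or 2")
        if self.lr_init <= 0 or not (0.0 < self.decay <= 1.0):
            raise ValueError("require lr_init > 0 and 0 < decay ≤ 1")
        if self.patience < 1 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("patience, max_epochs, batch_size must be ≥ 1")
        if self.decay_unit not in ("epoch", "step"):
            raise ValueError("decay_unit must be 'epoch' or 'step'")


def default_teacher_stages(seed: int = 0, **overrides) -> tuple[StageConfig, StageConfig]:
    """Two teacher stages: frozen-encoder warm-up, then end-to-end; γ=0."""
    w = LossWeights(alpha=1.0, beta=1.0, gamma=0.0, tau=1.0)
    s1 = StageConfig(1, lr_init=5e-4, batch_size=8, weights=w, freeze_backbone=True, seed=seed)
    s2 = StageConfig(2, lr_init=5e-5, batch_size=2, weights=w, freeze_backbone=False, seed=seed)
    return replace(s1, **overrides), replace(s2, **overrides)


def default_student_stages(
    seed: int = 0, gamma: float = 3.0, tau: float = 4.0, **overrides
) -> tuple[StageConfig, StageConfig]:
    """Student stages: stage 1 distillation-free, stage 2 with γ=3, τ=4."""
    w1 = LossWeights(alpha=1.0, beta=1.0, gamma=0.0, tau=1.0)
    w2 = LossWeights(alpha=1.0, beta=1.0, gamma=gamma, tau=tau if gamma > 0 else 1.0)
    s1 = StageConfig(1, lr_init=5e-4, batch_size=8, weights=w1, freeze_backbone=True, seed=seed)
    s2 = StageConfig(2, lr_init=5e-5, batch_size=2, weights=w2, freeze_backbone=False, seed=seed)
    return replace(s1, **overrides), replace(s2, **overrides)


@dataclass(frozen=True)
class AugmentConfig:
    """Joint geometric + intensity augmentation.

    Geometric transforms (scale, shift in pixels, flip, rotation in degrees)
    apply identically to image and mask; the mask is resampled with nearest
    neighbour and stays integer-valued.  Intensity jitter (brightness shift,
    contrast scale around 0.5) touches the image only — the grayscale
    counterpart of colour jittering.
    """

    scale_range: tuple[float, float] = (1.0, 1.0)
    shift_range: tuple[float, float] = (0.0, 0.0)
    flip_prob: float = 0.0
    rotate_range: tuple[float, float] = (0.0, 0.0)
    intensity_jitter: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def default(cls, image_size: int = 512) -> "AugmentConfig":
        shift = 0.02 * image_size
        return cls(
            scale_range=(0.9, 1.1),
            shift_range=(-shift, shift),
            flip_prob=0.5,
            rotate_range=(-10.0, 10.0),
            intensity_jitter=(0.10, 0.10),
        )

    def _geometric_identity(self) -> bool:
        return (
            self.scale_range == (1.0, 1.0)
            and self.shift_range == (0.0, 0.0)
            and self.rotate_range == (0.0, 0.0)
        )


def augment(sample: ImageSample, config: AugmentConfig, rng: np.random.Generator) -> ImageSample:
    """Random augmentation of one sample; identity config returns it unchanged."""
    img, mask = sample.image, sample.mask
    if config.flip_prob > 0 and rng.random() < config.flip_prob:
        img, mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
    if not config._geometric_identity():
        s = rng.uniform(*config.scale_range)
        theta = math.radians(rng.uniform(*config.rotate_range))
        ty = rng.uniform(*config.shift_range)
        tx = rng.uniform(*config.shift_range)
        ct, st = math.cos(theta), math.sin(theta)
        # output -> input map: rotate/scale about the centre, then shift
        a = np.array([[ct, st], [-st, ct]]) / s
        centre = (np.asarray(img.shape, dtype=float) - 1.0) / 2.0
        offset = centre - a @ (centre + np.array([ty, tx]))
        img = ndimage.affine_transform(img, a, offset=offset, order=1, mode="constant", cval=0.0)
        mask = ndimage.affine_transform(
            mask, a, offset=offset, order=0, mode="constant", cval=0
        ).astype(np.uint8)
        img = np.clip(img, 0.0, 1.0)
    bj, cj = config.intensity_jitter
    if bj > 0 or cj > 0:
        b = rng.uniform(-bj, bj)
        c = rng.uniform(1.0 - cj, 1.0 + cj)
        img = np.clip(c * (img - 0.5) + 0.5 + b, 0.0, 1.0)
    return ImageSample(image=img, mask=mask, id=sample.id)


def distill_targets(
    teacher: Segmenter | str | Path,
    sample: ImageSample,
    pad: int = 50,
    out_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full-size teacher logits for one (augmented) sample, plus validity.

    The ROI is taken from the sample's ground-truth mask, the image crop is
    forwarded through the (frozen) teacher at the model input size, and the
    crop-space logits are restored to full-image coordinates.  The validity
    mask is 1 inside the restored box and 0 elsewhere.  Deterministic: the
    teacher has no stochastic layers.
    """
    net = teacher if isinstance(teacher, Segmenter) else load_checkpoint(teacher)[0]
    if not sample.mask.any():
        raise EmptyMaskError(f"sample {sample.id} has an empty mask; no distillation target")
    box = extract_roi(sample.mask, pad)
    size = out_size or sample.image.shape[0]
    crop = crop_resize(sample.image, box, size, "bilinear")
    logits = net.predict_logits(crop)[0]
    return restore_logits(logits, box, fill=0.0)


# ---------------------------------------------------------------------------
# internal batch preparation and the stage loop
# ---------------------------------------------------------------------------


@dataclass
class _Item:
    image: np.ndarray
    mask: np.ndarray
    teacher_logits: np.ndarray | None = None
    support: np.ndarray | None = None


def _teacher_item(sample: ImageSample, pad: int, out_size: int) -> _Item | None:
    if not sample.mask.any():
        logger.warning("skipping sample %s: empty mask, no ROI", sample.id)
        return None
    box = extract_roi(sample.mask, pad)
    return _Item(
        image=crop_resize(sample.image, box, out_size, "bilinear"),
        mask=crop_resize(sample.mask, box, out_size, "nearest").astype(np.int64),
        teacher_logits=None,
        support=None,
    )


def _student_item(
    sample: ImageSample,
    teacher: Segmenter | None,
    gamma: float,
    pad: int,
    kd_support: str,
    aug_cfg: AugmentConfig | None,
    rng: np.random.Generator | None,
    base_sample: ImageSample | None = None,
) -> _Item:
    if gamma > 0:
        retries = 0
        while not sample.mask.any() and aug_cfg is not None and retries < 5:
            sample = augment(base_sample, aug_cfg, rng)
            retries += 1
        if sample.mask.any():
            tl, validity = distill_targets(teacher, sample, pad)
            support = validity if kd_support == "roi" else None
            return _Item(sample.image, sample.mask.astype(np.int64), tl, support)
        logger.warning("sample %s lost all foreground after retries; no KD", sample.id)
    return _Item(sample.image, sample.mask.astype(np.int64), None, None)


def _batch_loss(
    net: Segmenter, items: list[_Item], weights: LossWeights, need_grad: bool
) -> np.ndarray:
    """Mean combined loss over a batch; backprops into net when need_grad.

    Returns [total, ce, dice, kd] averaged over the batch.  A sample without
    a distillation target contributes with γ effectively 0.
    """
    x = np.stack([it.image for it in items])[:, None, :, :]
    logits = net.forward(x)
    n = len(items)
    comps = np.zeros(4)
    grads = np.empty_like(logits) if need_grad else None
    for i, it in enumerate(items):
        li = np.ascontiguousarray(logits[i].transpose(1, 2, 0)).astype(np.float64)
        w = weights if (weights.gamma == 0 or it.teacher_logits is not None) else replace(
            weights, gamma=0.0
        )
        bd, g = combined_loss_grad(
            it.mask, li, it.teacher_logits, w, it.support, need_grad=need_grad
        )
        comps += np.array(bd)
        if need_grad:
            grads[i] = (g / n).transpose(2, 0, 1)
    if need_grad:
        net.zero_grad()
        net.backward(grads)
    return comps / n


def _chunks(order: np.ndarray, size: int):
    for i in range(0, len(order), size):
        yield order[i : i + size]


class TrainingResults:
    """Outcome of a fitted teacher/student: network, history, diagnostics."""

    def __init__(
        self,
        network: Segmenter,
        role: str,
        history: list[dict],
        stages: tuple[StageConfig, ...],
        best_val_loss: float,
        best_epoch: int,
    ):
        self.network = network
        self.model_config = network.config
        self.role = role
        self.history = history
        self.stages = stages
        self.best_val_loss = best_val_loss
        self.best_epoch = best_epoch

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)

    def summary(self) -> str:
        lines = [
            f"vesselkd {self.role} training results",
            "=" * 42,
            f"parameters:        {count_parameters(self.network):,}",
            f"epochs run:        {len(self.history)}",
            f"best val loss:     {self.best_val_loss:.6f} (epoch {self.best_epoch})",
        ]
        for st in self.stages:
            ran = [r for r in self.history if r["stage"] == st.stage]
            if ran:
                lines.append(
                    f"stage {st.stage}: {len(ran)} epochs, lr {st.lr_init:g}·{st.decay}^(e−1), "
                    f"γ={st.weights.gamma:g}, τ={st.weights.tau:g}, "
                    f"best val {min(r['val_total'] for r in ran):.6f}"
                )
        return "\n".join(lines)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "role": self.role,
            "best_val_loss": self.best_val_loss,
            "best_epoch": self.best_epoch,
            "stages": [asdict(s) for s in self.stages],
        }
        save_checkpoint(self.network, path, meta)
        return path

    def evaluate(self, manifest: str | Path, split: str = "test", aggregation: str = "micro"):
        from .metrics import evaluate_dataset

        return evaluate_dataset(self.network, manifest, split, aggregation)

    def plot_history(self, path: str | Path | None = None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.history_frame()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df.index + 1, df["train_total"], label="train loss")
        ax.plot(df.index + 1, df["val_total"], label="val loss")
        for stage in sorted(df["stage"].unique())[1:]:
            ax.axvline(df[df["stage"] == stage].index[0] + 1, ls="--", c="gray", lw=0.8)
        ax.set_xlabel("epoch")
        ax.set_ylabel("combined loss")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


class _BaseTrainer:
    """Shared two-stage fitting loop for teacher and student."""

    role = "base"

    def __init__(
        self,
        train_samples: list[ImageSample],
        val_samples: list[ImageSample],
        model_config: ModelConfig | None = None,
        stages: tuple[StageConfig, StageConfig] | None = None,
        augment_config: AugmentConfig | None = None,
        roi_pad: int = 50,
    ):
        if not train_samples or not val_samples:
            raise ValueError("need non-empty train and val sample lists")
        size = train_samples[0].image.shape
        if size[0] != size[1]:
            raise ValueError("training images must be square")
        self.train_samples = train_samples
        self.val_samples = val_samples
        self.model_config = model_config or ModelConfig()
        self.stages = stages or self._default_stages()
        self.augment_config = augment_config
        self.roi_pad = roi_pad
        self.input_size = size[0]

    def _default_stages(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def _train_items(self, samples, weights, rng) -> list[_Item]:
        raise NotImplementedError

    def _val_items(self, weights) -> list[_Item]:
        raise NotImplementedError

    def fit(self, log_path: str | Path | None = None, verbose: bool = False) -> TrainingResults:
        net = build_segmenter(self.model_config)
        history: list[dict] = []
        fh = open(log_path, "w") if log_path else None
        best_overall, best_overall_epoch = math.inf, 0
        global_epoch = 0
        try:
            for stage in self.stages:
                set_backbone_frozen(net, stage.freeze_backbone)
                opt = Adam(net.parameters())
                rng = np.random.default_rng([max(stage.seed, 0), stage.stage])
                val_items = self._val_items(stage.weights)
                best_val, best_params, since, step = math.inf, None, 0, 0
                for epoch in range(1, stage.max_epochs + 1):
                    global_epoch += 1
                    lr = lr_schedule(stage.lr_init, stage.decay, epoch)
                    order = rng.permutation(len(self.train_samples))
                    train_comps, n_items = np.zeros(4), 0
                    for chunk in _chunks(order, stage.batch_size):
                        items = self._train_items(
                            [self.train_samples[i] for i in chunk], stage.weights, rng
                        )
                        if not items:
                            continue
                        step += 1
                        if stage.decay_unit == "step":
                            lr = lr_schedule(stage.lr_init, stage.decay, step)
                        comps = _batch_loss(net, items, stage.weights, need_grad=True)
                        opt.step(lr)
                        train_comps += comps * len(items)
                        n_items += len(items)
                    train_comps /= max(n_items, 1)
                    val_comps = np.zeros(4)
                    for chunk in _chunks(np.arange(len(val_items)), stage.batch_size):
                        batch = [val_items[i] for i in chunk]
                        val_comps += _batch_loss(net, batch, stage.weights, False) * len(batch)
                    val_comps /= len(val_items)
                    improved = val_comps[0] < best_val
                    if improved:
                        best_val = float(val_comps[0])
                        best_params = [p.value.copy() for p in net.parameters()]
                        since = 0
                    else:
                        since += 1
                    record = {
                        "stage": stage.stage,
                        "epoch": epoch,
                        "lr": lr,
                        "train_total": float(train_comps[0]),
                        "train_ce": float(train_comps[1]),
                        "train_dice": float(train_comps[2]),
                        "train_kd": float(train_comps[3]),
                        "val_total": float(val_comps[0]),
                        "val_ce": float(val_comps[1]),
                        "val_dice": float(val_comps[2]),
                        "val_kd": float(val_comps[3]),
                    }
                    history.append(record)
                    if fh:
                        fh.write(json.dumps(record, sort_keys=True) + "\n")
                        fh.flush()
                    if verbose:
                        print(
                            f"[{self.role} s{stage.stage} e{epoch:03d}] "
                            f"lr={lr:.2e} train={train_comps[0]:.4f} val={val_comps[0]:.4f}"
                        )
                    if best_val < best_overall:
                        best_overall = best_val
                        best_overall_epoch = global_epoch
                    if since >= stage.patience:
                        break
                if best_params is not None:  # keep the best, not the last, weights
                    for p, v in zip(net.parameters(), best_params):
                        p.value = v
        finally:
            if fh:
                fh.close()
        set_backbone_frozen(net, False)
        return TrainingResults(
            net, self.role, history, tuple(self.stages), best_overall, best_overall_epoch
        )


class TeacherModel(_BaseTrainer):
    """Fine-grained teacher trained on padded ROI crops of the vessel region."""

    role = "teacher"

    def _default_stages(self):
        return default_teacher_stages()

    @classmethod
    def from_manifest(cls, manifest: str | Path, **kwargs) -> "TeacherModel":
        return cls(load_split(manifest, "train"), load_split(manifest, "val"), **kwargs)

    def _train_items(self, samples, weights, rng):
        items = []
        for s in samples:
            aug = augment(s, self.augment_config, rng) if self.augment_config else s
            item = _teacher_item(aug, self.roi_pad, self.input_size)
            if item is not None:
                items.append(item)
        return items

    def _val_items(self, weights):
        items = [_teacher_item(s, self.roi_pad, self.input_size) for s in self.val_samples]
        items = [it for it in items if it is not None]
        if not items:
            raise ValueError("validation split has no samples with foreground")
        return items


class StudentModel(_BaseTrainer):
    """Full-size student, optionally distilling from a frozen teacher.

    With every stage at γ=0 this is exactly the no-distillation baseline; the
    teacher may then be omitted.  The teacher's parameters are never updated.
    """

    role = "student"

    def __init__(
        self,
        train_samples,
        val_samples,
        teacher: Segmenter | str | Path | None = None,
        kd_support: str = "roi",
        **kwargs,
    ):
        super().__init__(train_samples, val_samples, **kwargs)
        if kd_support not in ("roi", "full"):
            raise ValueError("kd_support must be 'roi' or 'full'")
        self.kd_support = kd_support
        needs_teacher = any(s.weights.gamma > 0 for s in self.stages)
        if needs_teacher and teacher is None:
            raise ValueError("a teacher checkpoint is required when any stage has gamma > 0")
        if teacher is not None and not isinstance(teacher, Segmenter):
            teacher = load_checkpoint(teacher)[0]
        self.teacher = teacher

    def _default_stages(self):
        return default_student_stages()

    @classmethod
    def from_manifest(cls, manifest: str | Path, teacher=None, **kwargs) -> "StudentModel":
        return cls(
            load_split(manifest, "train"), load_split(manifest, "val"), teacher=teacher, **kwargs
        )

    def _train_items(self, samples, weights, rng):
        items = []
        for s in samples:
            aug = augment(s, self.augment_config, rng) if self.augment_config else s
            items.append(
                _student_item(
                    aug, self.teacher, weights.gamma, self.roi_pad, self.kd_support,
                    self.augment_config, rng, base_sample=s,
                )
            )
        return items

    def _val_items(self, weights):
        return [
            _student_item(s, self.teacher, weights.gamma, self.roi_pad, self.kd_support, None, None)
            for s in self.val_samples
        ]


def train_teacher(
    manifest: str | Path,
    model_config: ModelConfig | None = None,
    stage_configs: tuple[StageConfig, StageConfig] | None = None,
    out_path: str | Path = "teacher.npz",
    augment_config: AugmentConfig | None = None,
    roi_pad: int = 50,
    log_path: str | Path | None = None,
    verbose: bool = False,
) -> Path:
    """Train the ROI-crop teacher from a dataset manifest; writes a checkpoint."""
    trainer = TeacherModel.from_manifest(
        manifest, model_config=model_config, stages=stage_configs,
        augment_config=augment_config, roi_pad=roi_pad,
    )
    results = trainer.fit(log_path=log_path, verbose=verbose)
    return results.save(out_path)


def train_student(
    manifest: str | Path,
    teacher_checkpoint: str | Path | None,
    model_config: ModelConfig | None = None,
    stage_configs: tuple[StageConfig, StageConfig] | None = None,
    out_path: str | Path = "student.npz",
    augment_config: AugmentConfig | None = None,
    roi_pad: int = 50,
    kd_support: str = "roi",
    log_path: str | Path | None = None,
    verbose: bool = False,
) -> Path:
    """Train the full-size student (γ=0 everywhere ⇒ the baseline model)."""
    trainer = StudentModel.from_manifest(
        manifest, teacher=teacher_checkpoint, model_config=model_config,
        stages=stage_configs, augment_config=augment_config, roi_pad=roi_pad,
        kd_support=kd_support,
    )
    results = trainer.fit(log_path=log_path, verbose=verbose)
    return results.save(out_path)
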