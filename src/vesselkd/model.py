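"""Configurable encoder–decoder segmentation network.

A DeepLab-flavoured architecture at desk scale: a strided convolutional
encoder, an optional atrous spatial pyramid (parallel dilated convolutions,
concatenated and projected) at the bottleneck, and a decoder that upsamples
back to full resolution with skip connections from each encoder stage.
Teacher and student use the same architecture.  The full-scale Xception
backbone and external pretraining of the original design are deliberately
replaced by this small randomly initialised encoder: the object of study is
the training scheme, not the backbone.

Output logits always match the input resolution, which the pixel-aligned
distillation requires; inputs must be divisible by 2**depth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _nn

__all__ = [
    "ModelConfig",
    "Segmenter",
    "build_segmenter",
    "set_backbone_frozen",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    num_classes: int = 4
    base_width: int = 16
    depth: int = 3
    use_aspp: bool = True
    aspp_rates: tuple[int, ...] = (2, 4, 8)
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("num_classes must be ≥ 2 (background + foreground)")
        if self.depth < 1:
            raise ValueError("depth must be ≥ 1")
        if self.base_width < 2:
            raise ValueError("base_width must be ≥ 2")
        if self.use_aspp and len(self.aspp_rates) == 0:
            raise ValueError("aspp_rates must be non-empty when use_aspp")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        d = json.loads(text)
        d["aspp_rates"] = tuple(d["aspp_rates"])
        return cls(**d)


class _ASPP(_nn.Module):
    """Atrous pyramid: 1×1 branch + one 3×3 branch per dilation rate."""

    def __init__(self, channels: int, rates: tuple[int, ...], rng, dtype):
        branch_ch = max(channels // (len(rates) + 1), 4)
        self.branches = [_nn.conv_block(channels, branch_ch, k=1, rng=rng, dtype=dtype)]
        self.branches += [
            _nn.conv_block(channels, branch_ch, k=3, dilation=r, rng=rng, dtype=dtype)
            for r in rates
        ]
        self.project = _nn.conv_block(
            branch_ch * len(self.branches), channels, k=1, rng=rng, dtype=dtype
        )
        self._split = branch_ch

    def params(self):
        return [p for b in self.branches for p in b.params()] + self.project.params()

    def forward(self, x):
        outs = [b.forward(x) for b in self.branches]
        return self.project.forward(np.concatenate(outs, axis=1))

    def backward(self, dy):
        g = self.project.backward(dy)
        dx = None
        for i, b in enumerate(self.branches):
            gi = g[:, i * self._split : (i + 1) * self._split]
            d = b.backward(np.ascontiguousarray(gi))
            dx = d if dx is None else dx + d
        return dx


class Segmenter:
    """Encoder–decoder network; forward/backward on (N, C, H, W) arrays."""

    def __init__(self, config: ModelConfig):
        self.config = config
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)
        w = config.base_width
        widths = [min(w << d, 8 * w) for d in range(config.depth + 1)]
        self.widths = widths

        self.stem = _nn.Sequential(
            _nn.conv_block(config.in_channels, widths[0], rng=rng, dtype=dtype),
            _nn.conv_block(widths[0], widths[0], rng=rng, dtype=dtype),
        )
        self.encoders = [
            _nn.Sequential(
                _nn.conv_block(widths[d - 1], widths[d], stride=2, rng=rng, dtype=dtype),
                _nn.conv_block(widths[d], widths[d], rng=rng, dtype=dtype),
            )
            for d in range(1, config.depth + 1)
        ]
        self.aspp = (
            _ASPP(widths[-1], config.aspp_rates, rng, dtype) if config.use_aspp else None
        )
        self.ups = [_nn.UpsampleNearest2x() for _ in range(config.depth)]
        self.decoders = [
            _nn.Sequential(
                _nn.conv_block(widths[d] + widths[d - 1], widths[d - 1], rng=rng, dtype=dtype)
            )
            for d in range(1, config.depth + 1)
        ]
        self.head = _nn.Conv2d(widths[0], config.num_classes, k=1, rng=rng, dtype=dtype)
        self._backbone = [self.stem] + self.encoders
        self._dskip_shapes = None

    # --- parameter access -------------------------------------------------
    def parameters(self) -> list[_nn.Param]:
        mods = [self.stem, *self.encoders]
        if self.aspp is not None:
            mods.append(self.aspp)
        mods += [*self.decoders, self.head]
        return [p for m in mods for p in m.params()]

    def backbone_parameters(self) -> list[_nn.Param]:
        return [p for m in self._backbone for p in m.params()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # --- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.config.dtype)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N, {self.config.in_channels}, H, W), got {x.shape}")
        div = 1 << self.config.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"input spatial size {x.shape[2:]} must be divisible by 2**depth={div}"
            )
        skips = [self.stem.forward(x)]
        for enc in self.encoders:
            skips.append(enc.forward(skips[-1]))
        h = skips[-1]
        if self.aspp is not None:
            h = self.aspp.forward(h)
        for d in range(self.config.depth, 0, -1):
            h = self.ups[d - 1].forward(h)
            h = np.concatenate([h, skips[d - 1]], axis=1)
            h = self.decoders[d - 1].forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        depth = self.config.depth
        g = self.head.backward(np.asarray(dlogits, dtype=self.config.dtype))
        dskips = [None] * depth
        for d in range(1, depth + 1):
            g = self.decoders[d - 1].backward(g)
            up_ch = self.widths[d]
            g_up, g_skip = g[:, :up_ch], g[:, up_ch:]
            dskips[d - 1] = np.ascontiguousarray(g_skip)
            g = self.ups[d - 1].backward(np.ascontiguousarray(g_up))
        if self.aspp is not None:
            g = self.aspp.backward(g)
        for d in range(depth, 0, -1):
            g = self.encoders[d - 1].backward(g)
            g = g + dskips[d - 1]
        return self.stem.backward(g)

    # --- inference --------------------------------------------------------
    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        """Forward a batch of H×W images (or N×H×W) to N×H×W×C logits."""
        arr = np.asarray(images)
        if arr.ndim == 2:
            arr = arr[None]
        logits = self.forward(arr[:, None, :, :])
        return np.ascontiguousarray(logits.transpose(0, 2, 3, 1)).astype(np.float64)

    def predict_mask(self, image: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_logits(image)[0], axis=-1).astype(np.uint8)


def build_segmenter(config: ModelConfig) -> Segmenter:
    """Build a network with deterministic seed-controlled initialisation."""
    return Segmenter(config)


def set_backbone_frozen(net: Segmenter, frozen: bool) -> None:
    """Include/exclude the encoder (stem + downsampling stages) from updates.

    The atrous pyramid, decoder and head always stay trainable.
    """
    for p in net.backbone_parameters():
        p.trainable = not frozen


def count_parameters(net: Segmenter) -> int:
    return int(sum(p.value.size for p in net.parameters()))


def save_checkpoint(net: Segmenter, path, meta: dict | None = None) -> None:
    """Self-describing checkpoint: weights + ModelConfig + stage metadata."""
    arrays = {f"p{i:04d}": p.value for i, p in enumerate(net.parameters())}
    header = json.dumps({"model_config": json.loads(net.config.to_json()), "meta": meta or {}})
    np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[Segmenter, dict]:
    """Rebuild a Segmenter from a checkpoint; returns (net, metadata)."""
    with np.load(path) as data:
        try:
            header = json.loads(bytes(data["__header__"]).decode())
        except KeyError:
            raise ValueError(f"{path} is not a vesselkd checkpoint") from None
        config = ModelConfig.from_json(json.dumps(header["model_config"]))
        net = build_segmenter(config)
        params = net.parameters()
        keys = sorted(k for k in data.files if k.startswith("p"))
        if len(keys) != len(params):
            raise ValueError(f"checkpoint {path} does not match architecture")
        for key, p in zip(keys, params):
            p.value = data[key].astype(p.value.dtype)
            p.grad = np.zeros_like(p.value)
    return net, header["meta"]
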