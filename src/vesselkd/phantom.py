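"""Synthetic three-vessel ultrasound phantoms.

Generates grayscale image / label-mask pairs that mimic the statistical
structure of a fetal-echocardiography three-vessel view: a dark speckled
field containing three bright-rimmed vessel cross-sections (pulmonary
artery, aorta, superior vena cava) of unequal size, with the SVC strictly
smallest, blurred boundaries and low contrast.  This is a stand-in for
clinical data, not an acoustic simulation: speckle is modelled as unit-mean
multiplicative gamma noise followed by a Gaussian blur, with no beamforming
or attenuation physics.

Class ids: 0 background, 1 pulmonary artery (PA), 2 aorta (AO),
3 superior vena cava (SVC).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "VesselSpec",
    "PhantomConfig",
    "ImageSample",
    "PhantomPlacementError",
    "generate_sample",
    "generate_dataset",
    "load_manifest",
    "load_sample",
    "load_split",
    "MASK_PALETTE",
]

#: Indexed-PNG palette for masks: background black, PA red, AO green, SVC yellow.
MASK_PALETTE = [(0, 0, 0), (220, 40, 40), (40, 200, 70), (230, 220, 60)]

CLASS_NAMES = {0: "background", 1: "PA", 2: "AO", 3: "SVC"}


class PhantomPlacementError(RuntimeError):
    """Raised when the three vessels cannot be placed without overlap."""


@dataclass(frozen=True)
class VesselSpec:
    """One vessel cross-section: class id, ellipse semi-axes (px), contrast.

    ``contrast`` in (0, 1] scales the brightness of the vessel above the
    background level; the rim is brighter than the interior.
    """

    class_id: int
    semi_axes: tuple[float, float]
    contrast: float

    def area(self) -> float:
        return float(np.pi * self.semi_axes[0] * self.semi_axes[1])


def _default_specs(scale: float) -> tuple[VesselSpec, ...]:
    return (
        VesselSpec(1, (46.0 * scale, 38.0 * scale), 0.55),
        VesselSpec(2, (40.0 * scale, 34.0 * scale), 0.60),
        VesselSpec(3, (24.0 * scale, 20.0 * scale), 0.50),
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom scene.

    Defaults describe a 512×512 view; :meth:`default` rescales the vessel
    sizes and blur for other image sizes.  ``speckle_scale`` is the standard
    deviation of the unit-mean multiplicative noise (0 disables it);
    ``blur_sigma`` is the Gaussian blur in pixels; ``placement_jitter`` is
    the maximal random displacement of each vessel centre.
    """

    image_size: int = 512
    vessel_specs: tuple[VesselSpec, ...] = field(default_factory=lambda: _default_specs(1.0))
    speckle_scale: float = 0.30
    blur_sigma: float = 1.5
    placement_jitter: float = 10.0
    background_level: float = 0.18
    rim_fraction: float = 0.78
    seed: int = 0

    @classmethod
    def default(cls, image_size: int = 512, seed: int = 0, **overrides) -> "PhantomConfig":
        s = image_size / 512.0
        cfg = cls(
            image_size=image_size,
            vessel_specs=_default_specs(s),
            blur_sigma=1.5 * s,
            placement_jitter=10.0 * s,
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    def validate(self) -> None:
        if len(self.vessel_specs) != 3:
            raise ValueError("exactly 3 vessel specs are required")
        ids = sorted(v.class_id for v in self.vessel_specs)
        if ids != [1, 2, 3]:
            raise ValueError(f"vessel class ids must be {{1,2,3}} once each, got {ids}")
        by_id = {v.class_id: v for v in self.vessel_specs}
        if not (by_id[3].area() < by_id[1].area() and by_id[3].area() < by_id[2].area()):
            raise ValueError("SVC (class 3) must be strictly smallest by area")
        for v in self.vessel_specs:
            if not (0.0 < v.contrast <= 1.0):
                raise ValueError(f"contrast must be in (0,1], got {v.contrast}")
            if min(v.semi_axes) < 2.0:
                raise ValueError("vessel semi-axes below 2 px render degenerately")
        if self.speckle_scale < 0 or self.blur_sigma < 0 or self.placement_jitter < 0:
            raise ValueError("noise/blur/jitter parameters must be non-negative")
        if self.image_size < 16:
            raise ValueError("image_size must be at least 16")


@dataclass
class ImageSample:
    """One grayscale image in [0,1] with its integer class mask."""

    image: np.ndarray
    mask: np.ndarray
    id: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask must share spatial dimensions")
        if self.mask.min() < 0 or self.mask.max() > 3:
            raise ValueError("mask values must lie in {0,1,2,3}")


def _ellipse_mask(size: int, cy: float, cx: float, a: float, b: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    return u * u + v * v <= 1.0


def _place_vessels(config: PhantomConfig, rng: np.random.Generator):
    """Place the three vessels roughly collinearly; returns per-vessel masks.

    The arrangement mirrors the three-vessel view: PA, AO, SVC in a row with
    decreasing calibre, small random jitter and rotation per vessel.
    Placement is retried a bounded number of times before failing.
    """
    size = config.image_size
    centres = {1: (0.54, 0.30), 2: (0.50, 0.52), 3: (0.46, 0.72)}  # (cy, cx) fractions
    order = sorted(config.vessel_specs, key=lambda v: v.class_id)
    margin = 2
    for _ in range(50):
        occupied = np.zeros((size, size), dtype=bool)
        masks: dict[int, np.ndarray] = {}
        ok = True
        for spec in order:
            fy, fx = centres[spec.class_id]
            placed = False
            for _ in range(50):
                jy, jx = rng.uniform(-1, 1, 2) * config.placement_jitter
                theta = rng.uniform(-0.45, 0.45)
                m = _ellipse_mask(size, fy * size + jy, fx * size + jx, *spec.semi_axes, theta)
                if not m.any():
                    continue
                border = np.zeros_like(m)
                border[:margin, :] = border[-margin:, :] = True
                border[:, :margin] = border[:, -margin:] = True
                if (m & border).any():
                    continue
                grown = ndimage.binary_dilation(m, iterations=margin)
                if (grown & occupied).any():
                    continue
                occupied |= grown
                masks[spec.class_id] = m
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return masks
    raise PhantomPlacementError(
        f"could not place 3 non-overlapping vessels after bounded retries; config={config}"
    )


def generate_sample(config: PhantomConfig, index: int) -> ImageSample:
    """Render phantom number ``index``; deterministic in (config.seed, index)."""
    config.validate()
    rng = np.random.default_rng([config.seed, index])
    size = config.image_size
    masks = _place_vessels(config, rng)

    image = np.full((size, size), config.background_level, dtype=np.float64)
    label = np.zeros((size, size), dtype=np.uint8)
    for spec in sorted(config.vessel_specs, key=lambda v: v.class_id):
        m = masks[spec.class_id]
        a, b = spec.semi_axes
        # rim = ellipse minus a concentric shrunken ellipse (vessel wall)
        cy, cx = ndimage.center_of_mass(m)
        inner = ndimage.binary_erosion(
            m, iterations=max(1, int(round(min(a, b) * (1.0 - config.rim_fraction))))
        )
        image[m] = config.background_level + 0.45 * spec.contrast
        image[m & ~inner] = config.background_level + 1.0 * spec.contrast
        label[m] = spec.class_id

    if config.speckle_scale > 0:
        shape = 1.0 / config.speckle_scale**2
        image = image * rng.gamma(shape, scale=1.0 / shape, size=image.shape)
    if config.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=config.blur_sigma)
    image = np.clip(image, 0.0, 1.0)
    return ImageSample(image=image, mask=label, id=f"phantom_{index:05d}")


def generate_dataset(
    config: PhantomConfig,
    n_train: int,
    n_val: int,
    n_test: int,
    out_dir: str | Path,
) -> Path:
    """Write a phantom dataset (PNG images/masks + CSV manifest) to disk.

    Returns the manifest path.  Images are 8-bit grayscale PNG; masks are
    8-bit paletted PNG whose pixel values are the class ids.  Regeneration
    with the same config is byte-identical.
    """
    if min(n_train, n_val, n_test) <= 0:
        raise ValueError("split sizes must be positive")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    palette = [c for rgb in MASK_PALETTE for c in rgb] + [0] * (768 - 3 * len(MASK_PALETTE))
    splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
    rows = []
    for index, split in enumerate(splits):
        sample = generate_sample(config, index)
        img_rel = f"images/{sample.id}.png"
        msk_rel = f"masks/{sample.id}.png"
        img8 = np.round(sample.image * 255.0).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out_dir / img_rel)
        pimg = Image.fromarray(sample.mask, mode="P")
        pimg.putpalette(palette)
        pimg.save(out_dir / msk_rel)
        rows.append((sample.id, split, img_rel, msk_rel))

    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "split", "image", "mask"])
        writer.writerows(rows)
    return manifest


def load_manifest(manifest: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest)
    missing = {"id", "split", "image", "mask"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {manifest} lacks columns {sorted(missing)}")
    return df


def load_sample(root: Path, row) -> ImageSample:
    img_path, msk_path = root / row.image, root / row.mask
    for p in (img_path, msk_path):
        if not p.exists():
            raise FileNotFoundError(f"dataset file missing for id {row.id}: {p}")
    image = np.asarray(Image.open(img_path), dtype=np.float64) / 255.0
    mask = np.asarray(Image.open(msk_path), dtype=np.uint8)
    return ImageSample(image=image, mask=mask, id=str(row.id))


def load_split(manifest: str | Path, split: str) -> list[ImageSample]:
    """Load all samples of one split (``train``/``val``/``test``) into memory."""
    manifest = Path(manifest)
    df = load_manifest(manifest)
    sub = df[df["split"] == split]
    if sub.empty:
        raise ValueError(f"split {split!r} is empty in {manifest}")
    root = manifest.parent
    return [load_sample(root, row) for row in sub.itertuples(index=False)]
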