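"""Region-of-interest crop / restore with exact coordinate bookkeeping.

The teacher network trains on the vessel region only: the tight bounding box
of all foreground pixels, padded by a fixed margin (50 px at the native
512×512 scale) on each edge, clipped at the image borders, then resized to a
square model input.  The box coordinates are recorded so crop-space logits
can be resized back and placed at the original location in the full image.

Coordinates are 0-based and half-open throughout.  Resizing uses a
half-pixel-centre mapping with edge replication; aspect ratio is *not*
preserved (each axis scales independently), and the restore step inverts the
anisotropic scaling.  When the box size equals the crop size (unit scale)
the round trip is bit-exact — the restore contract relies on this, which is
why the resampler lives here rather than behind a generic image library.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = ["RoiBox", "EmptyMaskError", "extract_roi", "crop_resize", "restore_logits"]


class EmptyMaskError(ValueError):
    """Raised when a mask has no foreground, so no ROI is definable."""


@dataclass(frozen=True)
class RoiBox:
    """Half-open crop window [row0,row1)×[col0,col1) in a full image."""

    row0: int
    col0: int
    row1: int
    col1: int
    full_height: int
    full_width: int

    def __post_init__(self):
        if not (0 <= self.row0 < self.row1 <= self.full_height):
            raise ValueError(f"invalid row bounds in {self}")
        if not (0 <= self.col0 < self.col1 <= self.full_width):
            raise ValueError(f"invalid col bounds in {self}")

    @property
    def height(self) -> int:
        return self.row1 - self.row0

    @property
    def width(self) -> int:
        return self.col1 - self.col0

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "RoiBox":
        return cls(**json.loads(text))


def extract_roi(mask: np.ndarray, pad: int = 50) -> RoiBox:
    """Tight bounding box of all nonzero pixels, padded then border-clipped."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("mask contains no foreground pixels; no ROI definable")
    h, w = mask.shape
    return RoiBox(
        row0=max(0, int(rows[0]) - pad),
        col0=max(0, int(cols[0]) - pad),
        row1=min(h, int(rows[-1]) + 1 + pad),
        col1=min(w, int(cols[-1]) + 1 + pad),
        full_height=h,
        full_width=w,
    )


def _resize(a: np.ndarray, out_h: int, out_w: int, order: int) -> np.ndarray:
    """Axis-separable resize; order 0 nearest, order 1 bilinear.

    Sample points follow the half-pixel-centre convention
    ``src = (dst + 0.5) * in/out - 0.5`` with edge replication, so an
    equal-size resize is the identity to the bit.
    """
    h, w = a.shape[:2]
    if (out_h, out_w) == (h, w):
        return a.copy()

    def axis_take(arr, coords, n, axis):
        if order == 0:
            idx = np.clip(np.floor(coords + 0.5).astype(int), 0, n - 1)
            return np.take(arr, idx, axis=axis)
        i0 = np.floor(coords).astype(int)
        frac = coords - i0
        lo = np.clip(i0, 0, n - 1)
        hi = np.clip(i0 + 1, 0, n - 1)
        shape = [1] * arr.ndim
        shape[axis] = -1
        f = frac.reshape(shape)
        return np.take(arr, lo, axis=axis) * (1.0 - f) + np.take(arr, hi, axis=axis) * f

    ry = (np.arange(out_h) + 0.5) * (h / out_h) - 0.5
    rx = (np.arange(out_w) + 0.5) * (w / out_w) - 0.5
    out = axis_take(a, ry, h, axis=0) if out_h != h else a
    out = axis_take(out, rx, w, axis=1) if out_w != w else out.copy()
    return out


def crop_resize(
    image_or_logits: np.ndarray,
    box: RoiBox,
    out_size: int = 512,
    interp: str = "bilinear",
) -> np.ndarray:
    """Crop the box out of a H×W(×C) array and resize to out_size×out_size.

    Masks should use ``interp='nearest'`` (value set is preserved),
    continuous maps ``'bilinear'``.  Each axis scales independently.
    """
    arr = np.asarray(image_or_logits)
    if arr.shape[:2] != (box.full_height, box.full_width):
        raise ValueError(
            f"array spatial size {arr.shape[:2]} does not match box "
            f"({box.full_height}, {box.full_width})"
        )
    if interp not in ("nearest", "bilinear"):
        raise ValueError("interp must be 'nearest' or 'bilinear'")
    crop = arr[box.row0 : box.row1, box.col0 : box.col1]
    return _resize(crop, out_size, out_size, order=0 if interp == "nearest" else 1)


def restore_logits(
    crop_logits: np.ndarray,
    box: RoiBox,
    fill: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Map crop-space logits back into full-image space.

    The square crop logits are resized (bilinear, per channel) to the box's
    height×width and written at the recorded location; everything outside is
    ``fill``.  Returns the full H×W×C map and a uint8 validity mask that is
    1 inside the box and 0 outside.
    """
    logits = np.asarray(crop_logits)
    if logits.ndim != 3:
        raise ValueError("crop_logits must be H×W×C")
    if logits.shape[0] != logits.shape[1]:
        raise ValueError("crop_logits must be square, as produced by crop_resize")
    restored = _resize(logits, box.height, box.width, order=1)
    full = np.full(
        (box.full_height, box.full_width, logits.shape[2]), fill, dtype=logits.dtype
    )
    full[box.row0 : box.row1, box.col0 : box.col1] = restored
    validity = np.zeros((box.full_height, box.full_width), dtype=np.uint8)
    validity[box.row0 : box.row1, box.col0 : box.col1] = 1
    return full, validity
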