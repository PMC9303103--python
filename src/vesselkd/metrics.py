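"""Overlap metrics (IoU, PA, Dice) and evaluation reports.

For a class c, S_a is the set of pixels *predicted* as c and S_b the set of
ground-truth pixels of c.  The three metrics, in percent:

    IoU  = |S_a ∩ S_b| / |S_a ∪ S_b| · 100
    PA   = |S_a ∩ S_b| / |S_a|       · 100
    Dice = 2|S_a ∩ S_b| / (|S_a| + |S_b|) · 100

PA is implemented exactly as printed — intersection over *predicted* area
(conventionally precision); fidelity to the stated formula wins over the
usual naming.  A metric whose denominator is zero is undefined and reported
as None, never silently 0 or 100.  Means are taken over the three vessel
classes only (background never enters a mean).

Two dataset aggregations are provided: ``micro`` accumulates pixel counts
over all images and applies the formulas once per class; ``per_image``
averages the defined per-image metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np

from . import phantom as _phantom

__all__ = [
    "ClassMetrics",
    "MetricsReport",
    "class_metrics",
    "report_from_pairs",
    "evaluate_dataset",
    "compare_report",
]

VESSEL_CLASSES = (1, 2, 3)
CLASS_LABELS = {1: "Pulmonary artery (PA)", 2: "Aorta (AO)", 3: "Superior vena cava (SVC)"}
METRIC_NAMES = ("iou", "pa", "dice")


class ClassMetrics(NamedTuple):
    iou: float | None
    pa: float | None
    dice: float | None


def _counts(pred: np.ndarray, gt: np.ndarray, class_id: int) -> tuple[int, int, int]:
    a = pred == class_id
    b = gt == class_id
    return int((a & b).sum()), int(a.sum()), int(b.sum())


def _from_counts(inter: int, na: int, nb: int) -> ClassMetrics:
    union = na + nb - inter
    iou = 100.0 * inter / union if union > 0 else None
    pa = 100.0 * inter / na if na > 0 else None
    dice = 200.0 * inter / (na + nb) if na + nb > 0 else None
    return ClassMetrics(iou, pa, dice)


def class_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray, class_id: int) -> ClassMetrics:
    """IoU/PA/Dice (percent) of one class for a single mask pair.

    Entries with a zero denominator are None (undefined), e.g. PA when the
    class is never predicted, or all three when it is absent from both masks.
    """
    pred, gt = np.asarray(pred_mask), np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    return _from_counts(*_counts(pred, gt, class_id))


def _mean_defined(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return sum(defined) / len(defined) if defined else None


@dataclass
class MetricsReport:
    """Per-class and mean IoU/PA/Dice over a test set, in percent."""

    per_class: dict[int, dict[str, float | None]]
    n_images: int
    aggregation: str
    mean: dict[str, float | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mean is None:
            self.mean = {
                m: _mean_defined([self.per_class[c][m] for c in VESSEL_CLASSES])
                for m in METRIC_NAMES
            }

    @classmethod
    def from_per_class(
        cls, per_class: dict[int, dict[str, float | None]], n_images: int = 0,
        aggregation: str = "micro",
    ) -> "MetricsReport":
        return cls(per_class=per_class, n_images=n_images, aggregation=aggregation)

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_class": {str(k): v for k, v in self.per_class.items()},
                "mean": self.mean,
                "n_images": self.n_images,
                "aggregation": self.aggregation,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MetricsReport":
        d = json.loads(text)
        return cls(
            per_class={int(k): v for k, v in d["per_class"].items()},
            n_images=d["n_images"],
            aggregation=d["aggregation"],
            mean=d["mean"],
        )

    def to_text(self, title: str = "Segmentation accuracy") -> str:
        def fmt(v):
            return "  n/a" if v is None else f"{v:5.1f}"

        lines = [title, f"(n={self.n_images} images, {self.aggregation} aggregation)", ""]
        lines.append(f"{'':26s}  IoU (%)  PA (%)  Dice (%)")
        for c in VESSEL_CLASSES:
            row = self.per_class[c]
            lines.append(
                f"{CLASS_LABELS[c]:26s}  {fmt(row['iou'])}    {fmt(row['pa'])}   {fmt(row['dice'])}"
            )
        lines.append(
            f"{'Mean':26s}  {fmt(self.mean['iou'])}    {fmt(self.mean['pa'])}   {fmt(self.mean['dice'])}"
        )
        return "\n".join(lines)


def report_from_pairs(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]], aggregation: str = "micro"
) -> MetricsReport:
    """Build a report from (predicted mask, ground-truth mask) pairs."""
    if aggregation not in ("micro", "per_image"):
        raise ValueError("aggregation must be 'micro' or 'per_image'")
    totals = {c: np.zeros(3, dtype=np.int64) for c in VESSEL_CLASSES}
    per_image: dict[int, dict[str, list[float]]] = {
        c: {m: [] for m in METRIC_NAMES} for c in VESSEL_CLASSES
    }
    n = 0
    for pred, gt in pairs:
        n += 1
        for c in VESSEL_CLASSES:
            inter, na, nb = _counts(np.asarray(pred), np.asarray(gt), c)
            totals[c] += (inter, na, nb)
            if aggregation == "per_image":
                cm = _from_counts(inter, na, nb)
                for m, v in zip(METRIC_NAMES, cm):
                    if v is not None:
                        per_image[c][m].append(v)
    if n == 0:
        raise ValueError("no mask pairs supplied")
    per_class: dict[int, dict[str, float | None]] = {}
    for c in VESSEL_CLASSES:
        if aggregation == "micro":
            cm = _from_counts(*totals[c])
            per_class[c] = dict(zip(METRIC_NAMES, cm))
        else:
            per_class[c] = {
                m: (sum(v) / len(v) if v else None) for m, v in per_image[c].items()
            }
    return MetricsReport(per_class=per_class, n_images=n, aggregation=aggregation)


def evaluate_dataset(
    checkpoint,
    manifest: str | Path,
    split: str = "test",
    aggregation: str = "micro",
) -> MetricsReport:
    """Evaluate a trained network (or checkpoint path) on one dataset split."""
    from . import model as _model

    if hasattr(checkpoint, "predict_mask"):
        net = checkpoint
    else:
        net, _ = _model.load_checkpoint(checkpoint)
    samples = _phantom.load_split(manifest, split)
    return report_from_pairs(
        ((net.predict_mask(s.image), s.mask) for s in samples), aggregation
    )


@dataclass
class ComparisonTable:
    """Method × metric matrix of mean vessel accuracies plus pairwise deltas."""

    means: dict[str, dict[str, float | None]]
    deltas: dict[tuple[str, str], dict[str, float | None]]
    text: str


def compare_report(reports: dict[str, MetricsReport]) -> ComparisonTable:
    """Tabulate ≥2 named reports and their pairwise mean-metric deltas.

    ``deltas[(a, b)][metric]`` is mean(b) − mean(a) for each ordered pair in
    listing order, so later-listed methods show their gain over earlier ones.
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    names = list(reports)
    means = {name: dict(reports[name].mean) for name in names}
    deltas: dict[tuple[str, str], dict[str, float | None]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            deltas[(a, b)] = {
                m: (
                    means[b][m] - means[a][m]
                    if means[a][m] is not None and means[b][m] is not None
                    else None
                )
                for m in METRIC_NAMES
            }

    def fmt(v, signed=False):
        if v is None:
            return "  n/a"
        return f"{v:+5.1f}" if signed else f"{v:5.1f}"

    width = max(len(n) for n in names) + 2
    lines = [f"{'':{width}s}  mIoU (%)  mPA (%)  mDice (%)"]
    for name in names:
        row = means[name]
        lines.append(
            f"{name:{width}s}  {fmt(row['iou'])}     {fmt(row['pa'])}    {fmt(row['dice'])}"
        )
    lines.append("")
    for (a, b), d in deltas.items():
        lines.append(
            f"{b} - {a}: ΔmIoU {fmt(d['iou'], True)}, ΔmPA {fmt(d['pa'], True)}, "
            f"ΔmDice {fmt(d['dice'], True)}"
        )
    return ComparisonTable(means=means, deltas=deltas, text="\n".join(lines))
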