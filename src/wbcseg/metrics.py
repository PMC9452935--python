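"""Segmentation evaluation: Dice, IoU, PPV, sensitivity and Hausdorff
distance, with per-image and dataset-mean aggregation.

With A the predicted foreground pixel set and B the ground truth:

    Dice = 2|A∩B| / (|A|+|B|)      IoU = |A∩B| / |A∪B|
    PPV  = |A∩B| / |A|             SE  = |A∩B| / |B|
    HD   = max_{a∈A} min_{b∈B} d(a, b)   (Euclidean, in pixels)

Empty-mask conventions (documented, deliberate): the four ratio metrics
are 1 when both masks are empty and 0 when exactly one is.  The directed
Hausdorff distance is undefined on empty masks and raises; the dataset
aggregator substitutes 0 when both are empty and the image diagonal when
exactly one is, so reports stay finite.  "mIOU" here is the foreground IoU
averaged over images.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import directed_hausdorff

_FIELDS = ("dice", "miou", "ppv", "sensitivity", "hd")


def _as_bool(mask) -> np.ndarray:
    m = np.asarray(mask)
    if not np.isin(m, (0, 1, False, True)).all():
        raise ValueError("mask must be binary")
    return m.astype(bool)


def _pair(a, b):
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a, b


def _ratio(num: float, den: float, a_any: bool, b_any: bool) -> float:
    if not a_any and not b_any:
        return 1.0
    if den == 0:
        return 0.0
    return num / den


def dice(a, b) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|); A = prediction, B = ground truth."""
    a, b = _pair(a, b)
    inter = np.logical_and(a, b).sum()
    return _ratio(2.0 * inter, float(a.sum() + b.sum()), a.any(), b.any())


def miou(a, b) -> float:
    """Foreground intersection-over-union |A∩B|/|A∪B|."""
    a, b = _pair(a, b)
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return _ratio(float(inter), float(union), a.any(), b.any())


def ppv(a, b) -> float:
    """Positive predictive value |A∩B|/|A| (foreground precision)."""
    a, b = _pair(a, b)
    inter = np.logical_and(a, b).sum()
    return _ratio(float(inter), float(a.sum()), a.any(), b.any())


def sensitivity(a, b) -> float:
    """Sensitivity |A∩B|/|B| (foreground recall)."""
    a, b = _pair(a, b)
    inter = np.logical_and(a, b).sum()
    return _ratio(float(inter), float(b.sum()), a.any(), b.any())


def hausdorff(a, b) -> float:
    """Directed Hausdorff distance max_{a∈A} min_{b∈B} d(a,b) in pixels."""
    a, b = _pair(a, b)
    if not a.any() or not b.any():
        raise ValueError("hausdorff distance is undefined for an empty mask")
    return float(directed_hausdorff(np.argwhere(a), np.argwhere(b))[0])


def hausdorff_symmetric(a, b) -> float:
    """Symmetric variant max(h(A,B), h(B,A))."""
    return max(hausdorff(a, b), hausdorff(b, a))


def _hd_with_convention(a, b) -> float:
    a_any, b_any = np.asarray(a).astype(bool).any(), np.asarray(b).astype(bool).any()
    if a_any and b_any:
        return hausdorff(a, b)
    if not a_any and not b_any:
        return 0.0
    return float(np.hypot(*np.asarray(a).shape))


@dataclass
class MetricsReport:
    """Dataset-mean metrics plus the per-image values they average."""

    dice: float
    miou: float
    ppv: float
    sensitivity: float
    hd: float
    per_image: list = field(default_factory=list)
    n_images: int = 0

    def to_json(self, path=None) -> str:
        payload = {k: getattr(self, k) for k in _FIELDS}
        payload["n_images"] = self.n_images
        payload["per_image"] = self.per_image
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(("image",) + _FIELDS)
            for i, row in enumerate(self.per_image):
                w.writerow([i] + [row[k] for k in _FIELDS])
            w.writerow(["mean"] + [getattr(self, k) for k in _FIELDS])


def evaluate_pair(pred, gt) -> dict:
    """All five metrics for one predicted/ground-truth mask pair."""
    return {
        "dice": dice(pred, gt),
        "miou": miou(pred, gt),
        "ppv": ppv(pred, gt),
        "sensitivity": sensitivity(pred, gt),
        "hd": _hd_with_convention(pred, gt),
    }


def evaluate_dataset(preds, gts) -> MetricsReport:
    """Per-image metrics and their arithmetic means over the dataset."""
    preds, gts = list(preds), list(gts)
    if not preds:
        raise ValueError("evaluate_dataset needs at least one mask pair")
    if len(preds) != len(gts):
        raise ValueError(f"{len(preds)} predictions vs {len(gts)} ground truths")
    per_image = [evaluate_pair(p, g) for p, g in zip(preds, gts)]
    means = {k: float(np.mean([r[k] for r in per_image])) for k in _FIELDS}
    return MetricsReport(per_image=per_image, n_images=len(per_image), **means)
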