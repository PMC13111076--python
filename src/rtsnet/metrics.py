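"""Dice loss, deep-supervision objective, and the segmentation metric suite.

Metrics follow the standard confusion-count definitions

.. math::

    IoU = TP/(TP+FP+FN), \\quad Dice = 2TP/(2TP+FP+FN),
    \\quad Acc = (TP+TN)/N,

F1 as the harmonic mean of precision and recall, the 95th-percentile
Hausdorff distance between 4-connected mask boundaries, and a rank-based
(Mann-Whitney) pixel AUC.

Two aggregation modes are reported side by side: the mean of per-image
values, and the value recomputed from dataset-pooled confusion counts.
(Mean-per-image Dice and pooled-count F1 are the pair under which the two
columns of a benchmark table differ even though Dice == F1 holds exactly
for any single confusion vector.)
"""

from __future__ import annotations

import json
import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from . import nn
from .errors import ShapeError, UndefinedMetricError

EPS_DICE = 1e-6
_CROSS = ndimage.generate_binary_structure(2, 1)   # 4-connectivity


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------

def dice_loss(p, g, eps: float = EPS_DICE):
    """Soft Dice loss ``1 - 2*sum(p*g) / (sum(p) + sum(g) + eps)``.

    Accepts either autodiff tensors (returns a scalar Tensor for training)
    or plain arrays (returns a float).
    """
    if isinstance(p, nn.Tensor):
        gt = g if isinstance(g, nn.Tensor) else nn.Tensor(
            np.asarray(g, dtype=p.data.dtype))
        if p.shape != gt.shape:
            raise ShapeError(f"dice_loss shapes differ: {p.shape} vs {gt.shape}")
        inter = (p * gt).sum()
        return 1.0 - (2.0 * inter) / (p.sum() + gt.sum() + eps)
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ShapeError(f"dice_loss shapes differ: {p.shape} vs {g.shape}")
    return float(1.0 - 2.0 * (p * g).sum() / (p.sum() + g.sum() + eps))


def total_loss(out, g, eps: float = EPS_DICE):
    """Deep-supervision objective: equal-weight mean of the Dice loss of the
    four segmentation heads (sigmoid of each head's logits) against ``g``."""
    heads = out.head_logits if hasattr(out, "head_logits") else out
    terms = [dice_loss(nn.sigmoid(h), g, eps) for h in heads]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


# --------------------------------------------------------------------------
# confusion counts and count-based metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN, self.TN + other.TN)

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def confusion(pred, g) -> ConfusionCounts:
    pred = np.asarray(pred)
    g = np.asarray(g)
    if pred.shape != g.shape:
        raise ShapeError(f"confusion shapes differ: {pred.shape} vs {g.shape}")
    if not np.isin(pred, (0, 1)).all() or not np.isin(g, (0, 1)).all():
        raise ValueError("confusion requires binary {0,1} masks")
    p = pred.astype(bool)
    t = g.astype(bool)
    return ConfusionCounts(TP=int(np.sum(p & t)), FP=int(np.sum(p & ~t)),
                           FN=int(np.sum(~p & t)), TN=int(np.sum(~p & ~t)))


def _ratio(num: int, den: int, c: ConfusionCounts) -> float:
    # empty-union convention: a 0/0 metric is 1 iff both masks are empty
    if den == 0:
        return 1.0 if (c.TP + c.FP + c.FN) == 0 else 0.0
    return num / den


def iou(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FP + c.FN, c)


def dice_coef(c: ConfusionCounts) -> float:
    return _ratio(2 * c.TP, 2 * c.TP + c.FP + c.FN, c)


def accuracy(c: ConfusionCounts) -> float:
    return _ratio(c.TP + c.TN, c.total, c)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FP, c)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.TP, c.TP + c.FN, c)


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    if p + r == 0:
        return 1.0 if (c.TP + c.FP + c.FN) == 0 else 0.0
    return 2 * p * r / (p + r)


# --------------------------------------------------------------------------
# boundary distance
# --------------------------------------------------------------------------

def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (image border counts as
    background). Returns an (M, 2) array of (row, col) coordinates."""
    fg = np.asarray(mask).astype(bool)
    if not fg.any():
        return np.empty((0, 2), dtype=int)
    inner = ndimage.binary_erosion(fg, structure=_CROSS, border_value=0)
    return np.argwhere(fg & ~inner)


def hd95(pred, g) -> float:
    """95th-percentile symmetric boundary distance, in pixels.

    Both masks empty -> 0; exactly one empty -> the image diagonal
    (sentinel for a completely missed / hallucinated structure).
    Percentiles use linear interpolation between order statistics.
    """
    pred = np.asarray(pred).astype(bool)
    g = np.asarray(g).astype(bool)
    if pred.shape != g.shape:
        raise ShapeError(f"hd95 shapes differ: {pred.shape} vs {g.shape}")
    pe, ge = pred.any(), g.any()
    if not pe and not ge:
        return 0.0
    if pe != ge:
        H, W = pred.shape
        return float(np.hypot(H, W))
    bp = np.zeros_like(pred)
    bg_ = np.zeros_like(g)
    pb = boundary_pixels(pred)
    gb = boundary_pixels(g)
    bp[pb[:, 0], pb[:, 1]] = True
    bg_[gb[:, 0], gb[:, 1]] = True
    # directed distances via the EDT of the complement of the other boundary
    dt_g = ndimage.distance_transform_edt(~bg_)
    dt_p = ndimage.distance_transform_edt(~bp)
    d_pg = dt_g[pb[:, 0], pb[:, 1]]
    d_gp = dt_p[gb[:, 0], gb[:, 1]]
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)))


# --------------------------------------------------------------------------
# AUC
# --------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC over a pooled pixel set; ties get
    midranks, so constant scores give exactly 0.5."""
    def _pool(x, dtype=None):
        if isinstance(x, (list, tuple)):
            return np.concatenate([np.asarray(v, dtype=dtype).ravel() for v in x])
        return np.asarray(x, dtype=dtype).ravel()

    s = _pool(scores, np.float64)
    y = _pool(labels)
    if s.shape != y.shape:
        raise ShapeError(f"auc shapes differ: {s.shape} vs {y.shape}")
    pos = y == 1
    P = int(pos.sum())
    N = int(y.size - P)
    if P == 0 or N == 0:
        raise UndefinedMetricError("AUC is undefined on a single-class pool")
    ranks = rankdata(s)                       # midranks
    return float((ranks[pos].sum() - P * (P + 1) / 2) / (P * N))


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

PER_IMAGE_FIELDS = ["iou", "dice", "accuracy", "precision", "recall", "f1",
                    "hd95", "auc"]


@dataclass
class MetricsReport:
    per_image: list[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = _csv.DictWriter(fh, fieldnames=["index"] + PER_IMAGE_FIELDS)
            w.writeheader()
            for i, row in enumerate(self.per_image):
                w.writerow({"index": i, **{k: row.get(k, "") for k in
                                           PER_IMAGE_FIELDS}})

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.aggregates, indent=2))


def evaluate_metrics(scores: list[np.ndarray], gts: list[np.ndarray],
                     threshold: float = 0.5) -> MetricsReport:
    """Score a set of probability maps against binary ground-truth masks.

    Per-image AUC is skipped (NaN) for single-class images; the pooled AUC
    uses every pixel of the set.
    """
    per_image = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for s, g in zip(scores, gts):
        s = np.asarray(s, dtype=np.float64)
        g = np.asarray(g)
        pred = (s > threshold).astype(np.uint8)
        c = confusion(pred, g)
        pooled = pooled + c
        try:
            a = auc(s, g)
        except UndefinedMetricError:
            a = float("nan")
        per_image.append({"iou": iou(c), "dice": dice_coef(c),
                          "accuracy": accuracy(c), "precision": precision(c),
                          "recall": recall(c), "f1": f1(c),
                          "hd95": hd95(pred, g), "auc": a})
    mean_mode = {k: float(np.nanmean([r[k] for r in per_image]))
                 for k in PER_IMAGE_FIELDS}
    pooled_mode = {"iou": iou(pooled), "dice": dice_coef(pooled),
                   "accuracy": accuracy(pooled), "precision": precision(pooled),
                   "recall": recall(pooled), "f1": f1(pooled)}
    try:
        pooled_mode["auc"] = auc(np.concatenate([np.ravel(s) for s in scores]),
                                 np.concatenate([np.ravel(g) for g in gts]))
    except (UndefinedMetricError, ValueError):
        pooled_mode["auc"] = float("nan")
    aggregates = {"mean_per_image": mean_mode, "pooled": pooled_mode,
                  "n_images": len(per_image)}
    return MetricsReport(per_image=per_image, aggregates=aggregates)
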