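"""Compound BCE + Dice training loss and overlap evaluation metrics.

Training optimises L = lambda1 * L_BCE + lambda2 * L_Dice with
lambda1 = 0.5, lambda2 = 1:

  L_BCE  = -(1/N) sum_i [ t_i log o_i + (1 - t_i) log(1 - o_i) ]
  L_Dice = 1 - (2 sum o_i t_i + eps) / (sum o_i + sum t_i + eps)

over probability maps o and binary masks t.  Evaluation binarises o at 0.5
and reports, from the pixel confusion counts,

  IoU  = TP / (TP + FP + FN)        Dice = 2 TP / (FP + 2 TP + FN)

computed per image and averaged.  Empty-versus-empty masks score 1.0 (a
correctly predicted lesion-free patch is a perfect prediction).
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

EPSILON = 1e-5
THRESHOLD = 0.5


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 0.5   # BCE weight
    lambda2: float = 1.0   # Dice weight
    epsilon: float = EPSILON

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass(frozen=True)
class ContingencyCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def _pair(o, t):
    od = o.data if isinstance(o, Tensor) else np.asarray(o, dtype=np.float64)
    td = t.data if isinstance(t, Tensor) else np.asarray(t, dtype=np.float64)
    if od.shape != td.shape:
        raise ValueError(f"shape mismatch: {od.shape} vs {td.shape}")
    o = o if isinstance(o, Tensor) else Tensor(od)
    t = t if isinstance(t, Tensor) else Tensor(td)
    return o, t


def bce_loss(o, t, epsilon=EPSILON):
    """Mean binary cross-entropy of probabilities o against binary t."""
    o, t = _pair(o, t)
    oc = o.clip(epsilon, 1.0 - epsilon)
    ll = t * oc.log() + (1.0 - t) * (1.0 - oc).log()
    return -ll.mean()


def dice_loss(o, t, epsilon=EPSILON):
    """Soft Dice loss; 0 for a perfect binary match, in [0, 1]."""
    o, t = _pair(o, t)
    inter = (o * t).sum()
    denom = o.sum() + t.sum()
    return 1.0 - (2.0 * inter + epsilon) / (denom + epsilon)


def combined_loss(o, t, weights: LossWeights = LossWeights()):
    """lambda1 * BCE + lambda2 * Dice."""
    return (weights.lambda1 * bce_loss(o, t, weights.epsilon)
            + weights.lambda2 * dice_loss(o, t, weights.epsilon))


def confusion_counts(pred_mask, true_mask):
    """Pixel confusion tallies between two binary masks."""
    p = np.asarray(pred_mask)
    t = np.asarray(true_mask)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    for name, a in (("pred", p), ("true", t)):
        if not np.isin(a, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary")
    p = p.astype(bool)
    t = t.astype(bool)
    return ContingencyCounts(tp=int((p & t).sum()),
                             fp=int((p & ~t).sum()),
                             fn=int((~p & t).sum()))


def evaluate_counts(c: ContingencyCounts):
    """(IoU, Dice) from confusion counts; empty-vs-empty scores (1, 1).

    The ratios are exact: their denominators vanish only in the
    empty-vs-empty case, which the convention above already covers, and
    exactness preserves the identity Dice = 2 IoU / (1 + IoU).
    """
    if c.tp == 0 and c.fp == 0 and c.fn == 0:
        return 1.0, 1.0
    iou = c.tp / (c.tp + c.fp + c.fn)
    dice = 2 * c.tp / (c.fp + 2 * c.tp + c.fn)
    return float(iou), float(dice)


def evaluate_batch(probs, true_masks, ids=None, threshold=THRESHOLD):
    """Per-image IoU/Dice rows for a batch of probability maps.

    Returns a list of dicts (id, iou, dice); prediction = probs >= threshold.
    """
    probs = np.asarray(probs)
    true_masks = np.asarray(true_masks)
    if probs.shape != true_masks.shape:
        raise ValueError("probability and mask batches must align")
    rows = []
    for i in range(probs.shape[0]):
        pred = (probs[i] >= threshold).astype(np.uint8)
        iou, dice = evaluate_counts(
            confusion_counts(pred, true_masks[i].astype(np.uint8)))
        rows.append({"id": ids[i] if ids is not None else str(i),
                     "iou": iou, "dice": dice})
    return rows


def summarize(rows):
    """Dataset-level means of the per-image metric rows."""
    return {"mean_iou": float(np.mean([r["iou"] for r in rows])),
            "mean_dice": float(np.mean([r["dice"] for r in rows])),
            "n_images": len(rows)}


def write_report(rows, csv_path, json_path=None):
    """Serialise per-image metrics as CSV and the means as JSON."""
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["id", "iou", "dice"])
        writer.writeheader()
        writer.writerows(rows)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(summarize(rows), fh, indent=2)
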