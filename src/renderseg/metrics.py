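"""Region and boundary evaluation metrics.

Region metrics derive from the thresholded confusion counts: Dice similarity
coefficient ``2TP/(2TP+FP+FN)``, precision, recall, and the recall-weighted
``F2 = 5TP/(5TP+4FN+FP)``.  Boundary accuracy is the symmetric Hausdorff
distance in pixels between mask boundaries, with an optional 95th-percentile
variant; boundaries are foreground pixels with at least one background
4-neighbour (erosion difference with the cross structuring element).

Degenerate-case conventions (stated because they matter for averaging over
slices that may contain no lesion): both masks empty => perfect agreement
(ratio metrics 1, HD 0); exactly one empty => ratio metrics 0 and HD equal
to the image diagonal.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

#: 4-connectivity cross used for boundary extraction.
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred, mask, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts after thresholding `pred` (>= threshold => foreground)."""
    pred = np.asarray(pred, dtype=float)
    mask = np.asarray(mask)
    if pred.shape != mask.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {mask.shape}")
    p = pred >= threshold
    g = mask.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)), tn=int(np.sum(~p & ~g)))


def _ratio(num: int, den: int, empty_value: float) -> float:
    return float(num) / den if den else empty_value


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient (F1); 1.0 when both masks are empty."""
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, 1.0)


def precision(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fp, 1.0 if c.fn == 0 else 0.0)


def recall(c: ConfusionCounts) -> float:
    return _ratio(c.tp, c.tp + c.fn, 1.0 if c.fp == 0 else 0.0)


def f2(c: ConfusionCounts) -> float:
    """Recall-weighted F-score: 5TP / (5TP + 4FN + FP)."""
    return _ratio(5 * c.tp, 5 * c.tp + 4 * c.fn + c.fp, 1.0)


def boundary_set(mask) -> np.ndarray:
    """Boundary pixels of a binary mask: foreground with a background 4-neighbour.

    Returns an (n, 2) array of (row, col) coordinates.
    """
    mask = np.asarray(mask).astype(bool)
    eroded = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(a: np.ndarray, b: np.ndarray, percentile: float = 100.0) -> float:
    """Symmetric Hausdorff distance (Euclidean, pixels) between point sets.

    `a`, `b`: (n, 2) coordinate arrays (e.g. from :func:`boundary_set`).
    ``percentile < 100`` gives the robust variant (e.g. HD95) computed on
    the pooled directed nearest-neighbour distances.  Conventions: both
    empty => 0; exactly one empty => inf (callers bound it by the image
    diagonal).
    """
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    if len(a) == 0 and len(b) == 0:
        return 0.0
    if len(a) == 0 or len(b) == 0:
        return float("inf")
    if percentile >= 100.0:
        return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    # robust variant: percentile over both directed distance pools
    from scipy.spatial import cKDTree

    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), percentile))


def hausdorff_masks(pred, mask, threshold: float = 0.5,
                    percentile: float = 100.0) -> float:
    """Hausdorff distance between the boundaries of two masks.

    One empty mask yields the image-diagonal convention; both empty yield 0.
    """
    pred = np.asarray(pred, dtype=float)
    mask = np.asarray(mask)
    pb = boundary_set(pred >= threshold)
    gb = boundary_set(mask)
    hd = hausdorff(pb, gb, percentile=percentile)
    if np.isinf(hd):
        return float(np.hypot(*mask.shape))
    return hd


def evaluate(preds, masks, threshold: float = 0.5,
             hd_percentile: float = 100.0) -> tuple[pd.DataFrame, dict]:
    """Score a list of probability maps against binary masks.

    Returns a per-sample frame (dsc, hd, f2, precision, recall) and a
    summary dict of per-slice means, matching how dataset scores are
    reported (mean over slices).
    """
    rows = []
    for i, (p, g) in enumerate(zip(preds, masks)):
        c = confusion(p, g, threshold)
        rows.append({
            "sample_id": i,
            "dsc": dsc(c),
            "hd": hausdorff_masks(p, g, threshold, hd_percentile),
            "f2": f2(c),
            "precision": precision(c),
            "recall": recall(c),
        })
    frame = pd.DataFrame(rows)
    summary = {k: float(frame[k].mean())
               for k in ("dsc", "hd", "f2", "precision", "recall")}
    return frame, summary


def overlay(pred, mask, image=None, threshold: float = 0.5) -> np.ndarray:
    """RGB overlay: red = correct (TP), blue = insufficient (FN), green = excessive (FP)."""
    pred = np.asarray(pred, dtype=float) >= threshold
    mask = np.asarray(mask).astype(bool)
    H, W = mask.shape
    if image is None:
        rgb = np.zeros((H, W, 3))
    else:
        img = np.asarray(image, dtype=float)
        rgb = np.repeat(img[:, :, None], 3, axis=2)
    rgb[pred & mask] = [1.0, 0.0, 0.0]
    rgb[~pred & mask] = [0.0, 0.0, 1.0]
    rgb[pred & ~mask] = [0.0, 1.0, 0.0]
    return rgb


def write_report(frame: pd.DataFrame, summary: dict, out_dir: str | Path) -> Path:
    """Write the per-sample CSV plus a one-row summary CSV; returns the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / "per_sample.csv", index=False)
    pd.DataFrame([summary]).to_csv(out_dir / "summary.csv", index=False)
    return out_dir
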