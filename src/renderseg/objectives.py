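"""Combined training objective: Dice loss + level-wise point supervision.

The fused full-resolution probability map is supervised with a smoothed
Dice loss,

    L_dice(p, g) = 1 - (2 sum p_i g_i + delta) / (sum p_i^2 + sum g_i^2 + delta),

and every render level contributes a binary cross-entropy computed only at
that level's selected points,

    L_total = L_dice(fused, mask) + lambda * sum_levels L_bce(points),

with ``lambda = 0.7`` by default.  The per-level BCE is averaged over its
points so that lambda's meaning does not depend on the point budget.  The
cross-entropy uses the standard orientation ``-(g log p + (1-g) log(1-p))``
with predictions clipped to ``[eps, 1-eps]``; point targets at non-integer
sample positions are bilinear samples of the binary mask (soft targets),
under the same half-pixel coordinate convention as the decoder.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from .autograd import Tensor

BCE_EPS = 1e-7


@dataclasses.dataclass(frozen=True)
class LossConfig:
    """Weights of the combined objective.

    lambda_point: weight of the summed per-level point BCE terms.
    delta: Dice smoothing constant (also defines the empty-mask behaviour).
    """

    lambda_point: float = 0.7
    delta: float = 1.0

    def __post_init__(self):
        if self.lambda_point < 0 or self.delta <= 0:
            raise ValueError("lambda_point must be >= 0 and delta > 0")


@dataclasses.dataclass
class PointTargets:
    """One render level's point supervision pair: predictions and targets."""

    predictions: Tensor      # (B, P) or (P,) mixer outputs
    targets: np.ndarray      # matching ground-truth values in [0, 1]


def _maybe_float(out: Tensor, like) -> Tensor | float:
    return out if isinstance(like, Tensor) else out.item()


def dice_loss(p, g, delta: float = 1.0):
    """Smoothed soft Dice loss over all pixels; in [0, 1).

    Returns a float for array inputs, a graph-attached tensor for tensors.
    """
    pt = ag.as_tensor(p)
    gt = ag.as_tensor(g)
    if pt.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pt.shape} vs {gt.shape}")
    num = 2.0 * (pt * gt).sum() + delta
    den = (pt ** 2.0).sum() + (gt ** 2.0).sum() + delta
    return _maybe_float(1.0 - num / den, p)


def point_bce(p, g, eps: float = BCE_EPS):
    """Mean binary cross-entropy over points, standard orientation.

    ``-(g log p + (1-g) log(1-p))`` with p clipped into [eps, 1-eps];
    targets g may be soft (bilinear mask samples).
    """
    pt = ag.as_tensor(p)
    gt = ag.as_tensor(g)
    if pt.shape != gt.shape:
        raise ValueError(f"length mismatch: {pt.shape} vs {gt.shape}")
    pc = pt.clip(eps, 1.0 - eps)
    loss = -(gt * pc.log() + (1.0 - gt) * (1.0 - pc).log()).mean()
    return _maybe_float(loss, p)


def sample_point_targets(mask: np.ndarray, norm_y: np.ndarray,
                         norm_x: np.ndarray) -> np.ndarray:
    """Bilinear samples of a binary mask at normalised positions.

    mask: (H, W) or (B, H, W); positions (P,) or (B, P).  Non-integer
    positions yield soft targets in [0, 1].
    """
    mask = np.asarray(mask, dtype=float)
    if mask.ndim == 2:
        mask = mask[None]
    grid = Tensor(mask[:, None])
    out = ag.bilinear_sample(grid, norm_y, norm_x)     # (B, 1, P)
    vals = out.data[:, 0]
    return vals[0] if vals.shape[0] == 1 and np.ndim(norm_y) == 1 else vals


def total_loss(fused, mask, per_level: list[PointTargets],
               cfg: LossConfig = LossConfig()):
    """Dice on the fused map plus lambda-weighted per-level point BCE.

    Returns ``(total, components)`` where components maps ``"dice"`` and
    ``"bce_level{i}"`` to plain floats for logging.  Levels with no points
    contribute nothing.
    """
    total = dice_loss(ag.as_tensor(fused), ag.as_tensor(mask), delta=cfg.delta)
    components = {"dice": total.item()}
    for i, lvl in enumerate(per_level):
        if lvl.predictions is None or ag.as_tensor(lvl.predictions).data.size == 0:
            components[f"bce_level{i}"] = 0.0
            continue
        bce = point_bce(ag.as_tensor(lvl.predictions), lvl.targets)
        components[f"bce_level{i}"] = bce.item()
        total = total + cfg.lambda_point * bce
    components["total"] = total.item()
    return _maybe_float(total, fused), components
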