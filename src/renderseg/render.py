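"""Uncertainty-driven point-rendering decoder.

Each render level doubles the resolution of the running coarse probability
map by bilinear interpolation, then repairs only its most ambiguous pixels:

1. uncertainty map ``M_u = |p - p_thd|`` (small = uncertain, default
   ``p_thd = 0.5``);
2. point selection — in training, oversample ``k*N`` random candidate
   pixels, keep the ``beta*N`` most uncertain, fill the remaining
   ``(1-beta)*N`` with fresh random positions; in inference, take the ``N``
   globally most uncertain pixels (ties broken by row-major index);
3. per point, bilinearly gather the transformer (global) features, the
   convolutional (local) features and the coarse probability, concatenate,
   and re-predict the lesion probability with a small two-layer pointwise
   mixer perceptron;
4. scatter the re-predictions back into the upsampled map — every pixel
   outside the point set keeps its interpolated value bit-exactly.

The per-level maps are finally merged by a channel-gated fusion: a global
average pool feeds an affine layer and a sigmoid, and the resulting
per-channel scalar is *added* to the stack (a multiplicative gate is
available behind ``fusion_mode="mul"``), before a 1x1 projection collapses
the levels to one probability map.

Defaults follow the ablation optimum: ``k = 3``, ``beta = 0.7``,
``p_thd = 0.5``.  Selection is seeded and fully deterministic; inference
selection is seed-free.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from . import nn

DEFAULT_K = 3.0
DEFAULT_BETA = 0.7
DEFAULT_P_THD = 0.5
_MAX_REDRAWS = 50


@dataclasses.dataclass(frozen=True)
class PointSet:
    """Selected pixel positions on an H x W grid, in selection order.

    ``rows``/``cols`` are integer pixel indices; ``norm_y``/``norm_x`` are
    the matching normalised positions ``(i + 0.5) / H`` used for feature
    sampling (half-pixel convention).  Importance-selected points come
    first, random fill points after, each group in draw order.
    """

    rows: np.ndarray
    cols: np.ndarray
    height: int
    width: int
    n_points: int
    k: float
    beta: float
    seed: int | None
    training: bool

    @property
    def norm_y(self) -> np.ndarray:
        return (self.rows + 0.5) / self.height

    @property
    def norm_x(self) -> np.ndarray:
        return (self.cols + 0.5) / self.width

    def __len__(self) -> int:
        return len(self.rows)

    def __post_init__(self):
        flat = self.rows * self.width + self.cols
        if len(np.unique(flat)) != len(flat):
            raise ValueError("point coordinates must be unique")
        if len(flat) and (self.rows.min() < 0 or self.rows.max() >= self.height
                          or self.cols.min() < 0 or self.cols.max() >= self.width):
            raise ValueError("point coordinates out of bounds")


def _as_map(p) -> np.ndarray:
    p = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=float)
    if p.ndim != 2:
        raise ValueError(f"expected an H x W map, got shape {p.shape}")
    return p


def coarse_upsample(p):
    """Bilinear 2x upsampling of a probability map.

    Accepts an (H, W) array (returns an (2H, 2W) array) or a (B, 1, H, W)
    tensor (returns the upsampled tensor, gradients attached).  Bilinear
    interpolation is convex, so outputs stay within the input's range.
    """
    if isinstance(p, Tensor) and p.ndim == 4:
        return ag.upsample2x_bilinear(p)
    arr = _as_map(p)
    _check_prob(arr)
    t = ag.upsample2x_bilinear(Tensor(arr[None, None]))
    return t.data[0, 0]


def _check_prob(arr: np.ndarray) -> None:
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1 or not np.isfinite(arr).all()):
        raise ValueError("probability map values must be finite and in [0, 1]")


def uncertainty_map(p, p_thd: float = DEFAULT_P_THD) -> np.ndarray:
    """Elementwise ``|p - p_thd|``; smaller values mean higher uncertainty."""
    if not 0.0 < p_thd < 1.0:
        raise ValueError(f"p_thd must lie in (0, 1), got {p_thd}")
    arr = p.data if isinstance(p, Tensor) else np.asarray(p, dtype=float)
    _check_prob(arr)
    return np.abs(arr - p_thd)


def select_points(u: np.ndarray, n_points: int, k: float = DEFAULT_K,
                  beta: float = DEFAULT_BETA, seed: int | None = None,
                  training: bool = True) -> PointSet:
    """Select ``n_points`` pixels of the uncertainty map `u` (H x W).

    Training mode draws ``round(k * n_points)`` candidate pixels uniformly
    at random *without replacement* (one ``default_rng(seed).choice`` call
    over row-major flat indices), keeps the ``round(beta * n_points)``
    candidates with smallest ``u`` (most uncertain), and fills the remainder
    with fresh uniform positions from the same generator, redrawn on
    collision (bounded attempts, then lowest-index unused pixels).
    Inference mode ignores `seed` and takes the ``n_points`` globally
    smallest values.  All orderings break ties by row-major pixel index.
    """
    u = np.asarray(u, dtype=float)
    H, W = u.shape
    n_pix = H * W
    if not k >= 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if n_points > n_pix:
        raise ValueError(f"cannot select {n_points} points from {n_pix} pixels")
    flat = u.ravel()

    if not training:
        order = np.argsort(flat, kind="stable")      # ties -> row-major index
        chosen = order[:n_points]
    else:
        m = int(round(k * n_points))
        if m > n_pix:
            raise ValueError(
                f"k*N = {m} candidates exceed the {n_pix}-pixel map")
        m = max(m, n_points)
        rng = np.random.default_rng(seed)
        candidates = rng.choice(n_pix, size=m, replace=False)
        n_imp = min(int(round(beta * n_points)), n_points)
        # sort candidates by (uncertainty, flat index)
        order = np.lexsort((candidates, flat[candidates]))
        important = candidates[order][:n_imp]
        used = set(important.tolist())
        fill: list[int] = []
        attempts = 0
        while len(fill) < n_points - n_imp and attempts < _MAX_REDRAWS:
            draw = rng.integers(0, n_pix, size=n_points - n_imp - len(fill))
            attempts += 1
            for d in draw.tolist():
                if d not in used and len(fill) < n_points - n_imp:
                    used.add(d)
                    fill.append(d)
        if len(fill) < n_points - n_imp:             # deterministic fallback
            for d in range(n_pix):
                if d not in used:
                    used.add(d)
                    fill.append(d)
                    if len(fill) == n_points - n_imp:
                        break
        chosen = np.concatenate([important, np.asarray(fill, dtype=np.int64)]) \
            if fill else important
    chosen = chosen.astype(np.int64)
    return PointSet(rows=chosen // W, cols=chosen % W, height=H, width=W,
                    n_points=int(n_points), k=float(k), beta=float(beta),
                    seed=seed, training=bool(training))


def gather_point_features(points: PointSet, global_feats, local_feats,
                          coarse) -> Tensor:
    """Concatenate bilinearly sampled features at the selected points.

    Feature sources may live on grids of any resolution; sampling uses the
    points' normalised positions.  Output (B, P, Cg + Cl + 1) with the fixed
    channel order (global, local, coarse probability).
    """
    gf = _as_bchw(global_feats)
    lf = _as_bchw(local_feats)
    cf = _as_bchw(coarse)
    ys, xs = points.norm_y, points.norm_x
    parts = [ag.bilinear_sample(src, ys, xs) for src in (gf, lf, cf)]
    return ag.concatenate(parts, axis=1).transpose(0, 2, 1)   # (B, P, F)


def _as_bchw(x) -> Tensor:
    x = ag.as_tensor(x)
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
    elif x.ndim == 3:
        x = x.reshape(1, *x.shape)
    if x.ndim != 4:
        raise ValueError(f"expected a feature grid, got shape {x.shape}")
    return x


class PointMixer(nn.Module):
    """Two-layer pointwise perceptron re-predicting lesion probability.

    Applied with shared weights to every point's concatenated feature row;
    PReLU between the affine layers, sigmoid output in (0, 1).
    """

    def __init__(self, in_features: int, rng: np.random.Generator,
                 hidden: int | None = None):
        super().__init__()
        hidden = in_features if hidden is None else hidden
        self.fc1 = nn.Linear(in_features, hidden, rng)
        self.act = nn.PReLU()
        self.fc2 = nn.Linear(hidden, 1, rng)

    def forward(self, features: Tensor) -> Tensor:
        out = self.fc2(self.act(self.fc1(ag.as_tensor(features))))
        B, P, _ = out.shape
        return out.reshape(B, P).sigmoid()


def mixer_predict(features, mixer: PointMixer) -> Tensor:
    """Functional alias: per-point probabilities (B, P) from features (B, P, F)."""
    return mixer(features)


def replace_points(coarse, points: PointSet, new_values):
    """Overwrite the point set's pixels with re-predicted values.

    Every other pixel of `coarse` is returned bit-identically.  Accepts an
    (H, W) array with (P,) values, or a (B, 1, H, W) tensor with (B, P)
    values (gradients flow into both the map and the values).
    """
    rows = np.asarray(points.rows, dtype=np.int64)
    cols = np.asarray(points.cols, dtype=np.int64)
    if isinstance(coarse, Tensor) and coarse.ndim == 4:
        B = coarse.shape[0]
        vals = ag.as_tensor(new_values)
        if vals.ndim == 1:
            vals = vals.reshape(1, -1)
        if vals.shape[-1] != len(points):
            raise ValueError("one value per selected point required")
        r = np.broadcast_to(rows, (B, len(points)))
        c = np.broadcast_to(cols, (B, len(points)))
        return ag.scatter_replace(coarse, r, c, vals)
    arr = _as_map(coarse)
    vals = np.asarray(new_values.data if isinstance(new_values, Tensor) else new_values,
                      dtype=float).ravel()
    if vals.size != len(points):
        raise ValueError("one value per selected point required")
    out = arr.copy()
    out[rows, cols] = vals
    return out


@dataclasses.dataclass
class RenderStepResult:
    probability: Tensor        # (B, 1, 2H, 2W) refined map
    upsampled: Tensor          # (B, 1, 2H, 2W) pure bilinear baseline
    points: list[PointSet]     # one per batch element
    point_preds: Tensor | None # (B, P) mixer outputs (None when P == 0)


def render_step(coarse_lowres, global_feats, local_feats, mixer: PointMixer,
                n_points: int, k: float = DEFAULT_K, beta: float = DEFAULT_BETA,
                p_thd: float = DEFAULT_P_THD, seed: int | None = None,
                training: bool = True) -> RenderStepResult:
    """One render level: upsample 2x, select, re-predict, replace.

    `coarse_lowres` is (B, 1, H, W) (arrays are wrapped).  Selection is done
    per batch element on the upsampled map's uncertainty; per-element seeds
    are ``seed + index``.  With ``n_points == 0`` the step reduces to pure
    bilinear upsampling.
    """
    coarse = _as_bchw(coarse_lowres)
    up = ag.upsample2x_bilinear(coarse)
    B = up.shape[0]
    if n_points == 0:
        return RenderStepResult(up, up, [], None)
    points = []
    for b in range(B):
        u = uncertainty_map(up.data[b, 0], p_thd)
        points.append(select_points(u, n_points, k=k, beta=beta,
                                    seed=None if seed is None else seed + b,
                                    training=training))
    rows = np.stack([p.rows for p in points])
    cols = np.stack([p.cols for p in points])
    gf, lf = _as_bchw(global_feats), _as_bchw(local_feats)
    H2, W2 = up.shape[2], up.shape[3]
    ys = (rows + 0.5) / H2
    xs = (cols + 0.5) / W2
    feats = ag.concatenate(
        [ag.bilinear_sample(src, ys, xs) for src in (gf, lf, up)], axis=1
    ).transpose(0, 2, 1)
    preds = mixer(feats)                              # (B, P)
    refined = ag.scatter_replace(up, rows, cols, preds)
    return RenderStepResult(refined, up, points, preds)


class FusionModule(nn.Module):
    """Channel-gated fusion of stacked per-level segmentation maps.

    ``gate = sigmoid(FC(GAP(X_r)))`` is broadcast over space and combined
    with the stack (additively by default, multiplicatively with
    ``mode="mul"``); a 1x1 projection and sigmoid collapse the level
    channels into one probability map.
    """

    def __init__(self, n_levels: int, rng: np.random.Generator, mode: str = "add"):
        super().__init__()
        if mode not in ("add", "mul"):
            raise ValueError(f"fusion_mode must be add or mul, got {mode!r}")
        self.mode = mode
        self.fc = nn.Linear(n_levels, n_levels, rng)
        self.proj = nn.Conv2d(n_levels, 1, 1, rng)
        # start as a calibrated average of the level maps: with the additive
        # gate near 0.5, sigmoid(4*mean(X_r) - 2) is monotone in the mean
        # probability and never saturates on [0, 1], keeping early gradients
        # informative (a steeper init saturates and stalls training)
        self.proj.weight.data[...] = 4.0 / n_levels
        self.proj.bias.data[...] = -4.0

    def gate(self, x_r: Tensor) -> Tensor:
        pooled = x_r.mean(axis=(2, 3))                # GAP: (B, L)
        g = self.fc(pooled).sigmoid()
        B, L = g.shape
        return g.reshape(B, L, 1, 1)

    def attend(self, x_r) -> Tensor:
        """The literal gate-and-combine: sigmoid(FC(GAP(X_r))) (+|*) X_r."""
        x_r = ag.as_tensor(x_r)
        if x_r.shape[1] != self.fc.weight.shape[0]:
            raise ValueError(
                f"fusion configured for {self.fc.weight.shape[0]} levels, "
                f"got {x_r.shape[1]} channels")
        g = self.gate(x_r)
        return g + x_r if self.mode == "add" else g * x_r

    def forward(self, x_r) -> Tensor:
        return self.proj(self.attend(x_r)).sigmoid()


def fuse(x_r, fusion: FusionModule) -> Tensor:
    """Functional alias: fused probability map (B, 1, H, W) from (B, L, H, W)."""
    return fusion(x_r)
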