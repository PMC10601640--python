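"""Hybrid encoder: hierarchical transformer branch + convolutional branch.

The transformer branch splits the image into patches, projects them to an
embedding, adds a learned positional embedding once, and runs pre-norm
transformer stages separated by patch merging (2x2 token concatenation +
linear projection: spatial resolution halves, channels double).  It supplies
the *global* skip connections.  The convolutional branch stacks residual
Conv-BN-PReLU blocks at full and pooled resolutions and supplies the *local*
skip connections.  ``HybridEncoder.forward`` emits both as a
:class:`FeaturePyramid` tagged by scale and branch.

Plain (unwindowed) multi-head self-attention is used throughout: per head,
``softmax(Q K^T / sqrt(d_k)) V`` with ``Q = X W_q`` etc., heads concatenated
and linearly recombined.

The architecture's depths and widths are configurable; defaults are
Swin-style (patch size 4, three stages of two layers, base embedding 48
doubling per merge, three heads per stage).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from . import nn


# ---------------------------------------------------------------------------
# functional operations (explicit-weight forms used by the module classes)
# ---------------------------------------------------------------------------

def patch_embed(x, patch_shape: tuple[int, int], projection, positional=None):
    """Embed an image into a patch-token sequence.

    x: (B, C, H, W) image; projection E: (P_H*P_W*C, D); positional E_pos:
    (N, D) added once.  Token ``i`` is the row-major ``i``-th patch, flattened
    channel-first (``patch[c, u, v]`` with ``c`` slowest), times E, plus the
    ``i``-th positional row.  Returns tokens (B, N, D).
    """
    x = ag.as_tensor(x)
    projection = ag.as_tensor(projection)
    B, C, H, W = x.shape
    ph, pw = patch_shape
    if H % ph or W % pw:
        raise ValueError(
            f"image {H}x{W} not divisible by patch {ph}x{pw}")
    gh, gw = H // ph, W // pw
    # (B, C, gh, ph, gw, pw) -> (B, gh, gw, C, ph, pw) -> (B, N, C*ph*pw)
    patches = x.reshape(B, C, gh, ph, gw, pw).transpose(0, 2, 4, 1, 3, 5)
    patches = patches.reshape(B, gh * gw, C * ph * pw)
    tokens = patches @ projection
    if positional is not None:
        tokens = tokens + ag.as_tensor(positional)
    return tokens


def msa(tokens, wq, wk, wv, wo, bo=None):
    """Multi-head self-attention with explicit per-head weights.

    tokens: (B, N, D); wq/wk/wv: (n_heads, D, d_k|d_v); wo: (n_heads*d_v, D).
    Per head: softmax(Q K^T / sqrt(d_k)) V; heads concatenated then projected.
    """
    tokens = ag.as_tensor(tokens)
    if not np.isfinite(tokens.data).all():
        raise ValueError("non-finite attention input")
    wq, wk, wv, wo = (ag.as_tensor(w) for w in (wq, wk, wv, wo))
    n_heads, D, d_k = wq.shape
    if D != tokens.shape[-1]:
        raise ValueError(f"weight dim {D} incompatible with tokens {tokens.shape}")
    heads = []
    for h in range(n_heads):
        q = tokens @ wq[h]
        k = tokens @ wk[h]
        v = tokens @ wv[h]
        logits = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(d_k))
        attn = ag.softmax(logits, axis=-1)
        heads.append(attn @ v)
    out = ag.concatenate(heads, axis=-1) @ wo
    if bo is not None:
        out = out + ag.as_tensor(bo)
    return out


def attention_matrices(tokens, wq, wk) -> np.ndarray:
    """Per-head row-stochastic attention matrices (diagnostics), (h, B, N, N)."""
    tokens = ag.as_tensor(tokens).data
    wq, wk = np.asarray(wq, float), np.asarray(wk, float)
    mats = []
    for h in range(wq.shape[0]):
        q = tokens @ wq[h]
        k = tokens @ wk[h]
        logits = q @ np.swapaxes(k, -1, -2) / np.sqrt(wq.shape[-1])
        e = np.exp(logits - logits.max(axis=-1, keepdims=True))
        mats.append(e / e.sum(axis=-1, keepdims=True))
    return np.stack(mats)


def patch_merge(tokens, grid_hw: tuple[int, int], projection):
    """Merge 2x2 neighbouring tokens and project: N/4 tokens, channels x2.

    tokens: (B, N, D) over a row-major (gh, gw) grid; projection: (4D, 2D).
    Concatenation order within each 2x2 block: top-left, top-right,
    bottom-left, bottom-right.
    """
    tokens = ag.as_tensor(tokens)
    projection = ag.as_tensor(projection)
    B, N, D = tokens.shape
    gh, gw = grid_hw
    if gh * gw != N:
        raise ValueError(f"grid {gh}x{gw} does not match {N} tokens")
    if gh % 2 or gw % 2:
        raise ValueError(f"patch merge needs even token grid, got {gh}x{gw}")
    g = tokens.reshape(B, gh // 2, 2, gw // 2, 2, D)
    g = g.transpose(0, 1, 3, 2, 4, 5)          # (B, gh/2, gw/2, 2, 2, D)
    g = g.reshape(B, (gh // 2) * (gw // 2), 4 * D)
    return g @ projection


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class PatchEmbed(nn.Module):
    def __init__(self, in_ch: int, patch_size: int, dim: int, n_tokens: int,
                 rng: np.random.Generator):
        super().__init__()
        self.patch_size = patch_size
        self.projection = nn.Parameter(
            nn.truncated_normal(rng, (patch_size * patch_size * in_ch, dim),
                                std=(patch_size * patch_size * in_ch) ** -0.5))
        self.positional = nn.Parameter(
            nn.truncated_normal(rng, (n_tokens, dim), std=0.02))

    def forward(self, x: Tensor) -> Tensor:
        return patch_embed(x, (self.patch_size, self.patch_size),
                           self.projection, self.positional)


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by {n_heads} heads")
        d_k = dim // n_heads
        std = dim ** -0.5
        self.wq = nn.Parameter(nn.truncated_normal(rng, (n_heads, dim, d_k), std=std))
        self.wk = nn.Parameter(nn.truncated_normal(rng, (n_heads, dim, d_k), std=std))
        self.wv = nn.Parameter(nn.truncated_normal(rng, (n_heads, dim, d_k), std=std))
        self.wo = nn.Parameter(nn.truncated_normal(rng, (dim, dim), std=std))
        self.bo = nn.Parameter(np.zeros(dim))

    def forward(self, tokens: Tensor) -> Tensor:
        return msa(tokens, self.wq, self.wk, self.wv, self.wo, self.bo)


class TransformerLayer(nn.Module):
    """Pre-norm residual transformer layer: x + MSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, dim: int, n_heads: int, mlp_ratio: float,
                 rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        t = tokens + self.attn(self.norm1(tokens))
        return t + self.fc2(self.fc1(self.norm2(t)).gelu())


class PatchMerge(nn.Module):
    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.projection = nn.Parameter(
            nn.truncated_normal(rng, (4 * dim, 2 * dim), std=(4 * dim) ** -0.5))

    def forward(self, tokens: Tensor, grid_hw: tuple[int, int]) -> Tensor:
        return patch_merge(tokens, grid_hw, self.projection)


class ConvBlock(nn.Module):
    """Channel-preserving double residual conv block.

    With ``a = PReLU(BN(conv1(x)))`` the output is
    ``PReLU(BN(conv2(a + x))) + a + x`` — two stacked 3x3/stride-1
    convolutions whose intermediate activation and input both re-enter
    additively, so spatial size and channel count are preserved.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, rng, padding=1)
        self.bn1 = nn.BatchNorm2d(channels)
        self.act1 = nn.PReLU(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng, padding=1)
        self.bn2 = nn.BatchNorm2d(channels)
        self.act2 = nn.PReLU(channels)

    def forward(self, x: Tensor) -> Tensor:
        a = self.act1(self.bn1(self.conv1(x)))
        return self.act2(self.bn2(self.conv2(a + x))) + a + x


def conv_block(x, block: "ConvBlock"):
    """Functional alias: apply a ConvBlock to (B, C, H, W) input."""
    return block(ag.as_tensor(x))


@dataclasses.dataclass
class PyramidLevel:
    scale: int            # downsampling factor relative to the input
    features: Tensor      # (B, C, H/scale, W/scale)
    branch: str           # "transformer" | "convolutional"


@dataclasses.dataclass
class FeaturePyramid:
    levels: list[PyramidLevel]

    def by_branch(self, branch: str) -> list[PyramidLevel]:
        return [lv for lv in self.levels if lv.branch == branch]

    def nearest(self, branch: str, scale: int) -> PyramidLevel:
        """Level of `branch` whose scale is closest (log-distance) to `scale`."""
        cands = self.by_branch(branch)
        return min(cands, key=lambda lv: abs(np.log2(lv.scale) - np.log2(scale)))


class HybridEncoder(nn.Module):
    """Two-branch encoder emitting a tagged multi-scale feature pyramid.

    Parameters
    ----------
    in_ch : input channels.
    image_hw : training resolution (fixes the positional embedding length).
    patch_size : transformer patch side; first transformer scale.
    depths : transformer layers per stage; patch merging between stages.
    embed_dim : stage-1 embedding width; doubles at every merge.
    n_heads : attention heads per stage (same count at every stage).
    mlp_ratio : transformer MLP expansion.
    conv_channels : convolutional-branch width at full resolution; doubles
        at each pooled level.
    n_conv_levels : number of convolutional levels (scales 1, 2, 4, ...).
    """

    def __init__(self, in_ch: int, image_hw: tuple[int, int], rng: np.random.Generator,
                 patch_size: int = 4, depths: tuple[int, ...] = (2, 2, 2),
                 embed_dim: int = 48, n_heads: int = 3, mlp_ratio: float = 4.0,
                 conv_channels: int = 16, n_conv_levels: int = 3):
        super().__init__()
        H, W = image_hw
        self.patch_size = patch_size
        self.depths = tuple(depths)
        self.image_hw = (H, W)
        total_stride = patch_size * 2 ** (len(depths) - 1)
        for name, size in (("height", H), ("width", W)):
            if size % total_stride:
                raise ValueError(
                    f"image {name} {size} not divisible by total stride "
                    f"{total_stride} (patch {patch_size} x {2 ** (len(depths) - 1)} merges)")
        self.embed = PatchEmbed(in_ch, patch_size, embed_dim,
                                (H // patch_size) * (W // patch_size), rng)
        self.stages = []
        self.merges = []
        dim = embed_dim
        for s, depth in enumerate(depths):
            self.stages.append([TransformerLayer(dim, n_heads, mlp_ratio, rng)
                                for _ in range(depth)])
            if s + 1 < len(depths):
                self.merges.append(PatchMerge(dim, rng))
                dim *= 2
        self.conv_lift = []
        self.conv_blocks = []
        ch = conv_channels
        prev = in_ch
        for _ in range(n_conv_levels):
            self.conv_lift.append(nn.Conv2d(prev, ch, 1, rng))
            self.conv_blocks.append(ConvBlock(ch, rng))
            prev, ch = ch, ch * 2

    def _children(self):
        yield from super()._children()
        for s, stage in enumerate(self.stages):
            for i, layer in enumerate(stage):
                yield f"stages.{s}.{i}", layer

    def transformer_scales(self) -> list[int]:
        return [self.patch_size * 2 ** s for s in range(len(self.depths))]

    def forward(self, x) -> FeaturePyramid:
        x = ag.as_tensor(x)
        B, C, H, W = x.shape
        if (H, W) != self.image_hw:
            raise ValueError(f"encoder configured for {self.image_hw}, got {(H, W)}")
        levels: list[PyramidLevel] = []

        # transformer branch
        tokens = self.embed(x)
        gh, gw = H // self.patch_size, W // self.patch_size
        for s, stage in enumerate(self.stages):
            for layer in stage:
                tokens = layer(tokens)
            D = tokens.shape[-1]
            grid = tokens.reshape(B, gh, gw, D).transpose(0, 3, 1, 2)
            levels.append(PyramidLevel(self.patch_size * 2 ** s, grid, "transformer"))
            if s < len(self.merges):
                tokens = self.merges[s](tokens, (gh, gw))
                gh, gw = gh // 2, gw // 2

        # convolutional branch
        feat = x
        for i, (lift, block) in enumerate(zip(self.conv_lift, self.conv_blocks)):
            if i > 0:
                feat = ag.avg_pool2x2(feat)
            feat = block(lift(feat))
            levels.append(PyramidLevel(2 ** i, feat, "convolutional"))

        return FeaturePyramid(levels)


def encode(x, encoder: HybridEncoder) -> FeaturePyramid:
    """Functional alias for :meth:`HybridEncoder.forward`."""
    return encoder(x)
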