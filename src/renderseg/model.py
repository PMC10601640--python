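"""Full segmentation network: hybrid encoder -> render decoder -> fusion.

The deepest transformer features produce an initial coarse probability map
(1x1 projection + sigmoid).  One render level per 2x doubling then carries
the map back to input resolution, each level re-predicting only its most
uncertain pixels from the nearest-scale global (transformer) and local
(convolutional) skip features.  Every level's map is bilinearly upsampled
to full resolution, stacked, and merged by the channel-gated fusion module.

``points_divisor`` sets the per-level point budget ``(h*w) // divisor``
(capped), which keeps the budget resolution-relative so small and large
lesions both receive boundary points; ``points_divisor = 0`` disables
rendering entirely (pure-bilinear ablation decoder).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from . import nn
from .encoder import HybridEncoder, FeaturePyramid
from .render import (
    DEFAULT_BETA,
    DEFAULT_K,
    DEFAULT_P_THD,
    FusionModule,
    PointMixer,
    RenderStepResult,
    render_step,
)


@dataclasses.dataclass
class ModelConfig:
    """Architecture and rendering hyper-parameters.

    k / beta: point-selection oversampling factor and importance fraction
    (ablation optima 3 and 0.7); p_thd: uncertainty threshold.
    """

    in_channels: int = 1
    image_height: int = 208
    image_width: int = 176
    patch_size: int = 4
    depths: tuple[int, ...] = (2, 2, 2)
    embed_dim: int = 48
    n_heads: int = 3
    mlp_ratio: float = 4.0
    conv_channels: int = 16
    n_conv_levels: int = 3
    points_divisor: int = 16
    points_cap: int = 8192
    k: float = DEFAULT_K
    beta: float = DEFAULT_BETA
    p_thd: float = DEFAULT_P_THD
    fusion_mode: str = "add"
    seed: int = 0

    def __post_init__(self):
        self.depths = tuple(self.depths)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclasses.dataclass
class ModelOutput:
    fused: Tensor                     # (B, 1, H, W) final probability map
    levels: list[RenderStepResult]    # per render level, coarse -> fine
    coarse: Tensor                    # (B, 1, h0, w0) initial map


class RenderSegNet(nn.Module):
    """Hybrid transformer/convolution encoder with a point-rendering decoder."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = HybridEncoder(
            config.in_channels, (config.image_height, config.image_width), rng,
            patch_size=config.patch_size, depths=config.depths,
            embed_dim=config.embed_dim, n_heads=config.n_heads,
            mlp_ratio=config.mlp_ratio, conv_channels=config.conv_channels,
            n_conv_levels=config.n_conv_levels)

        n_stages = len(config.depths)
        self.coarse_scale = config.patch_size * 2 ** (n_stages - 1)
        deepest_dim = config.embed_dim * 2 ** (n_stages - 1)
        self.coarse_head = nn.Conv2d(deepest_dim, 1, 1, rng)

        self.n_render_levels = int(np.log2(self.coarse_scale))
        if 2 ** self.n_render_levels != self.coarse_scale:
            raise ValueError("patch_size must be a power of two")
        self.mixers = []
        self._skip_scales = []
        scale = self.coarse_scale
        pyr_scales_t = [config.patch_size * 2 ** s for s in range(n_stages)]
        pyr_scales_c = [2 ** i for i in range(config.n_conv_levels)]
        for _ in range(self.n_render_levels):
            scale //= 2
            g_scale = min(pyr_scales_t, key=lambda s: abs(np.log2(s) - np.log2(scale)))
            c_scale = min(pyr_scales_c, key=lambda s: abs(np.log2(s) - np.log2(scale)))
            g_dim = config.embed_dim * 2 ** pyr_scales_t.index(g_scale)
            c_dim = config.conv_channels * 2 ** pyr_scales_c.index(c_scale)
            self._skip_scales.append((g_scale, c_scale))
            self.mixers.append(PointMixer(g_dim + c_dim + 1, rng))
        self.fusion = FusionModule(self.n_render_levels, rng, mode=config.fusion_mode)

    # -- point budget ----------------------------------------------------
    def n_points_for(self, out_h: int, out_w: int) -> int:
        if self.config.points_divisor <= 0:
            return 0
        return min(self.config.points_cap, (out_h * out_w) // self.config.points_divisor)

    def forward(self, x, seed: int | None = None,
                training_points: bool | None = None) -> ModelOutput:
        """Run the network.

        `seed` drives training-mode point selection (required for
        reproducible training steps); inference selection is seed-free.
        """
        x = ag.as_tensor(x)
        if training_points is None:
            training_points = self.training
        pyramid: FeaturePyramid = self.encoder(x)
        deepest = max(pyramid.by_branch("transformer"), key=lambda lv: lv.scale)
        coarse = self.coarse_head(deepest.features).sigmoid()

        levels: list[RenderStepResult] = []
        cur = coarse
        scale = self.coarse_scale
        for i in range(self.n_render_levels):
            scale //= 2
            g_scale, c_scale = self._skip_scales[i]
            g = pyramid.nearest("transformer", g_scale)
            c = pyramid.nearest("convolutional", c_scale)
            out_h = self.config.image_height // scale
            out_w = self.config.image_width // scale
            res = render_step(
                cur, g.features, c.features, self.mixers[i],
                n_points=self.n_points_for(out_h, out_w),
                k=self.config.k, beta=self.config.beta, p_thd=self.config.p_thd,
                seed=None if seed is None else (seed + 104729 * i) % (2 ** 31),
                training=training_points)
            levels.append(res)
            cur = res.probability

        # stack per-level maps at full resolution
        stacked = []
        scale = self.coarse_scale
        for res in levels:
            scale //= 2
            m = res.probability
            s = scale
            while s > 1:
                m = ag.upsample2x_bilinear(m)
                s //= 2
            stacked.append(m)
        x_r = ag.concatenate(stacked, axis=1)
        fused = self.fusion(x_r)
        return ModelOutput(fused=fused, levels=levels, coarse=coarse)

    def predict(self, images: np.ndarray, threshold: float = 0.5):
        """Deterministic inference on (B, C, H, W) or (H, W) images.

        Returns (probability maps (B, H, W), binary masks (B, H, W)).
        """
        arr = np.asarray(images, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        was_training = self.training
        self.eval()
        out = self.forward(Tensor(arr), training_points=False)
        self.train(was_training)
        probs = out.fused.data[:, 0]
        return probs, (probs >= threshold).astype(np.uint8)

    # -- persistence ------------------------------------------------------
    def save_checkpoint(self, path: str | Path, extra: dict | None = None) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {f"param/{k}": v for k, v in self.state_dict().items()}
        meta = {"config": self.config.to_dict(), "extra": extra or {}}
        payload["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:   # keep the caller's exact filename
            np.savez(fh, **payload)

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> tuple["RenderSegNet", dict]:
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
            state = {k[len("param/"):]: data[k] for k in data.files
                     if k.startswith("param/")}
        model = cls(ModelConfig.from_dict(meta["config"]))
        model.load_state_dict(state)
        return model, meta.get("extra", {})
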