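"""Training loop: AdamW on the combined Dice + point objective.

Optimisation uses AdamW with the library-default settings (learning rate
1e-3, betas (0.9, 0.999), weight decay 1e-2) and epoch-based early
stopping on the validation Dice score.  Every source of randomness —
shuffling and point selection — is derived deterministically from
``(seed, epoch, step)``, so a fixed seed and config reproduce the training
curve exactly, and a run resumed from a checkpoint continues identically
to an uninterrupted one.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .autograd import Tensor
from . import metrics
from .model import ModelConfig, ModelOutput, RenderSegNet
from .nn import AdamW
from .objectives import LossConfig, PointTargets, sample_point_targets, total_loss


@dataclasses.dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 8
    lr: float = 1e-3
    weight_decay: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    patience: int = 10          # epochs without val-DSC improvement before stopping
    lambda_point: float = 0.7
    delta: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        d = {k: v for k, v in d.items() if k in known}
        if "betas" in d:
            d["betas"] = tuple(d["betas"])
        return cls(**d)


@dataclasses.dataclass
class TrainState:
    epoch: int = 0
    best_val_dsc: float = -1.0
    epochs_without_improvement: int = 0
    stopped_early: bool = False


def point_targets_for(output: ModelOutput, masks: np.ndarray) -> list[PointTargets]:
    """Per-level supervision pairs: mixer predictions vs bilinear mask samples."""
    targets = []
    for res in output.levels:
        if res.point_preds is None:
            targets.append(PointTargets(predictions=None, targets=None))
            continue
        ys = np.stack([p.norm_y for p in res.points])
        xs = np.stack([p.norm_x for p in res.points])
        g = sample_point_targets(masks, ys, xs)
        targets.append(PointTargets(predictions=res.point_preds, targets=g))
    return targets


class Trainer:
    """Orchestrates epochs, validation, early stopping and checkpointing.

    `images`: (N, C, H, W) float arrays; `masks`: (N, H, W) binary.
    """

    def __init__(self, model: RenderSegNet, train_images, train_masks,
                 val_images, val_masks, cfg: TrainConfig = TrainConfig(),
                 log_path: str | Path | None = None):
        if len(train_images) == 0:
            raise ValueError("empty training dataset")
        self.model = model
        self.cfg = cfg
        self.loss_cfg = LossConfig(lambda_point=cfg.lambda_point, delta=cfg.delta)
        self.train_images = np.asarray(train_images, dtype=np.float64)
        self.train_masks = np.asarray(train_masks, dtype=np.float64)
        self.val_images = np.asarray(val_images, dtype=np.float64)
        self.val_masks = np.asarray(val_masks, dtype=np.float64)
        self.optimizer = AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                               weight_decay=cfg.weight_decay)
        self.state = TrainState()
        self.history: list[dict] = []
        self.log_path = Path(log_path) if log_path else None
        self.best_state: dict | None = None

    # -- single epoch -----------------------------------------------------
    def _step_seed(self, epoch: int, step: int) -> int:
        return int((self.cfg.seed * 1_000_003 + epoch * 1009 + step) % (2 ** 31))

    def run_epoch(self, epoch: int) -> dict:
        perm = np.random.default_rng([self.cfg.seed, epoch]).permutation(
            len(self.train_images))
        self.model.train()
        losses, comps_acc = [], []
        bs = self.cfg.batch_size
        for step, start in enumerate(range(0, len(perm), bs)):
            idx = perm[start:start + bs]
            x = Tensor(self.train_images[idx])
            m = self.train_masks[idx]
            out = self.model(x, seed=self._step_seed(epoch, step),
                             training_points=True)
            per_level = point_targets_for(out, m)
            loss, comps = total_loss(out.fused, m[:, None], per_level, self.loss_cfg)
            if not np.isfinite(loss.item()):
                dump = {"epoch": epoch, "step": step, "components": comps}
                raise RuntimeError(f"non-finite loss; diagnostics: {json.dumps(dump)}")
            self.optimizer.zero_grad()
            loss.backward()
            self.optimizer.step()
            losses.append(loss.item())
            comps_acc.append(comps)
        mean_comps = {k: float(np.mean([c[k] for c in comps_acc]))
                      for k in comps_acc[0]}
        return {"epoch": epoch, "loss": float(np.mean(losses)), **mean_comps}

    def _mean_dsc(self, images: np.ndarray, masks: np.ndarray) -> float:
        if len(images) == 0:
            return float("nan")
        probs, _ = self.model.predict(images)
        _, summary = metrics.evaluate(list(probs), list(masks))
        return summary["dsc"]

    def fit(self, epochs: int | None = None,
            checkpoint_path: str | Path | None = None) -> TrainState:
        """Train with early stopping; returns the final state.

        The best-validation model weights are kept (and written to
        `checkpoint_path` when given); call :meth:`restore_best` afterwards
        to load them back into the model.
        """
        epochs = self.cfg.epochs if epochs is None else epochs
        start = self.state.epoch
        for epoch in range(start, epochs):
            row = self.run_epoch(epoch)
            row["train_dsc"] = self._mean_dsc(self.train_images, self.train_masks)
            row["val_dsc"] = self._mean_dsc(self.val_images, self.val_masks)
            self.history.append(row)
            self._log(row)
            self.state.epoch = epoch + 1
            if row["val_dsc"] > self.state.best_val_dsc:
                self.state.best_val_dsc = row["val_dsc"]
                self.state.epochs_without_improvement = 0
                self.best_state = self.model.state_dict()
                if checkpoint_path is not None:
                    self.model.save_checkpoint(
                        checkpoint_path,
                        extra={"epoch": epoch, "val_dsc": row["val_dsc"],
                               "train_config": self.cfg.to_dict()})
            else:
                self.state.epochs_without_improvement += 1
                if self.state.epochs_without_improvement > self.cfg.patience:
                    self.state.stopped_early = True
                    break
        return self.state

    def restore_best(self) -> None:
        if self.best_state is not None:
            self.model.load_state_dict(self.best_state)

    def _log(self, row: dict) -> None:
        if self.log_path is not None:
            self.log_path.parent.mkdir(parents=True, exist_ok=True)
            with open(self.log_path, "a") as fh:
                fh.write(json.dumps(row) + "\n")

    # -- resumable snapshots ----------------------------------------------
    def save(self, path: str | Path) -> None:
        """Snapshot model + optimizer + progress for exact resumption."""
        payload = {f"model/{k}": v for k, v in self.model.state_dict().items()}
        payload.update({f"opt/{k}": v for k, v in self.optimizer.state_dict().items()})
        meta = {"state": dataclasses.asdict(self.state),
                "train_config": self.cfg.to_dict(),
                "model_config": self.model.config.to_dict()}
        payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **payload)

    @classmethod
    def load(cls, path: str | Path, train_images, train_masks,
             val_images, val_masks, log_path=None) -> "Trainer":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
            model_state = {k[6:]: data[k] for k in data.files if k.startswith("model/")}
            opt_state = {k[4:]: data[k] for k in data.files if k.startswith("opt/")}
        model = RenderSegNet(ModelConfig.from_dict(meta["model_config"]))
        model.load_state_dict(model_state)
        trainer = cls(model, train_images, train_masks, val_images, val_masks,
                      TrainConfig.from_dict(meta["train_config"]), log_path=log_path)
        trainer.optimizer.load_state_dict(opt_state)
        trainer.state = TrainState(**meta["state"])
        return trainer
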