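"""Train the reduced point-rendering network on synthetic lesions.

Runs the desk-scale study conditions (32 training / 8 validation samples of
64x64, contrast 0.3, noise 0.1) for a handful of epochs and prints the
training curve.  Early in training the Dice loss dominates; the per-level
point BCE terms supervise each render level's mixer at its selected points.
"""

from renderseg.experiments import REDUCED_MODEL, study_dataset
from renderseg.model import ModelConfig, RenderSegNet
from renderseg.train import TrainConfig, Trainer

(train_x, train_m), (val_x, val_m) = study_dataset(seed=0)
model = RenderSegNet(ModelConfig(seed=0, **REDUCED_MODEL))
trainer = Trainer(model, train_x, train_m, val_x, val_m,
                  TrainConfig(epochs=10, seed=0))
trainer.fit()

print(f"{'epoch':>5} {'loss':>8} {'dice':>8} {'train DSC':>10} {'val DSC':>8}")
for row in trainer.history:
    print(f"{row['epoch']:>5} {row['loss']:>8.4f} {row['dice']:>8.4f} "
          f"{row['train_dsc']:>10.4f} {row['val_dsc']:>8.4f}")
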