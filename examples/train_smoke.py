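"""A one-minute training demonstration on synthetic data.

Trains the narrow desk-scale configuration for 30 RMSProp steps on four
64x64 synthetic images and reports the fusion-loss trajectory and the
training-set dice scores.  (The full capacity check in the test suite runs
200 steps at 128x128 and reaches disc dice > 0.9.)
"""

from eards.data import make_synthetic_dataset
from eards.model import ModelConfig
from eards.train import TrainConfig, evaluate, train

samples = make_synthetic_dataset(4, seed=7, size=64, view="roi")
cfg = TrainConfig(seed=1, learning_rate=1e-4, batch_size=2, epochs=15,
                  max_steps=30, validate_every=15,
                  model=ModelConfig.small(seed=1))
model, log = train(cfg, samples)

print("epoch  fusion loss")
for e in log.epochs:
    print(f"{e.epoch:5d}  {e.train_loss:.4f}")
summary = evaluate(model, samples)
print(f"\ntraining-set disc dice after {log.steps} steps: "
      f"{summary['mean_dc_disc']:.3f}")
print("the loss falls from its initial value as the network first learns the",
      "background majority, then the bright disc;",
      "longer runs segment cup and disc almost perfectly on these images.")
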