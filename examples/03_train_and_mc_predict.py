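"""Train the small classifier briefly and query MC-dropout predictions.

Trains on a deliberately tiny cohort (a few minutes' desk-scale demo, far
from converged) and then runs T=10 stochastic forward passes on two test
samples: a clean mask and a perturbed one.  The normalized entropy of the
mean probability is the uncertainty score in [0, 1].
"""

import numpy as np

from contourqa.data import StructureCatalogue, acceptable_pools, build_balanced_set, build_epoch
from contourqa.model import ContourQualityNet, ModelConfig, TrainConfig, train
from contourqa.phantom import PhantomConfig, generate_cohort
from contourqa.uncertainty import mc_predict

phantom = PhantomConfig(seed=5)
train_p, val_p, test_p = generate_cohort(phantom, 20, 5, 5)
catalogue = StructureCatalogue(names=phantom.structure_names)
pools = acceptable_pools(train_p, catalogue)
val_set = build_balanced_set(acceptable_pools(val_p, catalogue), seed=1)

model = ContourQualityNet(ModelConfig(structure_code_length=len(catalogue)),
                          rng=np.random.default_rng(0))
model, log = train(model, lambda rng: build_epoch(pools, rng), val_set,
                   TrainConfig(epochs=12, initial_lr=3e-3, seed=2))
print(f"loss {log[0]['loss']:.3f} -> {log[-1]['loss']:.3f}, "
      f"best val accuracy {max(e['val_accuracy'] for e in log):.2f}")

test_set = build_balanced_set(acceptable_pools(test_p, catalogue), seed=9)
clean = next(s for s in test_set if s.label == 0)
broken = next(s for s in test_set if s.label == 1)
for name, sample in (("acceptable", clean), ("revision-required", broken)):
    pred = mc_predict(model, sample, T=10, seed=4)
    print(f"{name:18s} mean_prob={pred.mean_prob:.3f} entropy={pred.entropy:.3f} "
          f"-> predicted {pred.predicted_label_name}")
# mean_prob >= 0.5 flags the contour for revision; entropy near 0 means the
# T dropout passes agreed, entropy near 1 means the model is guessing.
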