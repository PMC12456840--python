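"""Train the shim-weight regressor on a small synthetic dataset.

Generates 128 augmented slices, derives multi-restart Adam reference
shims, trains a reduced-width residual regressor with the physics-informed
loss for a few epochs, and reports the test-set mean RMSE next to the
quadrature and reference arms.  (A few minutes on one CPU; enlarge the
dataset and epochs for results closer to the reference arm.)
"""

from dataclasses import replace

import numpy as np

from ptxshim import (
    GeneratorConfig,
    PredictorConfig,
    ShimObjectiveConfig,
    build_examples,
    quadrature_weights,
    rmse_percent,
    shim_volume,
    simulate_dataset,
)
from ptxshim.predictor import evaluate, train

volumes = simulate_dataset(
    GeneratorConfig(n_volumes=4, n_slices=8, n_rotations=4, grid_shape=(64, 64)),
    seed=1,
)
shim_cfg = ShimObjectiveConfig(n_restarts=8, max_iters=250)
references = [shim_volume(v, "adam", replace(shim_cfg, seed=i))
              for i, v in enumerate(volumes)]
examples = build_examples(volumes, references)

config = PredictorConfig(stage_widths=(16, 32, 64, 128), epochs=15,
                         batch_size=16, seed=0)
model, history = train(examples, config)

test = [examples[i] for i in history.splits["test"]]
report = evaluate(model, test)
quad = np.mean([
    rmse_percent(ex.fields_ref, quadrature_weights(8), ex.target_map, ex.mask)
    for ex in test
])
print(f"epochs trained        : {len(history.train_loss)}")
print(f"first/last train loss : {history.train_loss[0]:.2f} / "
      f"{history.train_loss[-1]:.2f}")
print(f"test mean RMSE        : predicted {report['mean']['predicted']:.2f} %, "
      f"reference {report['mean']['reference']:.2f} %, quadrature {quad:.2f} %")

# The physics loss (mean predicted-minus-reference RMSE) should fall over
# training, and the predicted mean should land below the quadrature
# baseline, approaching the Adam reference as data and epochs grow.
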