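"""Compare exact and reduced filters on Bernoulli change-point data.

Simulates binary sequences whose success rate is redrawn from a uniform prior
at hazard 0.05, then measures each model's mean squared error against the
true rate.  The 18-node reduced model tracks the exact filter at a fraction
of its cost.
"""

import numpy as np

from deltamix import (
    Bernoulli,
    FullModel,
    NodeSet,
    ReducedModel,
    log_spaced_nodes,
    sample_dataset_batch,
)

family = Bernoulli()
prior, h = (1.0, 2.0), 0.05  # uniform Beta(1, 1) prior on the rate
x, theta, _ = sample_dataset_batch(family, prior, h, T=1000, n_reps=10, seed=3)

full_preds, _ = FullModel(family, *prior, h=h, r_max=100).run(x)
red = ReducedModel(family, NodeSet(log_spaced_nodes(18, 1, 100), *prior), h)
red_preds, _ = red.run(x)

mse_full = np.mean((full_preds[:, 1:] - theta[:, 1:]) ** 2)
mse_red = np.mean((red_preds[:, 1:] - theta[:, 1:]) ** 2)
print(f"full model (101 run-lengths): MSE vs true rate = {mse_full:.4f}")
print(f"reduced model (18 nodes):     MSE vs true rate = {mse_red:.4f}")
print("The reduced model pays only a small accuracy cost for an order-of-"
      "magnitude reduction in state size.")
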