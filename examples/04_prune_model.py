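"""Iteratively remove non-predictive weights from a trained model.

Decoder weights whose relative ERV is <= 0 (no predictive contribution)
and hidden-layer weights with non-positive interlayer ERV are zeroed,
then the surviving weights are refit; this repeats until no weight is
removed. Validation R^2 should survive the shrinkage.
"""

import numpy as np

import primegrn as pg
from primegrn.preprocess import ExpressionMatrix

ds = pg.make_benchmark(pg.SyntheticSpec(seed=1))
rng = np.random.default_rng(5)
perm = rng.permutation(ds.expression.n_obs)
train_idx, val_idx = perm[:250], perm[250:]
x_train = ExpressionMatrix([ds.expression.obs_names[i] for i in train_idx],
                           list(ds.expression.gene_names),
                           ds.expression.values[train_idx], ds.expression.stage)
x_val = ds.expression.values[val_idx]

cfg = pg.TrainingConfig(epochs=400, refit_epochs=100, seed=0)
model = pg.initialize_from_prior(ds.prior, "hierarchical", seed=0)
pg.fit(model, x_train, cfg)
r2_before = pg.r_squared(x_val, pg.forward(model, x_val))
nnz_before = int(np.count_nonzero(model.decoder.weight))

model, log = pg.prune(model, x_train, cfg)
r2_after = pg.r_squared(x_val, pg.forward(model, x_val))
nnz_after = int(np.count_nonzero(model.decoder.weight))

print(log.to_string(index=False))
print(f"decoder nonzeros: {nnz_before} -> {nnz_after} "
      f"({100 * nnz_after / nnz_before:.0f}% retained)")
print(f"validation R^2: {r2_before:.3f} -> {r2_after:.3f}")
# Nonzero counts shrink monotonically while held-out prediction holds
# steady (or improves): the removed weights carried no signal.
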