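"""Objective, optimizer loop and hyperparameter search.

The model is fit by minibatch gradient descent with the Adam adaptive
optimizer on mean squared reconstruction error plus a ridge (weight-decay)
penalty zeta applied to the squared Frobenius norm of every weight matrix.
Dropout may be applied to the input genes and to the TF latent layer during
training only (inverted scaling, so evaluation needs no rescaling). Support
masks are re-applied after every optimizer step, so encoder entries outside
the prior are exactly zero at all times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GRNModel, JRLModel, Layer, relu0_grad, forward, forward_jrl
from .preprocess import ExpressionMatrix
from .priors import EdgeSet, PriorMatrix

logger = logging.getLogger(__name__)

# the search grids used for cross-validated selection
ZETA_GRID = (0.0,) + tuple(10.0 ** -e for e in range(10, 0, -1))
DROPOUT_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class TrainingConfig:
    """Hyperparameters for one fit."""

    zeta: float = 0.0             # ridge / weight-decay strength
    dropout_input: float = 0.5    # benchmark default: input 0.5, latent 0
    dropout_latent: float = 0.0
    epochs: int = 400
    refit_epochs: int = 100       # used after pruning
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")
        for p in (self.dropout_input, self.dropout_latent):
            if not 0 <= p < 1:
                raise ValueError("dropout rates must be in [0, 1)")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class FitReport:
    losses: list[float]
    validation_r2: float
    epochs_run: int
    seed: int
    config: TrainingConfig


def objective(m, x, zeta: float = 0.0) -> float:
    """MSE (mean over observations and genes) plus zeta times the summed
    squared Frobenius norms of every weight matrix present."""
    if isinstance(m, JRLModel):
        raise ValueError("use objective on a context_model for JRL")
    arr = m.align(x)
    xhat = forward(m, arr)
    mse = float(np.mean((arr - xhat) ** 2))
    penalty = sum(float(np.sum(l.weight**2)) for l in m.layers)
    return mse + zeta * penalty


class _Adam:
    def __init__(self, shapes, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = [0] * len(shapes)

    def step(self, idx, weight, grad):
        self.t[idx] += 1
        t = self.t[idx]
        self.m[idx] = self.b1 * self.m[idx] + (1 - self.b1) * grad
        self.v[idx] = self.b2 * self.v[idx] + (1 - self.b2) * grad**2
        mhat = self.m[idx] / (1 - self.b1**t)
        vhat = self.v[idx] / (1 - self.b2**t)
        weight -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _dropout(rng, x, p):
    if p == 0:
        return x
    keep = rng.random(x.shape) >= p
    return x * keep / (1.0 - p)


def _batch_grads(layers: list[Layer], xb: np.ndarray, cfg: TrainingConfig, rng, zeta):
    """Forward with dropout, backprop of MSE + ridge; returns (grads, loss)."""
    h = _dropout(rng, xb, cfg.dropout_input)
    pre, post = [], []
    for li, layer in enumerate(layers):
        z = h @ layer.weight.T
        a = np.maximum(0.0, z) if layer.activation == "relu0" else z
        if li == 0 and cfg.dropout_latent > 0:
            a = _dropout(rng, a, cfg.dropout_latent)
        pre.append(z)
        post.append(h)  # input to this layer
        h = a
    xhat = h
    resid = xhat - xb
    loss = float(np.mean(resid**2))
    grads = [None] * len(layers)
    d = 2.0 * resid / resid.size
    for li in range(len(layers) - 1, -1, -1):
        layer = layers[li]
        if layer.activation == "relu0":
            d = d * relu0_grad(pre[li])
        grads[li] = d.T @ post[li] + 2.0 * zeta * layer.weight
        if li > 0:
            d = d @ layer.weight
    if zeta > 0:
        loss += zeta * sum(float(np.sum(l.weight**2)) for l in layers)
    return grads, loss


def fit(
    m,
    x_train,
    config: TrainingConfig,
    contexts=None,
    x_val=None,
    val_contexts=None,
):
    """Train a GRNModel or JRLModel in place; returns (model, FitReport).

    For a JRLModel, ``contexts`` labels each training observation; data for
    each context is batched separately and routed through that context's
    encoder with Pi and Theta shared. Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    is_jrl = isinstance(m, JRLModel)
    arr = m.align(x_train)

    if is_jrl:
        if contexts is None:
            raise ValueError("JRL training requires context labels")
        labels = np.asarray([str(c) for c in contexts])
        unknown = set(np.unique(labels)) - set(m.encoders)
        if unknown:
            raise ValueError(f"unknown context labels: {sorted(unknown)}")
        ctx_names = sorted(m.encoders)
        params = [m.encoders[c] for c in ctx_names] + [m.inter, m.decoder]
        ctx_param = {c: i for i, c in enumerate(ctx_names)}
        shared_idx = (len(ctx_names), len(ctx_names) + 1)
    else:
        params = m.layers

    opt = _Adam([p.weight.shape for p in params], config.learning_rate)
    losses: list[float] = []

    for _ in range(config.epochs):
        epoch_losses = []
        if is_jrl:
            batches = []
            for c in ctx_names:
                idx = np.nonzero(labels == c)[0]
                if len(idx) == 0:
                    continue
                idx = rng.permutation(idx)
                for s in range(0, len(idx), config.batch_size):
                    batches.append((c, idx[s:s + config.batch_size]))
            order = rng.permutation(len(batches))
            for bi in order:
                c, idx = batches[bi]
                layers = [m.encoders[c], m.inter, m.decoder]
                grads, loss = _batch_grads(layers, arr[idx], config, rng, config.zeta)
                _check_finite(loss)
                for pi, g in zip((ctx_param[c], *shared_idx), grads):
                    opt.step(pi, params[pi].weight, g)
                    params[pi].apply_mask()
                epoch_losses.append(loss)
        else:
            idx = rng.permutation(arr.shape[0])
            for s in range(0, len(idx), config.batch_size):
                b = idx[s:s + config.batch_size]
                grads, loss = _batch_grads(m.layers, arr[b], config, rng, config.zeta)
                _check_finite(loss)
                for pi, g in enumerate(grads):
                    opt.step(pi, params[pi].weight, g)
                    params[pi].apply_mask()
                epoch_losses.append(loss)
        losses.append(float(np.mean(epoch_losses)))

    m.trained = True
    val_r2 = float("nan")
    if x_val is not None:
        from .evaluation import r_squared
        va = m.align(x_val)
        xhat = forward_jrl(m, va, val_contexts) if is_jrl else forward(m, va)
        val_r2 = r_squared(va, xhat)
    report = FitReport(losses=losses, validation_r2=val_r2,
                       epochs_run=config.epochs, seed=config.seed, config=config)
    return m, report


def _check_finite(loss: float) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite training loss ({loss}); reduce the learning rate or "
            "check input scaling"
        )


def grid_search(
    x,
    p: PriorMatrix,
    gold: EdgeSet,
    zeta_grid=ZETA_GRID,
    dropout_grid=((0.5, 0.0),),
    repeats: int = 2,
    seed: int = 0,
    architecture: str = "shallow",
    epochs: int = 100,
    batch_size: int = 256,
) -> pd.DataFrame:
    """Cross-validated hyperparameter table.

    For each (zeta, p_input, p_latent) and repeat: split observations 50/50
    into train/validation, fit from a fresh prior-primed initialization,
    score held-out-edge recovery (AUPR, prior edges excluded from the
    candidate universe) and validation R^2; report means over repeats.
    ``gold`` must be disjoint from the training prior.
    """
    from .erv import extract_grn
    from .evaluation import aupr, r_squared, candidate_universe
    from .model import initialize_from_prior

    if len(zeta_grid) == 0 or len(dropout_grid) == 0:
        raise ValueError("hyperparameter grids must be nonempty")
    overlap = gold.edges & p.edge_set().edges
    if overlap:
        raise ValueError(f"gold standard overlaps training prior: {sorted(overlap)[:5]}")

    if isinstance(x, ExpressionMatrix):
        arr = x.values
        x_genes = x.gene_names
    else:
        arr = np.asarray(x, dtype=float)
        x_genes = p.genes
    universe = candidate_universe(p, exclude_prior=True)

    rows = []
    for zeta in zeta_grid:
        for p_in, p_lat in dropout_grid:
            auprs, r2s = [], []
            for rep in range(repeats):
                rng = np.random.default_rng(seed + rep)
                perm = rng.permutation(arr.shape[0])
                half = arr.shape[0] // 2
                tr, va = perm[:half], perm[half:]
                model = initialize_from_prior(p, architecture, seed=seed + rep)
                cfg = TrainingConfig(zeta=zeta, dropout_input=p_in, dropout_latent=p_lat,
                                     epochs=epochs, batch_size=batch_size, seed=seed + rep)
                xt = ExpressionMatrix([f"o{i}" for i in tr], list(x_genes), arr[tr],
                                      stage="feature-scaled")
                fit(model, xt, cfg)
                ranked = extract_grn(model, arr[tr])
                auprs.append(aupr(ranked, gold, universe).aupr)
                r2s.append(r_squared(arr[va], forward(model, arr[va])))
            rows.append({"zeta": zeta, "dropout_input": p_in, "dropout_latent": p_lat,
                         "mean_aupr": float(np.mean(auprs)), "mean_r2": float(np.mean(r2s))})
    return pd.DataFrame(rows)


def select_hyperparameters(table: pd.DataFrame) -> pd.Series:
    """Selection rule: the row maximizing mean validation R^2 (AUPR is
    reported alongside, not optimized)."""
    return table.loc[table["mean_r2"].idxmax()]
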