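"""Shared fixtures and independent oracle implementations.

The oracle functions here re-derive quantities by explicit brute force
(two forward passes written out by hand, quadratic interval scans,
binomial-coefficient tail sums) and stay independent of the library code
paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import primegrn as pg


# --------------------------------------------------------------------------
# independent oracles


def oracle_forward(model, x):
    """Explicit forward pass written out layer by layer (no Layer.__call__)."""
    h = np.asarray(x, dtype=float)
    for layer in model.layers:
        z = h @ layer.weight.T
        h = np.maximum(0.0, z) if layer.activation == "relu0" else z
    return h


def oracle_erv(model, x, layer="tf"):
    """Two explicit forward passes and the 1 - MSE ratio, per (gene, feature)."""
    x = np.asarray(x, dtype=float)

    def act(z, a):
        return np.maximum(0.0, z) if a == "relu0" else z

    phi = act(x @ model.encoder.weight.T, model.encoder.activation)
    if layer == "tf":
        latent = phi

        def decode(z):
            if model.inter is not None:
                z = act(z @ model.inter.weight.T, model.inter.activation)
            return act(z @ model.decoder.weight.T, model.decoder.activation)
    else:
        latent = act(phi @ model.inter.weight.T, model.inter.activation)

        def decode(z):
            return act(z @ model.decoder.weight.T, model.decoder.activation)

    mse_full = ((x - decode(latent)) ** 2).mean(axis=0)
    n_feat = latent.shape[1]
    out = np.zeros((x.shape[1], n_feat))
    for k in range(n_feat):
        z = latent.copy()
        z[:, k] = 0.0
        mse_pert = ((x - decode(z)) ** 2).mean(axis=0)
        for i in range(x.shape[1]):
            if mse_pert[i] == 0:
                out[i, k] = 0.0
            else:
                out[i, k] = 1.0 - mse_full[i] / mse_pert[i]
    return out


def oracle_interlayer_erv(model, x, eps1=0.0, eps2=0.0):
    """Summed-MSE interlayer score over intersection gene sets, by brute force."""
    x = np.asarray(x, dtype=float)

    def act(z, a):
        return np.maximum(0.0, z) if a == "relu0" else z

    phi = act(x @ model.encoder.weight.T, model.encoder.activation)

    def from_tf(z):
        h = act(z @ model.inter.weight.T, model.inter.activation)
        return act(h @ model.decoder.weight.T, model.decoder.activation)

    mse_full = ((x - from_tf(phi)) ** 2).mean(axis=0)
    n_tf = phi.shape[1]
    mse_pert_tf = np.zeros((x.shape[1], n_tf))
    for k in range(n_tf):
        z = phi.copy()
        z[:, k] = 0.0
        mse_pert_tf[:, k] = ((x - from_tf(z)) ** 2).mean(axis=0)

    xi_tf = oracle_erv(model, x, layer="tf")
    xi_mtf = oracle_erv(model, x, layer="mtf")
    n_mtf = model.inter.weight.shape[0]
    out = np.zeros((n_mtf, n_tf))
    for m in range(n_mtf):
        for k in range(n_tf):
            genes = [
                i for i in range(x.shape[1])
                if xi_tf[i, k] > eps1 and xi_mtf[i, m] > eps2
            ]
            if not genes:
                continue
            denom = sum(mse_pert_tf[i, k] for i in genes)
            if denom == 0:
                continue
            out[m, k] = 1.0 - sum(mse_full[i] for i in genes) / denom
    return out


def oracle_fisher_one_sided(table):
    """One-sided (enrichment) Fisher p-value as an explicit hypergeometric
    tail sum from binomial coefficients."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for aa in range(a, min(row1, col1) + 1):
        bb, cc = row1 - aa, col1 - aa
        dd = n - row1 - cc
        if bb < 0 or cc < 0 or dd < 0:
            continue
        p += (math.comb(col1, aa) * math.comb(n - col1, bb)) / math.comb(n, row1)
    return p


def oracle_aupr(ranked_labels, n_pos):
    """Average precision from an ordered boolean list, by direct enumeration."""
    tp = 0
    ap = 0.0
    for rank, is_pos in enumerate(ranked_labels, start=1):
        if is_pos:
            tp += 1
            ap += tp / rank
    return ap / n_pos


def make_small_trained(seed, architecture="shallow", n_genes=8, n_tfs=4,
                       n_obs=20, epochs=15, activations=None):
    """A small trained model plus its training data, for oracle checks."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    tfs = [f"t{i}" for i in range(n_tfs)]
    support = rng.random((n_genes, n_tfs)) < 0.5
    support[rng.integers(n_genes, size=n_tfs), np.arange(n_tfs)] = True
    prior = pg.PriorMatrix(genes, tfs, support.astype(float))
    x = rng.normal(size=(n_obs, n_genes))
    model = pg.initialize_from_prior(prior, architecture, seed=seed,
                                     activations=activations)
    cfg = pg.TrainingConfig(epochs=epochs, batch_size=8, dropout_input=0.0, seed=seed)
    pg.fit(model, x, cfg)
    return model, x, prior


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def toy_prior():
    return pg.PriorMatrix(
        genes=["g0", "g1", "g2"],
        tfs=["tA", "tB"],
        values=np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]),
    )


@pytest.fixture(scope="session")
def benchmark():
    """The synthetic study conditions used throughout: 20 TFs, 200 genes,
    500 samples, out-degree 10, fn 0.2 / fp 0.1 prior corruption."""
    return pg.make_benchmark(pg.SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def trained_benchmark(benchmark):
    model = pg.initialize_from_prior(benchmark.prior, "hierarchical", seed=0)
    model, report = pg.fit(model, benchmark.expression,
                           pg.TrainingConfig(epochs=400, seed=0))
    return model, report
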