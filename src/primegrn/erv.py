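"""Explained relative variance (ERV): latent-feature knockout interpretation.

ERV is a coefficient of partial determination computed without retraining.
For a trained model, latent feature k is knocked out by setting its
activation to zero; the per-gene reconstruction error of the perturbed
model is compared with the full model:

    xi2[i, k] = 1 - MSE_full[i] / MSE_perturbed[i]

so xi2 lies in (-inf, 1], a predictive link has xi2 in (0, 1], and a
feature whose removal changes nothing scores exactly 0. ERV ranks TF->gene
(and mTF->gene) edges for network extraction, scores hidden-layer weights
through an intersection-set variant, drives iterative pruning of
non-predictive weights, and — restricted to observation subsets — yields
context-specific networks from a single trained model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GRNModel, JRLModel

logger = logging.getLogger(__name__)


@dataclass
class ERVMatrix:
    """Genes x latent-features xi2 for one layer of a trained model."""

    values: np.ndarray
    genes: list[str]
    features: list[str]
    layer: str          # "tf" or "mtf"
    n_obs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.features)


@dataclass
class InterlayerERV:
    """xi2 for hidden-layer weights pi[m, k] over intersection gene sets."""

    values: np.ndarray  # mtfs x tfs, matching Pi's shape
    mtfs: list[str]
    tfs: list[str]
    eps1: float
    eps2: float


@dataclass
class RelativeERV:
    """Per-gene xi2 normalized by the gene's maximum xi2.

    Genes whose maximum xi2 is <= 0 cannot be explained by any latent
    feature; their rows are zeroed and flagged.
    """

    values: np.ndarray
    genes: list[str]
    features: list[str]
    gene_max: np.ndarray
    unexplainable: np.ndarray  # boolean per gene


@dataclass
class RankedEdgeList:
    """Regulator->gene edges ranked by descending xi2; ties broken by
    (regulator, gene) lexical order."""

    table: pd.DataFrame  # columns: regulator, gene, erv, sign, rank

    def __len__(self) -> int:
        return len(self.table)

    def save(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def load(cls, path: str) -> "RankedEdgeList":
        return cls(pd.read_csv(path, sep="\t"))


def _require_trained(m) -> None:
    if not m.trained:
        raise ValueError("model must be trained before computing ERV")


def _per_gene_mse(x: np.ndarray, xhat: np.ndarray) -> np.ndarray:
    return np.mean((x - xhat) ** 2, axis=0)


def _latent_and_propagate(m: GRNModel, arr: np.ndarray, layer: str):
    """Base latent activations and the map from that layer to the output."""
    phi = m.encoder(arr)
    if layer == "tf":
        if m.inter is None:
            return phi, m.decoder, list(m.tfs)
        return phi, (lambda z: m.decoder(m.inter(z))), list(m.tfs)
    if layer == "mtf":
        if m.inter is None:
            raise ValueError("shallow model has no mTF layer")
        return m.inter(phi), m.decoder, list(m.mtfs)
    raise ValueError(f"unknown layer {layer!r}")


def _knockout_mse(arr, latent, propagate):
    """Per-gene MSE of the full model and of each single-feature knockout."""
    xhat = propagate(latent)
    mse_full = _per_gene_mse(arr, xhat)
    n_feat = latent.shape[1]
    mse_pert = np.empty((arr.shape[1], n_feat))
    for k in range(n_feat):
        z = latent.copy()
        z[:, k] = 0.0
        mse_pert[:, k] = _per_gene_mse(arr, propagate(z))
    return mse_full, mse_pert


def _xi2(mse_full, mse_pert):
    with np.errstate(divide="ignore", invalid="ignore"):
        xi = 1.0 - mse_full[:, None] / mse_pert
    xi[mse_pert == 0] = 0.0  # perturbation changed nothing
    return xi


def erv_latent(m: GRNModel, x, layer: str = "tf") -> ERVMatrix:
    """xi2 of every latent feature in ``layer`` for every output gene.

    Evaluation is deterministic (no dropout); the model is not retrained.
    For the TF layer of a hierarchical model, the knockout propagates
    through the mTF layer, so this is the indirect TF->gene effect.
    """
    _require_trained(m)
    arr = m.align(x)
    if arr.shape[0] == 0:
        raise ValueError("expression matrix is empty")
    latent, propagate, features = _latent_and_propagate(m, arr, layer)
    mse_full, mse_pert = _knockout_mse(arr, latent, propagate)
    return ERVMatrix(_xi2(mse_full, mse_pert), list(m.genes), features, layer,
                     n_obs=arr.shape[0])


def erv_interlayer(m: GRNModel, x, eps1: float = 0.0, eps2: float = 0.0) -> InterlayerERV:
    """xi2 for each hidden-layer weight pi[m, k] of a hierarchical model.

    For each (mTF m, TF k) pair, genes predictive for TF k (indirect xi2 >
    eps1) are intersected with genes predictive for mTF m (xi2 > eps2); the
    score is 1 minus the ratio of summed full-model MSE to summed
    TF-k-knockout MSE over that intersection, and exactly 0 when the
    intersection is empty.
    """
    _require_trained(m)
    if m.inter is None:
        raise ValueError("interlayer ERV requires a hierarchical model")
    arr = m.align(x)
    phi = m.encoder(arr)

    tf_latent = phi
    tf_prop = lambda z: m.decoder(m.inter(z))  # noqa: E731
    mse_full, mse_pert_tf = _knockout_mse(arr, tf_latent, tf_prop)
    xi_tf = _xi2(mse_full, mse_pert_tf)

    mtf_latent = m.inter(phi)
    _, mse_pert_mtf = _knockout_mse(arr, mtf_latent, m.decoder)
    xi_mtf = _xi2(mse_full, mse_pert_mtf)

    n_mtf, n_tf = m.inter.weight.shape
    out = np.zeros((n_mtf, n_tf))
    tf_pass = xi_tf > eps1     # genes x tfs
    mtf_pass = xi_mtf > eps2   # genes x mtfs
    for mi in range(n_mtf):
        for k in range(n_tf):
            sel = tf_pass[:, k] & mtf_pass[:, mi]
            if not sel.any():
                continue
            denom = mse_pert_tf[sel, k].sum()
            if denom == 0:
                continue
            out[mi, k] = 1.0 - mse_full[sel].sum() / denom
    return InterlayerERV(out, list(m.mtfs), list(m.tfs), eps1, eps2)


def relative_erv(e: ERVMatrix) -> RelativeERV:
    """Normalize each gene's xi2 row by its maximum xi2 (Eq.-style selection
    score); rows whose maximum is <= 0 are zeroed and flagged."""
    if not np.isfinite(e.values).all():
        raise ValueError("ERV matrix must be finite")
    gene_max = e.values.max(axis=1)
    unexplainable = gene_max <= 0
    safe = np.where(unexplainable, 1.0, gene_max)
    rel = e.values / safe[:, None]
    rel[unexplainable] = 0.0
    return RelativeERV(rel, list(e.genes), list(e.features), gene_max, unexplainable)


def extract_grn(m: GRNModel, x) -> RankedEdgeList:
    """TF->gene network ranked by xi2.

    Shallow: direct TF->gene effects, restricted to the nonzero support of
    the decoder Theta. Hierarchical: indirect TF->gene effects through the
    mTF layer (knock out the TF activation, measure downstream gene error),
    over all TF x gene pairs. The sign annotation is the sign of the net
    model weight path (Theta, or Theta @ Pi).
    """
    _require_trained(m)
    e = erv_latent(m, x, layer="tf")
    if m.inter is None:
        support = m.decoder.weight != 0          # genes x tfs
        path = m.decoder.weight
    else:
        support = np.ones_like(e.values, dtype=bool)
        path = m.decoder.weight @ m.inter.weight  # genes x tfs
    gi, ki = np.nonzero(support)
    table = pd.DataFrame({
        "regulator": [m.tfs[k] for k in ki],
        "gene": [m.genes[g] for g in gi],
        "erv": e.values[gi, ki],
        "sign": np.sign(path[gi, ki]).astype(int),
    })
    table = table.sort_values(
        ["erv", "regulator", "gene"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankedEdgeList(table)


def context_erv(m: GRNModel, x, context_labels, layer: str = "tf") -> dict[str, ERVMatrix]:
    """xi2 computed separately within each context's observations.

    The model is unchanged across contexts — this is post-training analysis,
    so one trained model yields one network per context. Contexts with fewer
    than 2 observations are skipped with a warning.
    """
    _require_trained(m)
    arr = m.align(x)
    labels = np.asarray([str(c) for c in context_labels])
    if len(labels) != arr.shape[0]:
        raise ValueError("one context label per observation required")
    out: dict[str, ERVMatrix] = {}
    for c in np.unique(labels):
        sel = labels == c
        if sel.sum() < 2:
            logger.warning("context %r has < 2 observations; skipped", c)
            continue
        out[c] = erv_latent(m, arr[sel], layer=layer)
    return out


def prune(
    m: GRNModel,
    x,
    config=None,
    eps: float = 0.0,
    max_iters: int = 10,
    eps1: float = 0.0,
    eps2: float = 0.0,
):
    """Iteratively remove non-predictive weights and refit.

    Each iteration: compute xi2 and relative xi2 for the decoder's input
    layer; zero decoder weights whose relative xi2 is <= eps; for a
    hierarchical model additionally zero hidden-layer weights pi[m, k] whose
    interlayer xi2 is <= 0; then refit the surviving weights (warm start).
    Stops when an iteration removes nothing or after ``max_iters``. Nonzero
    counts are non-increasing by construction (removals are recorded in
    support masks).

    Returns (model, iteration log) where the log is a DataFrame with per-
    iteration removal and nonzero counts.
    """
    from .training import TrainingConfig, fit

    _require_trained(m)
    if eps >= 1:
        raise ValueError("eps must be < 1 (eps >= 1 would remove every weight)")
    if config is None:
        config = TrainingConfig()

    if m.decoder.mask is None:
        m.decoder.mask = np.ones_like(m.decoder.weight, dtype=bool)
    if m.inter is not None and m.inter.mask is None:
        m.inter.mask = np.ones_like(m.inter.weight, dtype=bool)

    dec_layer = "mtf" if m.inter is not None else "tf"
    log = []
    for it in range(max_iters):
        rel = relative_erv(erv_latent(m, x, layer=dec_layer))
        drop_dec = m.decoder.mask & (m.decoder.weight != 0) & (rel.values <= eps)
        n_dec = int(drop_dec.sum())
        m.decoder.mask &= ~drop_dec
        m.decoder.apply_mask()

        n_pi = 0
        if m.inter is not None:
            inter_xi = erv_interlayer(m, x, eps1=eps1, eps2=eps2)
            drop_pi = m.inter.mask & (m.inter.weight != 0) & (inter_xi.values <= 0)
            n_pi = int(drop_pi.sum())
            m.inter.mask &= ~drop_pi
            m.inter.apply_mask()

        log.append({
            "iteration": it, "removed_decoder": n_dec, "removed_inter": n_pi,
            "nnz_decoder": int(np.count_nonzero(m.decoder.weight)),
            "nnz_inter": int(np.count_nonzero(m.inter.weight)) if m.inter is not None else 0,
        })
        if n_dec == 0 and n_pi == 0:
            break
        refit_cfg = replace_epochs(config)
        fit(m, m.align(x), refit_cfg)
    return m, pd.DataFrame(log)


def replace_epochs(config):
    """A copy of the config using the post-pruning refit epoch budget."""
    from dataclasses import replace as _replace
    return _replace(config, epochs=config.refit_epochs)


def save_erv(e: ERVMatrix, path: str) -> None:
    e.to_frame().to_csv(path, sep="\t")


def load_erv(path: str, layer: str = "tf") -> ERVMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ERVMatrix(df.to_numpy(float), list(map(str, df.index)),
                     list(map(str, df.columns)), layer)
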