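"""Structure-primed autoencoder architectures for GRN inference.

The encoder maps gene expression x to transcription-factor activity (TFA)
phi = sigma(W x), where the support of W is fixed to the nonzero pattern of
the prior network P: each TF only reads from the genes the prior links to
it, enforcing the causal flow from regulator to target. The shallow model
decodes phi directly, x_hat = sigma(Theta phi); the hierarchical model
inserts a meta-TF (mTF) layer, phi_hat = sigma(Pi phi), whose features
aggregate TFs into pathway-like groups. Joint representation learning (JRL)
uses one encoder per biological context with Pi and Theta shared.

Weights outside the prior support are exactly zero at all times — at
initialization and after every training step.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np

from .preprocess import ExpressionMatrix
from .priors import PriorMatrix

logger = logging.getLogger(__name__)

ACTIVATIONS = ("linear", "relu0")


def relu0(z):
    """Rectifier max(0, z); its subgradient at z == 0 is taken as 1,
    so units sitting exactly at zero still receive gradient."""
    return np.maximum(0.0, np.asarray(z, dtype=float))


def relu0_grad(z):
    """Derivative of relu0 with the z == 0 convention: 1 for z >= 0."""
    return (np.asarray(z) >= 0.0).astype(float)


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "linear":
        return z
    if activation == "relu0":
        return relu0(z)
    raise ValueError(f"unknown activation {activation!r}")


@dataclass
class Layer:
    """A weight matrix (out_features x in_features) with an optional fixed
    support mask and an activation applied to its output."""

    weight: np.ndarray
    activation: str = "linear"
    mask: np.ndarray | None = None  # bool; True where the weight may be nonzero

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.weight.shape:
                raise ValueError("mask shape must match weight shape")
            self.weight = self.weight * self.mask

    def apply_mask(self) -> None:
        if self.mask is not None:
            self.weight[~self.mask] = 0.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """x: (samples, in_features) -> (samples, out_features)."""
        return _activate(x @ self.weight.T, self.activation)


@dataclass
class GRNModel:
    """Shallow or hierarchical structure-primed autoencoder."""

    genes: list[str]
    tfs: list[str]
    encoder: Layer                   # tfs x genes, support = prior
    decoder: Layer                   # genes x latent
    inter: Layer | None = None       # mtfs x tfs (hierarchical only)
    mtfs: list[str] | None = None
    trained: bool = False

    @property
    def architecture(self) -> str:
        return "hierarchical" if self.inter is not None else "shallow"

    @property
    def layers(self) -> list[Layer]:
        if self.inter is None:
            return [self.encoder, self.decoder]
        return [self.encoder, self.inter, self.decoder]

    def align(self, x) -> np.ndarray:
        """Return a samples x model-genes array from an ExpressionMatrix or
        ndarray. Genes missing from the data are imputed as zero columns."""
        if isinstance(x, ExpressionMatrix):
            idx = {g: i for i, g in enumerate(x.gene_names)}
            overlap = [g for g in self.genes if g in idx]
            if not overlap:
                raise ValueError("no overlap between model genes and data genes")
            if len(overlap) < len(self.genes):
                logger.warning(
                    "%d model genes absent from data; imputing zeros",
                    len(self.genes) - len(overlap),
                )
            out = np.zeros((x.n_obs, len(self.genes)))
            for j, g in enumerate(self.genes):
                if g in idx:
                    out[:, j] = x.values[:, idx[g]]
            return out
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != len(self.genes):
            raise ValueError(f"expected (samples, {len(self.genes)}) array, got {x.shape}")
        return x


@dataclass
class JRLModel:
    """Joint representation learning: per-context structure-primed encoders
    feeding a shared mTF layer and decoder."""

    genes: list[str]
    tfs: list[str]
    encoders: dict[str, Layer]
    inter: Layer
    decoder: Layer
    mtfs: list[str]
    trained: bool = False

    @property
    def architecture(self) -> str:
        return "jrl"

    def context_model(self, context: str) -> GRNModel:
        """The hierarchical model seen by one context (shared layers aliased)."""
        if context not in self.encoders:
            raise KeyError(f"unknown context {context!r}")
        return GRNModel(
            genes=self.genes, tfs=self.tfs, encoder=self.encoders[context],
            decoder=self.decoder, inter=self.inter, mtfs=self.mtfs,
            trained=self.trained,
        )

    def align(self, x) -> np.ndarray:
        proxy = next(iter(self.encoders.values()))
        return GRNModel(self.genes, self.tfs, proxy, self.decoder).align(x)


@dataclass
class LatentActivity:
    """Per-observation TF activity (and mTF activity when hierarchical)."""

    tfa: np.ndarray                  # observations x TFs
    tfs: list[str]
    mtfa: np.ndarray | None = None   # observations x mTFs
    mtfs: list[str] | None = None


def initialize_from_prior(
    p: PriorMatrix,
    architecture: str = "shallow",
    seed: int = 0,
    n_mtfs: int | None = None,
    activations: dict[str, str] | None = None,
) -> GRNModel:
    """Build a model whose encoder support is the prior's nonzero pattern.

    Nonzero encoder entries are drawn uniformly in (0, 1/sqrt(fan-in)) — the
    fan-in being the TF's number of prior targets — and are therefore
    non-negative; the shallow decoder Theta starts as the non-negative
    mirror (transpose) of W on the same entries but all its entries are free
    thereafter. The hierarchical Pi starts near identity with small noise,
    and Theta starts with small non-negative values on all entries.
    """
    if architecture not in ("shallow", "hierarchical"):
        raise ValueError(f"unknown architecture {architecture!r}")
    rng = np.random.default_rng(seed)
    support = (p.values != 0)                      # genes x TFs
    fan_in = support.sum(axis=0).astype(float)     # per TF
    w = rng.uniform(0.0, 1.0, size=support.T.shape) / np.sqrt(fan_in)[:, None]
    w = np.abs(w) * support.T                      # tfs x genes

    defaults = (
        {"encoder": "linear", "inter": "linear", "decoder": "linear"}
        if architecture == "shallow"
        else {"encoder": "relu0", "inter": "relu0", "decoder": "linear"}
    )
    if activations:
        defaults.update(activations)

    encoder = Layer(w, activation=defaults["encoder"], mask=support.T.copy())

    if architecture == "shallow":
        decoder = Layer(w.T.copy(), activation=defaults["decoder"], mask=None)
        return GRNModel(list(p.genes), list(p.tfs), encoder, decoder)

    k = p.n_tfs
    m = n_mtfs or k
    pi = np.eye(m, k) + rng.normal(0.0, 0.01, size=(m, k))
    inter = Layer(pi, activation=defaults["inter"], mask=None)
    theta = np.abs(rng.normal(0.0, 0.01, size=(p.n_genes, m)))
    decoder = Layer(theta, activation=defaults["decoder"], mask=None)
    mtfs = [f"mTF_{i}" for i in range(m)]
    return GRNModel(list(p.genes), list(p.tfs), encoder, decoder, inter, mtfs)


def initialize_jrl(
    priors: dict[str, PriorMatrix],
    seed: int = 0,
    n_mtfs: int | None = None,
    activations: dict[str, str] | None = None,
) -> JRLModel:
    """Build a JRL model from one prior per context; all priors must share
    the TF axis (and here the gene axis)."""
    if not priors:
        raise ValueError("at least one context prior required")
    contexts = sorted(priors)
    first = priors[contexts[0]]
    for c in contexts[1:]:
        if priors[c].tfs != first.tfs or priors[c].genes != first.genes:
            raise ValueError("all context priors must share gene and TF axes")
    base = initialize_from_prior(first, "hierarchical", seed, n_mtfs, activations)
    encoders = {contexts[0]: base.encoder}
    for i, c in enumerate(contexts[1:], start=1):
        m = initialize_from_prior(priors[c], "hierarchical", seed + i, n_mtfs, activations)
        encoders[c] = m.encoder
    return JRLModel(
        genes=base.genes, tfs=base.tfs, encoders=encoders,
        inter=base.inter, decoder=base.decoder, mtfs=base.mtfs,
    )


def encode_tfa(m: GRNModel, x) -> LatentActivity:
    """TF activity phi = sigma(W x) per observation; the hierarchical model
    also returns mTF activity phi_hat = sigma(Pi phi)."""
    arr = m.align(x)
    phi = m.encoder(arr)
    if m.inter is None:
        return LatentActivity(tfa=phi, tfs=list(m.tfs))
    phi_hat = m.inter(phi)
    return LatentActivity(tfa=phi, tfs=list(m.tfs), mtfa=phi_hat, mtfs=list(m.mtfs))


def forward(m, x, context: str | None = None) -> np.ndarray:
    """Reconstruction x_hat for a GRNModel, or for a JRLModel given a context
    label per call (all observations routed through that context's encoder)."""
    if isinstance(m, JRLModel):
        if context is None:
            raise ValueError("JRL forward requires a context label")
        return forward(m.context_model(context), x)
    arr = m.align(x)
    h = arr
    for layer in m.layers:
        h = layer(h)
    return h


def forward_jrl(m: JRLModel, x, labels) -> np.ndarray:
    """JRL forward for per-observation context labels."""
    arr = m.align(x)
    labels = np.asarray(labels)
    out = np.empty_like(arr)
    for c in np.unique(labels):
        if str(c) not in m.encoders:
            raise ValueError(f"unknown context label {c!r}")
        sel = labels == c
        out[sel] = forward(m.context_model(str(c)), arr[sel])
    return out


# --- serialization: text-only model directories -----------------------------

def _write_axis(path: str, names: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(names) + "\n")


def _read_axis(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n")]


def _write_layer(prefix: str, layer: Layer) -> None:
    # triplet TSV with %.17g round-trips float64 exactly
    r, c = np.nonzero(layer.weight)
    with open(prefix + ".weights.tsv", "w") as fh:
        for i, j in zip(r, c):
            fh.write(f"{i}\t{j}\t{layer.weight[i, j]:.17g}\n")
    if layer.mask is not None:
        r, c = np.nonzero(layer.mask)
        with open(prefix + ".mask.tsv", "w") as fh:
            for i, j in zip(r, c):
                fh.write(f"{i}\t{j}\n")


def _read_layer(prefix: str, shape: tuple[int, int], activation: str) -> Layer:
    w = np.zeros(shape)
    with open(prefix + ".weights.tsv") as fh:
        for line in fh:
            i, j, v = line.split("\t")
            w[int(i), int(j)] = float(v)
    mask = None
    if os.path.exists(prefix + ".mask.tsv"):
        mask = np.zeros(shape, dtype=bool)
        with open(prefix + ".mask.tsv") as fh:
            for line in fh:
                i, j = line.split("\t")
                mask[int(i), int(j)] = True
    return Layer(w, activation=activation, mask=mask)


def save_model(m, path: str) -> None:
    """Serialize a model to a directory of text files (bit-exact round trip)."""
    os.makedirs(path, exist_ok=True)
    _write_axis(os.path.join(path, "genes.tsv"), m.genes)
    _write_axis(os.path.join(path, "tfs.tsv"), m.tfs)
    cfg = {"architecture": m.architecture, "trained": str(m.trained)}
    if isinstance(m, JRLModel):
        _write_axis(os.path.join(path, "mtfs.tsv"), m.mtfs)
        _write_axis(os.path.join(path, "contexts.tsv"), sorted(m.encoders))
        for c in m.encoders:
            _write_layer(os.path.join(path, f"encoder.{c}"), m.encoders[c])
            cfg[f"activation.encoder.{c}"] = m.encoders[c].activation
        _write_layer(os.path.join(path, "inter"), m.inter)
        _write_layer(os.path.join(path, "decoder"), m.decoder)
        cfg["activation.inter"] = m.inter.activation
        cfg["activation.decoder"] = m.decoder.activation
    else:
        if m.mtfs is not None:
            _write_axis(os.path.join(path, "mtfs.tsv"), m.mtfs)
        _write_layer(os.path.join(path, "encoder"), m.encoder)
        cfg["activation.encoder"] = m.encoder.activation
        if m.inter is not None:
            _write_layer(os.path.join(path, "inter"), m.inter)
            cfg["activation.inter"] = m.inter.activation
        _write_layer(os.path.join(path, "decoder"), m.decoder)
        cfg["activation.decoder"] = m.decoder.activation
    with open(os.path.join(path, "config.txt"), "w") as fh:
        for k in sorted(cfg):
            fh.write(f"{k}={cfg[k]}\n")


def load_model(path: str):
    cfg = {}
    with open(os.path.join(path, "config.txt")) as fh:
        for line in fh:
            k, v = line.rstrip("\n").split("=", 1)
            cfg[k] = v
    genes = _read_axis(os.path.join(path, "genes.tsv"))
    tfs = _read_axis(os.path.join(path, "tfs.tsv"))
    n, k = len(genes), len(tfs)
    trained = cfg["trained"] == "True"
    arch = cfg["architecture"]
    if arch == "jrl":
        mtfs = _read_axis(os.path.join(path, "mtfs.tsv"))
        contexts = _read_axis(os.path.join(path, "contexts.tsv"))
        encoders = {
            c: _read_layer(os.path.join(path, f"encoder.{c}"), (k, n),
                           cfg[f"activation.encoder.{c}"])
            for c in contexts
        }
        inter = _read_layer(os.path.join(path, "inter"), (len(mtfs), k),
                            cfg["activation.inter"])
        decoder = _read_layer(os.path.join(path, "decoder"), (n, len(mtfs)),
                              cfg["activation.decoder"])
        return JRLModel(genes, tfs, encoders, inter, decoder, mtfs, trained)
    encoder = _read_layer(os.path.join(path, "encoder"), (k, n), cfg["activation.encoder"])
    inter = None
    mtfs = None
    latent = k
    if arch == "hierarchical":
        mtfs = _read_axis(os.path.join(path, "mtfs.tsv"))
        inter = _read_layer(os.path.join(path, "inter"), (len(mtfs), k),
                            cfg["activation.inter"])
        latent = len(mtfs)
    decoder = _read_layer(os.path.join(path, "decoder"), (n, latent),
                          cfg["activation.decoder"])
    return GRNModel(genes, tfs, encoder, decoder, inter, mtfs, trained)
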