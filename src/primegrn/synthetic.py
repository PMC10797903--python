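"""Ground-truth simulator: networks, TF activity, expression, noisy priors.

Emulates the generative assumptions of the structure-primed autoencoder:
a sparse signed TF->gene network, non-negative skewed (log-normal) TF
activity, expression as an (optionally rectified) linear readout of TFA
plus Gaussian noise, and prior evidence that is a corrupted view of the
true network (false negatives removed, false positives added). Context
effects are planted by toggling context-specific regulator activity off
outside its context, which makes context-restricted ERV and enrichment
testable with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import AccessibilityMask, ExpressionMatrix
from .priors import EdgeSet, PriorMatrix


@dataclass
class SyntheticSpec:
    """Study conditions for one simulated dataset."""

    n_genes: int = 200
    n_tfs: int = 20
    n_mtfs: int | None = None        # optional pathway grouping of TFs
    samples_per_context: int = 500
    contexts: int = 1
    out_degree: int = 10             # targets per TF (constant out-degree)
    tfa_mu: float = 0.0              # log-normal TFA parameters
    tfa_sigma: float = 0.5
    activation: str = "linear"       # readout: "linear" or "relu0"
    noise_sd: float = 0.5
    fp_rate: float = 0.1             # false prior edges, as fraction of true edges
    fn_rate: float = 0.2             # fraction of true edges missing from prior
    context_tfs_per_context: int = 0  # regulators active only in their context
    positive_weights: bool = False   # activator-only regulons (no sign flips)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.fp_rate, self.fn_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        for c in (self.n_genes, self.n_tfs, self.samples_per_context, self.contexts):
            if c < 1:
                raise ValueError("counts must be >= 1")


@dataclass
class SyntheticNetwork:
    tfs: list[str]
    genes: list[str]
    weights: np.ndarray              # tfs x genes, signed
    mtf_of_tf: np.ndarray | None = None

    def edge_set(self) -> EdgeSet:
        ti, gi = np.nonzero(self.weights)
        edges = {(self.tfs[t], self.genes[g]) for t, g in zip(ti, gi)}
        scores = {(self.tfs[t], self.genes[g]): float(self.weights[t, g])
                  for t, g in zip(ti, gi)}
        return EdgeSet(edges=edges, scores=scores)


@dataclass
class SyntheticDataset:
    network: SyntheticNetwork
    tfa: np.ndarray                  # samples x tfs (true activity)
    expression: ExpressionMatrix     # continuous readout + noise
    context_labels: np.ndarray
    context_of_tf: dict[str, str]    # context-specific regulators
    counts: ExpressionMatrix | None = None
    prior: PriorMatrix | None = None
    gold: EdgeSet | None = None
    mask: AccessibilityMask | None = None


def simulate_network(spec: SyntheticSpec) -> SyntheticNetwork:
    """Sparse signed TF->gene weights with constant out-degree; signs are
    equiprobable and magnitudes uniform in [0.5, 1.5]. With n_mtfs set, TFs
    are grouped round-robin into pathway labels (used only as metadata)."""
    if spec.out_degree > spec.n_genes:
        raise ValueError(
            f"out_degree {spec.out_degree} exceeds n_genes {spec.n_genes}"
        )
    rng = np.random.default_rng(spec.seed)
    tfs = [f"TF_{i}" for i in range(spec.n_tfs)]
    genes = [f"G_{i:04d}" for i in range(spec.n_genes)]
    w = np.zeros((spec.n_tfs, spec.n_genes))
    for t in range(spec.n_tfs):
        targets = rng.choice(spec.n_genes, size=spec.out_degree, replace=False)
        mag = rng.uniform(0.5, 1.5, size=spec.out_degree)
        sign = (np.ones(spec.out_degree) if spec.positive_weights
                else rng.choice((-1.0, 1.0), size=spec.out_degree))
        w[t, targets] = mag * sign
    mtf = None
    if spec.n_mtfs:
        mtf = np.arange(spec.n_tfs) % spec.n_mtfs
    return SyntheticNetwork(tfs=tfs, genes=genes, weights=w, mtf_of_tf=mtf)


def simulate_expression(network: SyntheticNetwork, spec: SyntheticSpec) -> SyntheticDataset:
    """Expression = activation(TFA @ W) + Gaussian noise.

    TFA is log-normal per sample and TF. With multiple contexts, the first
    ``context_tfs_per_context`` unassigned TFs are dedicated to each context
    and their activity is zero outside it (planted context regulons). A
    count-like variant is produced by treating exp(expression) as rates and
    multinomially sampling a log-normal sequencing depth per cell.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_ctx = spec.contexts
    n_samples = n_ctx * spec.samples_per_context
    labels = np.repeat([f"C{c}" for c in range(n_ctx)], spec.samples_per_context)

    tfa = rng.lognormal(spec.tfa_mu, spec.tfa_sigma, size=(n_samples, spec.n_tfs))

    context_of_tf: dict[str, str] = {}
    if n_ctx > 1 and spec.context_tfs_per_context > 0:
        need = n_ctx * spec.context_tfs_per_context
        if need > spec.n_tfs:
            raise ValueError("not enough TFs for the requested context regulons")
        t = 0
        for c in range(n_ctx):
            for _ in range(spec.context_tfs_per_context):
                context_of_tf[network.tfs[t]] = f"C{c}"
                tfa[labels != f"C{c}", t] = 0.0
                t += 1

    signal = tfa @ network.weights
    if spec.activation == "relu0":
        signal = np.maximum(0.0, signal)
    elif spec.activation != "linear":
        raise ValueError(f"unknown activation {spec.activation!r}")
    x = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)

    obs = [f"S_{i:05d}" for i in range(n_samples)]
    expr = ExpressionMatrix(obs, list(network.genes), x, stage="feature-scaled")

    # count-like variant: exp(signal) as relative rates, multinomial depth draw
    rates = np.exp(np.clip(signal, -10, 10))
    probs = rates / rates.sum(axis=1, keepdims=True)
    depths = rng.lognormal(np.log(5000), 0.3, size=n_samples).astype(int)
    counts = np.vstack([rng.multinomial(d, pr) for d, pr in zip(depths, probs)]).astype(float)
    counts_em = ExpressionMatrix(obs, list(network.genes), counts, stage="raw")

    return SyntheticDataset(
        network=network, tfa=tfa, expression=expr, context_labels=labels,
        context_of_tf=context_of_tf, counts=counts_em,
    )


def corrupt_prior(
    network: SyntheticNetwork, fp_rate: float, fn_rate: float, seed: int
) -> tuple[PriorMatrix, EdgeSet]:
    """A corrupted binary prior plus a disjoint gold standard.

    False negatives: a ``fn_rate`` fraction of true edges is removed from the
    prior and becomes the gold standard (true edges the model never sees).
    False positives: ``fp_rate`` (relative to the true edge count) non-edges
    are added as spurious evidence. The gold standard is disjoint from the
    returned prior by construction.
    """
    if fn_rate >= 1:
        raise ValueError("fn_rate must be < 1 (fn_rate 1 empties the prior)")
    rng = np.random.default_rng(seed)
    true = (network.weights != 0)        # tfs x genes
    ti, gi = np.nonzero(true)
    n_edges = len(ti)

    n_fn = int(round(fn_rate * n_edges))
    fn_pick = rng.choice(n_edges, size=n_fn, replace=False)
    prior = true.copy()
    prior[ti[fn_pick], gi[fn_pick]] = False
    gold = EdgeSet(edges={
        (network.tfs[ti[i]], network.genes[gi[i]]) for i in fn_pick
    })

    n_fp = int(round(fp_rate * n_edges))
    if n_fp:
        fi, fg = np.nonzero(~true)
        fp_pick = rng.choice(len(fi), size=n_fp, replace=False)
        prior[fi[fp_pick], fg[fp_pick]] = True

    p = PriorMatrix(list(network.genes), list(network.tfs),
                    prior.T.astype(float))
    return p, gold


def simulate_atac_mask(
    dataset: SyntheticDataset, accessible_rate: float = 0.8, seed: int = 0
) -> AccessibilityMask:
    """Bernoulli per-cell gene accessibility (regulated genes of an active
    context regulator are always accessible in that context)."""
    rng = np.random.default_rng(seed)
    e = dataset.expression
    values = (rng.random((e.n_obs, e.n_genes)) < accessible_rate).astype(int)
    return AccessibilityMask(list(e.obs_names), list(e.gene_names), values)


def simulate_phase_markers(
    n_cells: int = 500,
    markers_per_phase: int = 5,
    n_background_genes: int = 50,
    effect: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
):
    """Cells with planted cell-cycle marker signal.

    Each cell is assigned a phase (round-robin over G1, S, G2, M, M/G1); its
    own phase's marker genes are shifted up by ``effect`` standard
    deviations over Gaussian background. Returns (ExpressionMatrix, markers
    mapping, true labels).
    """
    from .preprocess import PHASE_ORDER

    rng = np.random.default_rng(seed)
    phases = list(PHASE_ORDER)
    labels = np.array([phases[i % len(phases)] for i in range(n_cells)])
    markers = {
        p: [f"{p.replace('/', '')}_MARK_{j}" for j in range(markers_per_phase)]
        for p in phases
    }
    genes = [g for p in phases for g in markers[p]]
    genes += [f"BG_{j}" for j in range(n_background_genes)]
    x = rng.normal(0.0, noise_sd, size=(n_cells, len(genes)))
    col = {g: i for i, g in enumerate(genes)}
    for p in phases:
        sel = labels == p
        for g in markers[p]:
            x[sel, col[g]] += effect
    em = ExpressionMatrix([f"cell_{i}" for i in range(n_cells)], genes, x,
                          stage="feature-scaled")
    return em, markers, labels


def make_benchmark(spec: SyntheticSpec) -> SyntheticDataset:
    """Network + expression + corrupted prior + gold standard in one call."""
    net = simulate_network(spec)
    ds = simulate_expression(net, spec)
    ds.prior, ds.gold = corrupt_prior(net, spec.fp_rate, spec.fn_rate, spec.seed + 2)
    return ds


def shuffle_expression(e: ExpressionMatrix, seed: int) -> ExpressionMatrix:
    """Negative-control data: permute each gene's values independently across
    observations, destroying gene-gene covariance while keeping marginals."""
    rng = np.random.default_rng(seed)
    x = e.values.copy()
    for j in range(x.shape[1]):
        rng.shuffle(x[:, j])
    return ExpressionMatrix(list(e.obs_names), list(e.gene_names), x, e.stage)
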