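"""Prior-knowledge regulatory networks: loading, splitting, shuffling, construction.

A prior network is a genes x TFs evidence matrix P. Its nonzero pattern
constrains ("primes") the encoder of the autoencoder, so every TF latent
feature only reads from the genes the prior links it to. Gold-standard edge
sets, held out of P, are used exclusively for scoring inferred networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)


@dataclass
class PriorMatrix:
    """Genes x TFs non-negative evidence matrix.

    ``values`` may be binary {0,1} or summed-signal weights; the encoder only
    uses the nonzero pattern. TF columns with no evidence are dropped at
    construction (a TF with no informative genes cannot be represented).
    """

    genes: list[str]
    tfs: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.tfs)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.tfs)} TFs"
            )
        _check_unique(self.genes, "gene")
        _check_unique(self.tfs, "TF")
        if np.any(self.values < 0):
            raise ValueError("prior matrix entries must be non-negative")
        if not np.isfinite(self.values).all():
            raise ValueError("prior matrix entries must be finite")
        if self.values.size == 0 or not self.values.any():
            raise ValueError("prior matrix is empty (no nonzero entries)")
        empty = ~self.values.any(axis=0)
        if empty.any():
            dropped = [t for t, e in zip(self.tfs, empty) if e]
            logger.warning("dropping %d all-zero TF columns: %s", len(dropped), dropped)
            self.tfs = [t for t, e in zip(self.tfs, empty) if not e]
            self.values = self.values[:, ~empty]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    @property
    def nnz(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def density(self) -> float:
        return self.nnz / self.values.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.tfs)

    def edge_set(self) -> "EdgeSet":
        gi, ti = np.nonzero(self.values)
        return EdgeSet(
            edges={(self.tfs[t], self.genes[g]) for g, t in zip(gi, ti)},
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PriorMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)), df.to_numpy(float))


@dataclass
class EdgeSet:
    """A set of (tf, gene) regulatory edges, optionally scored."""

    edges: set[tuple[str, str]]
    scores: dict[tuple[str, str], float] | None = None

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return edge in self.edges


@dataclass
class HoldoutSplit:
    """A prior split into a training part and a held-out gold standard."""

    prior_part: PriorMatrix
    heldout_part: EdgeSet
    fraction: float
    seed: int


@dataclass
class PeakRecord:
    """A genomic interval (0-based half-open) with a label and signal value."""

    chromosome: str
    start: int
    end: int
    label: str
    signal: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak start {self.start} must be < end {self.end}")
        if self.signal < 0:
            raise ValueError("peak signal must be non-negative")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})
    if dups:
        raise ValueError(f"duplicate {what} identifiers: {dups}")


def load_prior(path: str, format: str = "dense-tsv") -> PriorMatrix:
    """Load a prior matrix from a dense TSV (genes x TFs, headers) or a
    triplet TSV with columns (gene, tf, value)."""
    if format == "dense-tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique(list(df.index.astype(str)), "gene")
        _check_unique(list(df.columns.astype(str)), "TF")
        return PriorMatrix.from_frame(df)
    if format == "triplet-tsv":
        trip = pd.read_csv(path, sep="\t", header=None, names=["gene", "tf", "value"],
                           dtype={"gene": str, "tf": str})
        if trip.duplicated(["gene", "tf"]).any():
            dups = trip[trip.duplicated(["gene", "tf"])][["gene", "tf"]]
            raise ValueError(f"duplicate (gene, tf) triplets: {dups.values.tolist()}")
        df = trip.pivot(index="gene", columns="tf", values="value").fillna(0.0)
        df = df.sort_index(axis=0).sort_index(axis=1)
        return PriorMatrix.from_frame(df)
    raise ValueError(f"unknown prior format {format!r}")


def save_prior(p: PriorMatrix, path: str, format: str = "dense-tsv") -> None:
    if format == "dense-tsv":
        p.to_frame().to_csv(path, sep="\t")
    elif format == "triplet-tsv":
        gi, ti = np.nonzero(p.values)
        rows = [(p.genes[g], p.tfs[t], p.values[g, t]) for g, t in zip(gi, ti)]
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown prior format {format!r}")


def split_prior(p: PriorMatrix, holdout_fraction: float, seed: int) -> HoldoutSplit:
    """Hold out a uniform sample of prior edges as a gold standard.

    Held-out edges are zeroed in the returned training prior. If the holdout
    empties a TF column entirely, one held-out edge of that column (the
    lexicographically first by gene identifier) is returned to the prior so
    the TF stays representable in the model.
    """
    if not 0 < holdout_fraction < 1:
        raise ValueError(f"holdout_fraction must be in (0, 1), got {holdout_fraction}")
    rng = np.random.default_rng(seed)
    gi, ti = np.nonzero(p.values)
    nnz = len(gi)
    n_hold = int(round(holdout_fraction * nnz))
    pick = rng.choice(nnz, size=n_hold, replace=False)
    hold_mask = np.zeros(nnz, dtype=bool)
    hold_mask[pick] = True

    values = p.values.copy()
    values[gi[hold_mask], ti[hold_mask]] = 0.0

    # re-seed TF columns emptied by the split
    heldout = {(p.tfs[t], p.genes[g]) for g, t in zip(gi[hold_mask], ti[hold_mask])}
    for col in range(p.n_tfs):
        if not values[:, col].any():
            tf = p.tfs[col]
            candidates = sorted(g for t, g in heldout if t == tf)
            g = candidates[0]
            values[p.genes.index(g), col] = p.values[p.genes.index(g), col]
            heldout.discard((tf, g))

    return HoldoutSplit(
        prior_part=PriorMatrix(list(p.genes), list(p.tfs), values),
        heldout_part=EdgeSet(edges=heldout),
        fraction=holdout_fraction,
        seed=seed,
    )


def shuffle_prior(p: PriorMatrix, seed: int) -> PriorMatrix:
    """Negative-control prior: permute the gene labels of the rows.

    A single permutation of the gene axis preserves per-TF degree
    distributions and overall density exactly while destroying the
    gene-to-TF assignments.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(p.n_genes)
    return PriorMatrix(list(p.genes), list(p.tfs), p.values[perm])


def sparsify_prior(p: PriorMatrix, keep_fraction_per_tf: float = 0.015) -> PriorMatrix:
    """Keep only the top ``floor(keep_fraction * n_genes)`` values per TF column,
    shrinking the rest to zero. Ties at the cut are broken by gene-identifier
    order (earlier gene wins)."""
    if keep_fraction_per_tf <= 0:
        raise ValueError("keep_fraction_per_tf must be positive")
    k = int(np.floor(keep_fraction_per_tf * p.n_genes))
    values = p.values.copy()
    order = np.argsort(p.genes)  # rank of each row position by identifier
    id_rank = np.empty(p.n_genes, dtype=int)
    id_rank[order] = np.arange(p.n_genes)
    for col in range(p.n_tfs):
        v = values[:, col]
        nz = np.nonzero(v)[0]
        if len(nz) <= k:
            continue
        # sort descending by value, ties by gene identifier order
        key = sorted(nz, key=lambda i: (-v[i], id_rank[i]))
        drop = key[k:]
        v[drop] = 0.0
    return PriorMatrix(list(p.genes), list(p.tfs), values)


def peaks_to_prior(
    peaks: list[PeakRecord],
    genes: pd.DataFrame,
    regions: list[PeakRecord] | None = None,
    upstream_bp: int = 50_000,
    downstream_bp: int = 2_000,
) -> PriorMatrix:
    """Build a prior from TF binding peaks and gene annotations.

    ``genes`` is a DataFrame indexed by gene identifier with columns
    ``chromosome``, ``tss``, ``strand``, ``start``, ``end`` (0-based
    half-open span). A peak (by its midpoint) links to a gene when it lies
    within ``[TSS - upstream, TSS + downstream]`` oriented by strand and no
    other gene body lies between the peak midpoint and the TSS. If
    ``regions`` is given, peaks are first filtered to those overlapping a
    region. The prior entry is the sum of signal values of linked peaks.
    """
    required = {"chromosome", "tss", "strand", "start", "end"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene annotation missing columns: {sorted(missing)}")

    if regions is not None:
        trees: dict[str, IntervalTree] = {}
        for r in regions:
            trees.setdefault(r.chromosome, IntervalTree()).addi(r.start, r.end)
        peaks = [
            pk for pk in peaks
            if pk.chromosome in trees and trees[pk.chromosome].overlap(pk.start, pk.end)
        ]

    known_chroms = set(genes["chromosome"])
    skipped = sum(1 for pk in peaks if pk.chromosome not in known_chroms)
    if skipped:
        logger.warning("skipping %d peaks on chromosomes absent from the annotation", skipped)

    # interval trees of gene bodies per chromosome for the no-intervening-gene test
    body_trees: dict[str, IntervalTree] = {}
    for name, row in genes.iterrows():
        body_trees.setdefault(row["chromosome"], IntervalTree()).addi(
            int(row["start"]), int(row["end"]), name
        )

    gene_names = list(map(str, genes.index))
    tf_names = sorted({pk.label for pk in peaks if pk.chromosome in known_chroms})
    values = np.zeros((len(gene_names), len(tf_names)), dtype=float)
    tf_index = {t: j for j, t in enumerate(tf_names)}
    gene_index = {g: i for i, g in enumerate(gene_names)}

    for pk in peaks:
        if pk.chromosome not in known_chroms:
            continue
        mid = pk.midpoint
        sub = genes[genes["chromosome"] == pk.chromosome]
        for name, row in sub.iterrows():
            tss = int(row["tss"])
            if row["strand"] == "+":
                lo, hi = tss - upstream_bp, tss + downstream_bp
            else:
                lo, hi = tss - downstream_bp, tss + upstream_bp
            if not (lo <= mid <= hi):
                continue
            a, b = (mid, tss) if mid < tss else (tss, mid)
            blocked = False
            if b > a:
                for iv in body_trees[pk.chromosome].overlap(a, b):
                    if iv.data != name:
                        blocked = True
                        break
            if not blocked:
                values[gene_index[str(name)], tf_index[pk.label]] += pk.signal

    return PriorMatrix(gene_names, tf_names, values)


def load_edge_list(path: str) -> EdgeSet:
    """Read an edge list TSV with columns (tf, gene[, score])."""
    df = pd.read_csv(path, sep="\t", header=None)
    edges = {(str(r[0]), str(r[1])) for r in df.itertuples(index=False)}
    scores = None
    if df.shape[1] >= 3:
        scores = {(str(r[0]), str(r[1])): float(r[2]) for r in df.itertuples(index=False)}
    return EdgeSet(edges=edges, scores=scores)


def save_edge_list(e: EdgeSet, path: str) -> None:
    rows = sorted(e.edges)
    df = pd.DataFrame(rows, columns=["tf", "gene"])
    if e.scores is not None:
        df["score"] = [e.scores.get(r, float("nan")) for r in rows]
    df.to_csv(path, sep="\t", header=False, index=False)
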