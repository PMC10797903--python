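"""Network and prediction scoring, context enrichment, and the NCA baseline.

Inferred networks are scored by the area under the precision-recall curve
(AUPR) against a gold-standard edge set held out of the training prior;
prediction accuracy by pooled R^2. Context-specific networks are tested for
enrichment of concordant gene annotations with a one-sided Fisher exact
test. Network component analysis (NCA) is the two-stage least-squares
baseline: solve for TF activity against the fixed prior, then for the
regulatory matrix against that activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .erv import ERVMatrix, RankedEdgeList
from .priors import EdgeSet, PriorMatrix

logger = logging.getLogger(__name__)


@dataclass
class PRResult:
    precision: np.ndarray
    recall: np.ndarray
    aupr: float
    n_positives: int
    n_candidates: int


@dataclass
class ContingencyResult:
    table: np.ndarray          # 2x2 counts
    odds_ratio: float
    p_value: float             # one-sided (enrichment of concordance)
    threshold: float
    n_ties_dropped: int = 0


@dataclass
class NCAFit:
    tfa: np.ndarray            # samples x TFs
    tfs: list[str]
    grn: np.ndarray | None = None   # TFs x genes
    genes: list[str] | None = None
    residual: float | None = None


def candidate_universe(p: PriorMatrix, exclude_prior: bool = True) -> EdgeSet:
    """All (tf, gene) pairs over the prior's axes, minus the prior's own
    edges when a holdout protocol is in effect."""
    all_pairs = {(t, g) for t in p.tfs for g in p.genes}
    if exclude_prior:
        all_pairs -= p.edge_set().edges
    return EdgeSet(edges=all_pairs)


def aupr(ranked: RankedEdgeList, gold: EdgeSet, candidate_universe: EdgeSet) -> PRResult:
    """Average-precision AUPR of a ranked edge list against held-out edges.

    Only edges in the candidate universe are scored; candidates missing from
    the ranking are appended at the bottom (score -inf) in deterministic
    (regulator, gene) order. AUPR is the sum over true-positive ranks of
    precision-at-rank times the recall increment.
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    missing_gold = gold.edges - candidate_universe.edges
    if missing_gold:
        raise ValueError(
            f"{len(missing_gold)} gold edges outside the candidate universe"
        )
    in_universe = ranked.table[
        [
            (r, g) in candidate_universe.edges
            for r, g in zip(ranked.table["regulator"], ranked.table["gene"])
        ]
    ]
    ordered = list(zip(in_universe["regulator"], in_universe["gene"]))
    unranked = sorted(candidate_universe.edges - set(ordered))
    ordered += unranked

    labels = np.array([e in gold.edges for e in ordered], dtype=bool)
    tp = np.cumsum(labels)
    ranks = np.arange(1, len(labels) + 1)
    precision = tp / ranks
    recall = tp / len(gold)
    ap = float(precision[labels].sum() / len(gold))
    return PRResult(precision=precision, recall=recall, aupr=ap,
                    n_positives=len(gold), n_candidates=len(ordered))


def r_squared(x, x_hat, per_gene: bool = False):
    """1 - SS_res / SS_tot pooled over all entries (or per gene)."""
    x = np.asarray(getattr(x, "values", x), dtype=float)
    x_hat = np.asarray(getattr(x_hat, "values", x_hat), dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    if per_gene:
        ss_res = ((x - x_hat) ** 2).sum(axis=0)
        ss_tot = ((x - x.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 1.0 - ss_res / ss_tot
        return out
    ss_tot = float(((x - x.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero total variance; R^2 undefined")
    return 1.0 - float(((x - x_hat) ** 2).sum()) / ss_tot


def fisher_context_enrichment(
    erv_a: ERVMatrix,
    erv_b: ERVMatrix,
    annotation: dict[str, str],
    floor: float = 0.01,
) -> ContingencyResult:
    """Test whether edges classified to a context target that context's genes.

    Edges with xi2 > floor in at least one context are classified to the
    context where their xi2 is higher (exact ties dropped and counted). The
    2x2 table crosses classified context with the target gene's annotation
    ("A" or "B", matching erv_a / erv_b); the one-sided Fisher exact test
    asks whether concordant classification is over-represented.
    """
    if erv_a.genes != erv_b.genes or erv_a.features != erv_b.features:
        raise ValueError("ERV matrices must share gene and feature axes")
    a, b = erv_a.values, erv_b.values
    consider = (a > floor) | (b > floor)
    gi, ki = np.nonzero(consider)
    counts = np.zeros((2, 2), dtype=int)
    ties = 0
    for g, k in zip(gi, ki):
        gene = erv_a.genes[g]
        ann = annotation.get(gene)
        if ann is None:
            continue
        if a[g, k] == b[g, k]:
            ties += 1
            continue
        cls = 0 if a[g, k] > b[g, k] else 1
        col = 0 if ann == "A" else 1
        counts[cls, col] += 1
    if counts.sum(axis=0).min() == 0 or counts.sum(axis=1).min() == 0:
        raise ValueError(f"degenerate contingency table margin: {counts.tolist()}")
    res = stats.fisher_exact(counts, alternative="greater")
    return ContingencyResult(table=counts, odds_ratio=float(res.statistic),
                             p_value=float(res.pvalue), threshold=floor,
                             n_ties_dropped=ties)


def nca_estimate_tfa(
    y, p: PriorMatrix, ridge_fallback: bool = False, ridge: float = 1e-8
) -> NCAFit:
    """Stage one of NCA: TFA = argmin || Y - phi P^T || by ordinary least
    squares against the fixed prior structure.

    Y is samples x genes on the prior's gene axis. Requires the prior to
    have full column rank; with ``ridge_fallback`` a small ridge term is
    used instead of failing.
    """
    y = np.asarray(getattr(y, "values", y), dtype=float)
    if y.shape[1] != p.n_genes:
        raise ValueError(f"Y has {y.shape[1]} genes, prior has {p.n_genes}")
    mat = p.values  # genes x TFs
    rank = np.linalg.matrix_rank(mat)
    if rank < p.n_tfs:
        if not ridge_fallback:
            raise ValueError(
                f"prior is rank-deficient ({rank} < {p.n_tfs}); enable ridge_fallback"
            )
        logger.warning("rank-deficient prior; using ridge fallback")
        gram = mat.T @ mat + ridge * np.eye(p.n_tfs)
        tfa = y @ mat @ np.linalg.inv(gram)
    else:
        # phi^T = argmin || P phi^T - Y^T ||
        tfa = np.linalg.lstsq(mat, y.T, rcond=None)[0].T
    resid = float(np.linalg.norm(y - tfa @ mat.T))
    return NCAFit(tfa=tfa, tfs=list(p.tfs), genes=list(p.genes), residual=resid)


def nca_estimate_grn(y, tfa_fit: NCAFit) -> NCAFit:
    """Stage two of NCA: GRN = argmin || Y - phi_hat Theta || by least
    squares; no support constraint (the prior is fixed only in stage one).

    TFs whose estimated activity is identically zero get a zero row with a
    warning.
    """
    y = np.asarray(getattr(y, "values", y), dtype=float)
    phi = tfa_fit.tfa
    if y.shape[0] != phi.shape[0]:
        raise ValueError("Y and TFA sample counts differ")
    zero_cols = ~phi.any(axis=0)
    grn = np.zeros((phi.shape[1], y.shape[1]))
    if zero_cols.any():
        logger.warning("%d TFs have zero activity; their GRN rows set to 0",
                       int(zero_cols.sum()))
    active = ~zero_cols
    if active.any():
        sol = np.linalg.lstsq(phi[:, active], y, rcond=None)[0]
        grn[active] = sol
    resid = float(np.linalg.norm(y - phi @ grn))
    return NCAFit(tfa=phi, tfs=list(tfa_fit.tfs), grn=grn,
                  genes=tfa_fit.genes, residual=resid)


def rank_edges_by_weight(m) -> RankedEdgeList:
    """Baseline ranking by decoder weight magnitude |theta| (for comparison
    with ERV ranking). Hierarchical models use the net path |Theta @ Pi|."""
    if m.inter is None:
        path = m.decoder.weight
        support = path != 0
    else:
        path = m.decoder.weight @ m.inter.weight
        support = np.ones_like(path, dtype=bool)
    gi, ki = np.nonzero(support)
    table = pd.DataFrame({
        "regulator": [m.tfs[k] for k in ki],
        "gene": [m.genes[g] for g in gi],
        "erv": np.abs(path[gi, ki]),
        "sign": np.sign(path[gi, ki]).astype(int),
    })
    table = table.sort_values(
        ["erv", "regulator", "gene"], ascending=[False, True, True]
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankedEdgeList(table)
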