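"""Expression normalization, accessibility masking, and cell-cycle phase calls.

Single-cell counts go through gene filtering, depth normalization and log1p.
Features are then scaled either to zero mean / unit variance (bulk-style) or
with a sparsity-preserving robust range scaler whose per-gene minimum is 0,
so zero counts stay exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STAGES = ("raw", "depth-normalized", "log1p", "feature-scaled")
PHASE_ORDER = ("G1", "S", "G2", "M", "M/G1")


@dataclass
class ExpressionMatrix:
    """Observations x genes expression with a processing-stage tag."""

    obs_names: list[str]
    gene_names: list[str]
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.obs_names), len(self.gene_names)):
            raise ValueError(
                f"shape {self.values.shape} does not match {len(self.obs_names)} "
                f"observations x {len(self.gene_names)} genes"
            )
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if self.stage == "raw" and np.any(self.values < 0):
            raise ValueError("raw expression must be non-negative")

    @property
    def n_obs(self) -> int:
        return len(self.obs_names)

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.obs_names, columns=self.gene_names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stage: str = "raw") -> "ExpressionMatrix":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy(float), stage)


@dataclass
class ScalerParams:
    """Per-gene affine scaling parameters; degenerate genes are flagged."""

    center: np.ndarray
    scale: np.ndarray
    method: str
    degenerate: np.ndarray = field(default=None)  # boolean per gene


@dataclass
class AccessibilityMask:
    """Binary observations x genes mask derived from chromatin accessibility.

    Entry (s, i) is 1 when at least one accessible peak mapped to gene i is
    present in cell s.
    """

    obs_names: list[str]
    gene_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.obs_names), len(self.gene_names)):
            raise ValueError("mask shape does not match axis labels")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("mask entries must be binary")


@dataclass
class PhaseAssignment:
    labels: pd.Series                # cell -> phase
    phase_scores: pd.DataFrame       # cells x phases mean marker score


def depth_normalize(
    e: ExpressionMatrix,
    min_cells: int = 10,
    target: float | None = None,
) -> ExpressionMatrix:
    """Filter rarely-expressed genes, scale cells to a common total, log1p.

    Genes expressed in fewer than ``min_cells`` cells are removed; cells with
    zero total counts are removed with a logged count. Each remaining cell is
    scaled so its total equals ``target`` (the dataset median total by
    default), then natural-log(value + 1) is applied.
    """
    if e.stage != "raw":
        raise ValueError(f"depth_normalize expects raw counts, got stage {e.stage!r}")
    x = e.values
    keep_genes = (x > 0).sum(axis=0) >= min_cells
    if not keep_genes.any():
        raise ValueError("no genes pass the min_cells filter")
    x = x[:, keep_genes]
    gene_names = [g for g, k in zip(e.gene_names, keep_genes) if k]

    totals = x.sum(axis=1)
    keep_cells = totals > 0
    if not keep_cells.all():
        logger.warning("removing %d cells with zero total counts", int((~keep_cells).sum()))
    x = x[keep_cells]
    totals = totals[keep_cells]
    obs_names = [o for o, k in zip(e.obs_names, keep_cells) if k]
    if x.size == 0:
        raise ValueError("no cells left after filtering")

    if target is None:
        target = float(np.median(totals))
    x = x * (target / totals)[:, None]
    return ExpressionMatrix(obs_names, gene_names, np.log1p(x), stage="log1p")


def standard_scale(e: ExpressionMatrix) -> tuple[ExpressionMatrix, ScalerParams]:
    """Per-gene z-scoring with population standard deviation (ddof 0).

    Constant genes map to all-zero and are flagged degenerate.
    """
    mu = e.values.mean(axis=0)
    sd = e.values.std(axis=0, ddof=0)
    degenerate = sd == 0
    safe = np.where(degenerate, 1.0, sd)
    z = (e.values - mu) / safe
    z[:, degenerate] = 0.0
    params = ScalerParams(center=mu, scale=safe, method="standard", degenerate=degenerate)
    return ExpressionMatrix(list(e.obs_names), list(e.gene_names), z, "feature-scaled"), params


def robust_min_scale(
    e: ExpressionMatrix, lo: float = 1.0, hi: float = 99.0
) -> tuple[ExpressionMatrix, ScalerParams]:
    """Sparsity-preserving scaling: divide each gene by its (hi - lo)
    percentile range, then shift so the per-gene minimum is 0.

    Percentiles use linear interpolation. A gene whose minimum is already 0
    keeps its zeros exactly, so single-cell sparsity is retained. Zero-range
    genes map to all-zero and are flagged degenerate.
    """
    q_lo = np.percentile(e.values, lo, axis=0)
    q_hi = np.percentile(e.values, hi, axis=0)
    rng = q_hi - q_lo
    degenerate = rng == 0
    safe = np.where(degenerate, 1.0, rng)
    scaled = e.values / safe
    mins = scaled.min(axis=0)
    out = scaled - mins
    out[:, degenerate] = 0.0
    params = ScalerParams(center=mins * safe, scale=safe, method="robust-min",
                          degenerate=degenerate)
    return ExpressionMatrix(list(e.obs_names), list(e.gene_names), out, "feature-scaled"), params


def apply_atac_mask(e: ExpressionMatrix, m: AccessibilityMask) -> ExpressionMatrix:
    """Zero expression entries where no accessible peak maps to the gene in
    that cell; elementwise, no renormalization. Idempotent."""
    if m.obs_names != e.obs_names or m.gene_names != e.gene_names:
        raise ValueError("mask axes do not match expression axes")
    return ExpressionMatrix(
        list(e.obs_names), list(e.gene_names), e.values * m.values, e.stage
    )


def assign_cell_cycle_phase(
    e: ExpressionMatrix, markers: dict[str, list[str]]
) -> PhaseAssignment:
    """Call a cell-cycle phase per cell from marker-gene groups.

    Each marker gene is standardized to mean 0 / unit variance; each cell is
    assigned the phase whose markers have the maximum mean standardized
    expression. Ties go to the earlier phase in (G1, S, G2, M, M/G1).
    """
    phases = [p for p in PHASE_ORDER if p in markers]
    phases += [p for p in markers if p not in PHASE_ORDER]
    gene_idx = {g: i for i, g in enumerate(e.gene_names)}
    missing = [p for p in phases if not any(g in gene_idx for g in markers[p])]
    if missing:
        raise ValueError(f"no marker genes present in data for phases: {missing}")

    x = e.values
    scores = {}
    for p in phases:
        cols = [gene_idx[g] for g in markers[p] if g in gene_idx]
        sub = x[:, cols]
        sd = sub.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        z = (sub - sub.mean(axis=0)) / sd
        scores[p] = z.mean(axis=1)
    score_df = pd.DataFrame(scores, index=e.obs_names)
    # idxmax takes the first column on ties, which is the fixed phase order
    labels = score_df.idxmax(axis=1)
    return PhaseAssignment(labels=labels, phase_scores=score_df)


def load_expression(path: str, stage: str = "raw") -> ExpressionMatrix:
    """Read an observations x genes matrix from a delimited file."""
    sep = "," if path.endswith(".csv") else "\t"
    return ExpressionMatrix.from_frame(pd.read_csv(path, sep=sep, index_col=0), stage)


def save_expression(e: ExpressionMatrix, path: str) -> None:
    sep = "," if path.endswith(".csv") else "\t"
    e.to_frame().to_csv(path, sep=sep)
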