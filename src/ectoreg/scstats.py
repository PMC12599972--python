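"""Single-cell statistics: QC, normalization, localization and noise.

Cells are filtered on detected-gene count, depth-normalized to a fixed total
and log1p-transformed.  Per-gene statistics use the population (n) standard
deviation throughout — the n/(n-1) distinction is negligible at single-cell
cell counts.  The coefficient of variation (CoV = sd/mean) defaults to the
depth-scaled, pre-log values: the log transform compresses variance, and the
scaled space keeps CoV invariant to a global rescaling of expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse
from scipy import stats

from .errors import ConfigError
from .formats_io import CellMatrix

__all__ = [
    "qc_filter",
    "normalize_total",
    "normalize_log",
    "ZScoreMatrix",
    "cluster_zscore",
    "gene_cov",
    "GeneSetComparison",
    "compare_gene_sets",
]


def qc_filter(m: CellMatrix, min_genes: int = 1500) -> CellMatrix:
    """Keep cells detecting at least ``min_genes`` genes (count > 0).

    The gene list is unchanged; the cutoff is inclusive, so a cell with
    exactly ``min_genes`` detected genes is retained.
    """
    mat = m.matrix
    if scipy.sparse.issparse(mat):
        detected = np.asarray((mat > 0).sum(axis=0)).ravel()
    else:
        detected = (np.asarray(mat) > 0).sum(axis=0)
    keep = detected >= min_genes
    mat_kept = mat[:, keep] if not scipy.sparse.issparse(mat) else mat.tocsc()[:, keep].tocsr()
    cell_ids = [c for c, k in zip(m.cell_ids, keep) if k]
    clusters = (
        [c for c, k in zip(m.clusters, keep) if k] if m.clusters is not None else None
    )
    return CellMatrix(mat_kept, list(m.gene_ids), cell_ids, clusters)


def normalize_total(m: CellMatrix, scale_total: float = 10_000) -> CellMatrix:
    """Scale each cell's counts to sum to ``scale_total`` (pre-log space)."""
    dense = m.dense().astype(float)
    totals = dense.sum(axis=0)
    if np.any(totals == 0):
        raise ConfigError("cell with zero total counts; run qc_filter first")
    scaled = dense * (scale_total / totals)
    return CellMatrix(scaled, list(m.gene_ids), list(m.cell_ids),
                      list(m.clusters) if m.clusters is not None else None)


def normalize_log(m: CellMatrix, scale_total: float = 10_000) -> CellMatrix:
    """Depth-normalize to ``scale_total`` per cell, then natural log(1 + x)."""
    scaled = normalize_total(m, scale_total)
    return CellMatrix(np.log1p(scaled.dense()), list(m.gene_ids),
                      list(m.cell_ids),
                      list(m.clusters) if m.clusters is not None else None)


@dataclass
class ZScoreMatrix:
    """Genes x clusters z-scores of per-cluster mean expression.

    Rows with zero spread across clusters are all-zero and listed in
    ``flat_genes``.
    """

    z: pd.DataFrame
    cluster_means: pd.DataFrame
    flat_genes: list[str]


def cluster_zscore(norm: CellMatrix) -> ZScoreMatrix:
    """Z-score each gene's per-cluster mean expression across clusters.

    ``z = (cluster mean - mean of cluster means) / population sd of cluster
    means``.  Genes whose cluster means are constant get a row of zeros and
    are flagged.
    """
    if norm.clusters is None:
        raise ConfigError("matrix carries no cluster labels")
    dense = norm.dense()
    labels = np.asarray(norm.clusters)
    cluster_names = sorted(set(norm.clusters))
    means = np.column_stack(
        [dense[:, labels == c].mean(axis=1) for c in cluster_names]
    )
    row_mean = means.mean(axis=1, keepdims=True)
    row_sd = means.std(axis=1, keepdims=True)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(row_sd > 0, (means - row_mean) / row_sd, 0.0)
    flat = [g for g, sd in zip(norm.gene_ids, row_sd.ravel()) if sd == 0]
    return ZScoreMatrix(
        pd.DataFrame(z, index=norm.gene_ids, columns=cluster_names),
        pd.DataFrame(means, index=norm.gene_ids, columns=cluster_names),
        flat,
    )


def gene_cov(
    norm: CellMatrix, cells: Sequence[str] | np.ndarray | None = None
) -> pd.DataFrame:
    """Per-gene mean, population sd and CoV over the chosen cells.

    ``cells`` may be a list of cell ids or a boolean mask; by default all
    cells are used.  Genes with zero mean have undefined CoV: they are kept
    in the table with ``defined = False`` and ``cov = NaN``.
    """
    dense = norm.dense()
    if cells is not None:
        cells = np.asarray(cells)
        if cells.dtype == bool:
            mask = cells
        else:
            wanted = set(cells.tolist())
            mask = np.array([c in wanted for c in norm.cell_ids])
        dense = dense[:, mask]
    if dense.shape[1] == 0:
        raise ConfigError("no cells selected")
    mean = dense.mean(axis=1)
    sd = dense.std(axis=1)  # population sd
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "cov": cov,
            "n_cells": dense.shape[1],
            "defined": mean > 0,
        },
        index=norm.gene_ids,
    )


@dataclass
class GeneSetComparison:
    """Two-sample rank-sum comparison of a per-gene metric between sets."""

    metric: str
    n_a: int
    n_b: int
    u_statistic: float
    p: float
    median_a: float
    median_b: float
    direction: str  # "a_lower" | "a_higher" | "tied"


def compare_gene_sets(
    gene_stats: pd.DataFrame,
    set_a: Sequence[str],
    set_b: Sequence[str],
    metric: str = "cov",
) -> GeneSetComparison:
    """Wilcoxon rank-sum test on a per-gene metric between two gene sets.

    Genes missing from the table or with undefined metric values are dropped
    first; the sets must then be disjoint and nonempty.  Small groups without
    ties use the exact null distribution; otherwise the normal approximation
    with tie and continuity corrections is used.
    """
    if metric not in gene_stats.columns:
        raise ConfigError(f"stats table lacks metric column {metric!r}")

    def _values(genes: Sequence[str], label: str) -> np.ndarray:
        present = [g for g in genes if g in gene_stats.index]
        vals = gene_stats.loc[present, metric].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ConfigError(f"gene set {label!r} is empty after filtering")
        return vals

    inter = set(set_a) & set(set_b) & set(gene_stats.index)
    if inter:
        raise ConfigError(f"gene sets overlap after filtering: {sorted(inter)[:5]}")
    a_vals = _values(set_a, "set_a")
    b_vals = _values(set_b, "set_b")
    res = stats.mannwhitneyu(
        a_vals, b_vals, alternative="two-sided", method="auto", use_continuity=True
    )
    med_a, med_b = float(np.median(a_vals)), float(np.median(b_vals))
    if med_a < med_b:
        direction = "a_lower"
    elif med_a > med_b:
        direction = "a_higher"
    else:
        direction = "tied"
    return GeneSetComparison(
        metric, a_vals.size, b_vals.size, float(res.statistic), float(res.pvalue),
        med_a, med_b, direction,
    )
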