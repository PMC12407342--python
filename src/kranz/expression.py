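"""Cell QC, library-size normalization, and per-(gene, cell type, condition) profiles.

Normalization is counts-per-10k (cp10k) with a log1p companion layer: fully
deterministic, and sufficient for the rank-based testing and mean-expression
profiles downstream.  QC follows the strict rule "UMIs > 500 and genes > 200"
(both inequalities strict); thresholds are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

logger = logging.getLogger(__name__)


class EmptyResultError(ValueError):
    """A filtering step removed every record."""


@dataclass
class NormalizedMatrix:
    """cp10k and log1p(cp10k) layers over the same genes x cells axes."""

    gene_ids: list[str]
    cell_ids: list[str]
    cp10k: sp.csr_matrix
    log1p: sp.csr_matrix

    @property
    def shape(self) -> tuple[int, int]:
        return self.cp10k.shape

    def layer(self, name: str) -> sp.csr_matrix:
        if name not in ("cp10k", "log1p"):
            raise ValueError(f"unknown layer {name!r}; choose 'cp10k' or 'log1p'")
        return getattr(self, name)


def qc_filter(
    counts: CountMatrix,
    cells: pd.DataFrame,
    min_umi: int = 500,
    min_genes: int = 200,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Retain cells with total UMIs > ``min_umi`` AND detected genes > ``min_genes``.

    Both inequalities are strict.  Genes are untouched.  Returns the filtered
    matrix and the matching annotation rows; raises :class:`EmptyResultError`
    if nothing survives.
    """
    if list(cells["cell_id"]) != list(counts.cell_ids):
        cells = cells.set_index("cell_id").loc[counts.cell_ids].reset_index()
    totals = counts.cell_totals()
    n_genes = counts.genes_per_cell()
    keep = (totals > min_umi) & (n_genes > min_genes)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise EmptyResultError(
            f"QC removed all {len(keep)} cells (min_umi={min_umi}, min_genes={min_genes})"
        )
    logger.info("QC retained %d/%d cells (removed %d)", int(keep.sum()), len(keep), n_removed)
    kept_ids = [c for c, k in zip(counts.cell_ids, keep) if k]
    filtered = CountMatrix(counts.gene_ids, kept_ids, counts.matrix[:, np.flatnonzero(keep)])
    return filtered, cells.loc[keep].reset_index(drop=True)


def normalize_cp10k(counts: CountMatrix) -> NormalizedMatrix:
    """Scale each cell to 10,000 total counts; add a log1p layer.

    cp10k[g, c] = counts[g, c] / total[c] * 1e4.  Cells with zero total are
    rejected (they should have been removed by QC).
    """
    totals = counts.cell_totals()
    if np.any(totals == 0):
        bad = counts.cell_ids[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"cell {bad!r} has zero total counts; run QC first")
    scale = sp.diags(1e4 / totals)
    cp10k = (counts.matrix @ scale).tocsr()
    log1p = cp10k.copy()
    log1p.data = np.log1p(log1p.data)
    return NormalizedMatrix(list(counts.gene_ids), list(counts.cell_ids), cp10k, log1p)


def celltype_means(
    norm: NormalizedMatrix,
    cells: pd.DataFrame,
    layer: str = "cp10k",
) -> pd.DataFrame:
    """Mean expression per (gene, cell_type, condition) group.

    Returns a long-format frame with columns gene_id, cell_type, condition,
    mean, n_cells.  Groups with zero cells are simply absent.  The arithmetic
    mean is over all cells of the group, per gene.
    """
    mat = norm.layer(layer)
    ann = cells.set_index("cell_id").loc[norm.cell_ids]
    groups = ann.groupby(["cell_type", "condition"], sort=True, observed=True).indices
    records = []
    for (ct, cond), idx in sorted(groups.items()):
        means = np.asarray(mat[:, idx].mean(axis=1)).ravel()
        records.append(pd.DataFrame({
            "gene_id": norm.gene_ids,
            "cell_type": ct,
            "condition": cond,
            "mean": means,
            "n_cells": len(idx),
        }))
    return pd.concat(records, ignore_index=True)


def profile_wide(profile: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long profile to genes x (cell_type, condition) means."""
    return profile.pivot_table(
        index="gene_id", columns=["cell_type", "condition"], values="mean"
    )
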