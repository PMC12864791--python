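"""Expression-matrix and clone-level QC gates applied before statistics.

Cell filters follow the "more than / less than" convention: a cell is kept
iff its total UMIs and expressed genes strictly exceed their floors and its
mitochondrial percentage is strictly below the ceiling (the ceiling is
platform-dependent: 30% for split-pool nuclei, 20% for droplet data).
Gene retention is inclusive: protein-coding genes with at least
``min_gene_total`` counts in the dataset.

Clone-level gates: clones observed fewer than ``min_clone_cells`` times in
any time point or condition where they appear are set aside (flagged, not
deleted), and clones are given a reference phenotype label when a
qualified majority of their reference cells share a cluster.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from .io import DataError, FilterSpec


def filter_cells(
    table: pd.DataFrame, spec: FilterSpec
) -> tuple[pd.DataFrame, dict]:
    """Apply per-cell QC gates; returns (kept table, removal report).

    Kept iff ``total_umi > min_total_umi`` and ``n_genes > min_genes`` and
    ``pct_mito < max_pct_mito``. The report partitions removed cells by the
    first failing criterion, in that order.
    """
    for col in ("total_umi", "n_genes", "pct_mito"):
        if col not in table.columns:
            raise DataError(f"filter_cells: missing column {col}")
    umi_fail = ~(table["total_umi"] > spec.min_total_umi)
    gene_fail = ~(table["n_genes"] > spec.min_genes)
    mito_fail = ~(table["pct_mito"] < spec.max_pct_mito)
    first_fail = np.where(
        umi_fail, "low_umi", np.where(gene_fail, "few_genes", np.where(mito_fail, "high_mito", ""))
    )
    kept = table.loc[first_fail == ""].reset_index(drop=True)
    report = {
        "input": len(table),
        "kept": len(kept),
        "removed": {
            "low_umi": int((first_fail == "low_umi").sum()),
            "few_genes": int((first_fail == "few_genes").sum()),
            "high_mito": int((first_fail == "high_mito").sum()),
        },
    }
    return kept, report


def filter_genes(
    matrix,
    gene_metadata: pd.DataFrame,
    spec: FilterSpec,
):
    """Keep protein-coding genes with enough total counts.

    ``matrix`` is genes x cells (sparse or dense); ``gene_metadata`` has one
    row per matrix row with a ``biotype`` column (required when
    ``protein_coding_only``). Returns (filtered matrix, filtered metadata).
    """
    if matrix.shape[0] != len(gene_metadata):
        raise DataError("filter_genes: matrix rows do not match gene metadata")
    if matrix.shape[0] == 0:
        return matrix, gene_metadata.reset_index(drop=True)
    totals = np.asarray(matrix.sum(axis=1)).ravel()
    keep = totals >= spec.min_gene_total
    if spec.protein_coding_only:
        if "biotype" not in gene_metadata.columns:
            raise DataError("filter_genes: protein_coding_only requires a biotype column")
        keep &= (gene_metadata["biotype"] == "protein_coding").to_numpy()
    if sparse.issparse(matrix):
        filtered = matrix.tocsr()[keep]
    else:
        filtered = matrix[keep]
    return filtered, gene_metadata.loc[keep].reset_index(drop=True)


def filter_sci_doublets(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Remove low-depth noise and likely doublets from split-pool nuclei.

    Kept iff ``total_umi >= sci_min_umi`` and
    ``total_umi <= mean + sci_doublet_sd * sd``, where mean and sd are
    computed once over all cells before any removal. With fewer than two
    cells the sd arm is skipped with a warning.
    """
    totals = table["total_umi"].astype(float)
    keep = totals >= spec.sci_min_umi
    if len(table) >= 2:
        mean, sd = totals.mean(), totals.std(ddof=1)
        keep &= totals <= mean + spec.sci_doublet_sd * sd
    else:
        warnings.warn("filter_sci_doublets: <2 cells, skipping the sd arm", stacklevel=2)
    return table.loc[keep].reset_index(drop=True)


def filter_small_clones(table: pd.DataFrame, spec: FilterSpec) -> pd.DataFrame:
    """Flag clones under-represented in any time point or condition.

    A clone is retained iff its cell count is at least ``min_clone_cells``
    in *every* (timepoint, condition) grouping where it appears; absence
    from a grouping is not a violation. Violating clones are set aside via
    a boolean ``clone_set_aside`` column, not deleted.
    """
    if "clone_id" not in table.columns:
        raise DataError("filter_small_clones: missing clone_id column")
    group_cols = [c for c in ("timepoint", "condition") if c in table.columns]
    out = table.copy()
    if not group_cols:
        counts = out.groupby("clone_id").size()
        bad = set(counts.index[counts < spec.min_clone_cells])
    else:
        counts = out.dropna(subset=["clone_id"]).groupby(["clone_id", *group_cols]).size()
        per_clone_min = counts.groupby(level=0).min()
        bad = set(per_clone_min.index[per_clone_min < spec.min_clone_cells])
    out["clone_set_aside"] = out["clone_id"].isin(bad)
    return out


def annotate_clone_phenotype(
    table: pd.DataFrame,
    reference_clusters: Mapping[str, str],
    majority: float = 0.75,
) -> dict[str, str]:
    """Label clones by their dominant reference-state cluster.

    ``reference_clusters`` maps reference-timepoint cells to
    ``{"iPSC", "iPSC-neuro", ...}``. A clone is labelled ``iPSC`` or
    ``iPSC-neuro`` when at least ``majority`` of its reference cells fall
    in that cluster; otherwise ``mixed``. Clones with no reference cells
    get no label (warning).
    """
    labels: dict[str, str] = {}
    clones = table.dropna(subset=["clone_id"]).groupby("clone_id")
    for clone_id, grp in clones:
        ref = [reference_clusters[c] for c in grp["cell_id"] if c in reference_clusters]
        if not ref:
            warnings.warn(f"clone {clone_id}: no reference cells, label missing", stacklevel=2)
            continue
        n = len(ref)
        frac_ipsc = ref.count("iPSC") / n
        frac_neuro = ref.count("iPSC-neuro") / n
        if frac_ipsc >= majority:
            labels[clone_id] = "iPSC"
        elif frac_neuro >= majority:
            labels[clone_id] = "iPSC-neuro"
        else:
            labels[clone_id] = "mixed"
    return labels
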