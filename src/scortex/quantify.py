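"""UMI quantification, cell-level QC and log2(TPM/10 + 1) normalization.

A molecule is counted once per distinct ``(barcode, gene, umi)`` tuple;
duplicate reads carrying an identical UMI are discarded.  QC removes cells
with fewer than 1,000 detected genes, fewer than 20,000 distinct UMIs or a
mapping ratio below 20% (thresholds inclusive for retention: the removal
rule is "fewer than"), plus an optional upper guard on raw reads against
cells that may not truly be single cells.

Normalization is log2(TPM/10 + 1), where TPM is the UMI count scaled to a
per-cell total of 10^6 with no gene-length term; dividing by 10 avoids
counting each transcript several times when cells carry far fewer than one
million molecules.
"""

from __future__ import annotations

from typing import Iterable

import anndata as ad
import numpy as np
import pandas as pd

MIN_GENES = 1_000
MIN_UMIS = 20_000
MIN_MAP_RATIO = 0.20


def demultiplex_count(reads: pd.DataFrame | Iterable[tuple[str, str, str]]) -> ad.AnnData:
    """Collapse tagged reads to distinct-UMI counts per (cell, gene).

    Accepts a DataFrame with columns ``barcode, umi, gene`` or an iterable of
    such tuples.  Cells and genes come out in lexicographic order; an empty
    stream yields a 0 x 0 matrix.
    """
    if not isinstance(reads, pd.DataFrame):
        reads = pd.DataFrame(list(reads), columns=["barcode", "umi", "gene"])
    if len(reads) == 0:
        return ad.AnnData(
            X=np.zeros((0, 0), dtype=np.int64),
            obs=pd.DataFrame(index=pd.Index([], name="cell_id")),
            var=pd.DataFrame(index=pd.Index([], name="gene")),
        )
    if reads[["barcode", "umi", "gene"]].isna().any().any():
        raise ValueError("tagged reads contain missing fields")
    distinct = reads.drop_duplicates(["barcode", "gene", "umi"])
    tab = distinct.groupby(["barcode", "gene"], sort=True).size()
    mat = tab.unstack(fill_value=0).sort_index(axis=0).sort_index(axis=1)
    return ad.AnnData(
        X=mat.to_numpy(dtype=np.int64),
        obs=pd.DataFrame(index=pd.Index(mat.index.astype(str), name="cell_id")),
        var=pd.DataFrame(index=pd.Index(mat.columns.astype(str), name="gene")),
    )


def attach_metadata(adata: ad.AnnData, meta: pd.DataFrame) -> ad.AnnData:
    """Join per-cell metadata (region, embryo, raw_reads, mapping_ratio) onto counts."""
    meta = meta.copy()
    if "cell_id" in meta.columns:
        meta = meta.set_index("cell_id")
    meta.index = meta.index.astype(str)
    for col in meta.columns:
        adata.obs[col] = meta[col].reindex(adata.obs_names)
    return adata


def qc_filter_cells(
    adata: ad.AnnData,
    min_genes: int = MIN_GENES,
    min_umis: int = MIN_UMIS,
    min_map_ratio: float = MIN_MAP_RATIO,
    max_raw_reads: float | str | None = None,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Apply the cell-level QC thresholds; returns (filtered, removal log).

    A cell is retained iff detected genes >= ``min_genes`` AND total UMIs >=
    ``min_umis`` AND mapping ratio >= ``min_map_ratio`` AND (when an upper
    guard is requested) raw reads <= ``max_raw_reads``.  Pass
    ``max_raw_reads="auto"`` to guard at the 99.5th percentile of raw reads;
    the guard is off by default because the appropriate cut-off is
    protocol-dependent.
    """
    if "mapping_ratio" not in adata.obs.columns or adata.obs["mapping_ratio"].isna().any():
        raise ValueError("QC requires a populated 'mapping_ratio' metadata column")
    X = np.asarray(adata.X)
    n_genes_det = (X > 0).sum(axis=1)
    n_umis = X.sum(axis=1)
    map_ratio = adata.obs["mapping_ratio"].to_numpy(dtype=float)

    reasons = [[] for _ in range(adata.n_obs)]
    keep = np.ones(adata.n_obs, dtype=bool)
    for mask, tag in [
        (n_genes_det < min_genes, "genes"),
        (n_umis < min_umis, "umis"),
        (map_ratio < min_map_ratio, "mapping_ratio"),
    ]:
        keep &= ~mask
        for i in np.nonzero(mask)[0]:
            reasons[i].append(tag)

    if max_raw_reads is not None:
        if "raw_reads" not in adata.obs.columns or adata.obs["raw_reads"].isna().any():
            raise ValueError("raw-read guard requires a populated 'raw_reads' metadata column")
        raw = adata.obs["raw_reads"].to_numpy(dtype=float)
        cut = float(np.quantile(raw, 0.995)) if max_raw_reads == "auto" else float(max_raw_reads)
        mask = raw > cut
        keep &= ~mask
        for i in np.nonzero(mask)[0]:
            reasons[i].append("raw_reads")

    log = pd.DataFrame(
        {
            "cell_id": np.asarray(adata.obs_names),
            "n_genes": n_genes_det,
            "n_umis": n_umis,
            "mapping_ratio": map_ratio,
            "removed": ~keep,
            "reasons": [";".join(r) for r in reasons],
        }
    )
    return adata[keep].copy(), log


def normalize(adata: ad.AnnData) -> ad.AnnData:
    """log2(TPM/10 + 1) per cell: expr = log2(count / total * 1e5 + 1)."""
    X = np.asarray(adata.X, dtype=np.float64)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("empty cell: zero total count (run QC first)")
    expr = np.log2(X / totals[:, None] * 1e5 + 1.0)
    out = ad.AnnData(X=expr, obs=adata.obs.copy(), var=adata.var.copy())
    return out
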