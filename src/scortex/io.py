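"""Readers and writers for the on-disk formats used throughout the pipeline.

Count matrices travel as a Matrix-Market bundle (``matrix.mtx`` stored
genes x cells, plus ``genes.tsv`` and ``barcodes.tsv`` name files and a
``metadata.tsv`` with per-cell annotations).  Tagged reads are a three-column
TSV ``(barcode, umi, gene)``.  Gene sets use the GMT convention
(set name, description, member genes, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

META_COLUMNS = ["region", "embryo", "raw_reads", "mapping_ratio"]


def write_counts(adata: ad.AnnData, dir_path: str | Path) -> None:
    """Write a cells x genes count AnnData as an MTX bundle (genes x cells on disk)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(np.asarray(adata.X).T if not sp.issparse(adata.X) else adata.X.T)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(dir_path / "genes.tsv", sep="\t",
                                      index=False, header=False)
    pd.Series(adata.obs_names).to_csv(dir_path / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    meta = adata.obs.reindex(columns=META_COLUMNS)
    meta.index.name = "cell_id"
    meta.to_csv(dir_path / "metadata.tsv", sep="\t")


def read_counts(dir_path: str | Path) -> ad.AnnData:
    """Read an MTX bundle written by :func:`write_counts` into cells x genes AnnData."""
    dir_path = Path(dir_path)
    mat = scipy.io.mmread(str(dir_path / "matrix.mtx"))
    if sp.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=np.int64).T  # disk is genes x cells
    genes = pd.read_csv(dir_path / "genes.tsv", sep="\t", header=None)[0].astype(str) \
        if (dir_path / "genes.tsv").stat().st_size else pd.Series([], dtype=str)
    cells = pd.read_csv(dir_path / "barcodes.tsv", sep="\t", header=None)[0].astype(str) \
        if (dir_path / "barcodes.tsv").stat().st_size else pd.Series([], dtype=str)
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    meta_path = dir_path / "metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
        meta.index = meta.index.astype(str)
        for col in META_COLUMNS:
            if col in meta.columns:
                adata.obs[col] = meta[col].reindex(adata.obs_names)
    return adata


def write_tagged_reads(reads: pd.DataFrame, path: str | Path) -> None:
    reads[["barcode", "umi", "gene"]].to_csv(path, sep="\t", index=False)


def read_tagged_reads(path: str | Path) -> pd.DataFrame:
    reads = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"barcode", "umi", "gene"} - set(reads.columns)
    if missing:
        raise ValueError(f"tagged-read file missing columns: {sorted(missing)}")
    return reads


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [genes...]}`` (description field ignored)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, _desc, genes = fields[0], fields[1], fields[2:]
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_truth(truth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth(path: str | Path):
    from .simulate import SimTruth

    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))
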