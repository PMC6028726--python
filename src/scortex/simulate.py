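"""Ground-truthed synthetic data generator.

Emulates a UMI-tagged plate-based scRNA-seq experiment: negative-binomial
gene counts with per-cell library-size factors, K planted cell clusters
distinguished by disjoint marker-gene sets, optional planted overdispersed
genes, region labels that differ only in cluster composition, low-quality
cells that the QC thresholds are expected to remove, and duplicate reads
sharing a molecule's UMI.

The count law is a gamma-Poisson mixture: for mean mu and dispersion d the
variance is mu + mu^2 * d, the standard overdispersed model for UMI counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from . import io as sio

_BASES = np.array(list("ACGT"))

#: library-size thresholds the QC stage enforces; low-quality cells are
#: planted safely below / healthy cells safely above these.
QC_MIN_UMIS = 20_000
QC_MIN_MAP_RATIO = 0.20


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    ``regions`` maps a region label to its cluster mixing proportions
    (length ``n_clusters``, summing to 1).  When omitted, a single region
    holds exactly ``cells_per_cluster`` cells of every cluster.
    """

    n_clusters: int = 5
    cells_per_cluster: int = 120
    n_genes: int = 2000
    n_markers_per_cluster: int = 25
    marker_fold: float = 8.0
    nb_dispersion: float = 0.1
    mean_library_size: int = 100_000
    regions: Mapping[str, Sequence[float]] | None = None
    frac_low_quality: float = 0.0
    umi_dup_rate: float = 0.0
    umi_length: int = 8
    n_planted_hvgs: int = 0
    hvg_bio_cv2: float = 0.5
    baseline_log_sd: float = 1.5
    library_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.cells_per_cluster < 1 or self.n_genes < 1:
            raise ValueError("n_clusters, cells_per_cluster and n_genes must be positive")
        if self.n_markers_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("marker overcommit: n_markers_per_cluster * n_clusters > n_genes")
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if not 0 <= self.frac_low_quality <= 1:
            raise ValueError("frac_low_quality must lie in [0, 1]")
        if not 0 <= self.umi_dup_rate < 1:
            raise ValueError("umi_dup_rate must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.regions is not None:
            for name, props in self.regions.items():
                props = np.asarray(props, dtype=float)
                if props.size != self.n_clusters or props.min() < 0:
                    raise ValueError(f"region {name!r}: need {self.n_clusters} nonnegative proportions")
                if abs(props.sum() - 1.0) > 1e-8:
                    raise ValueError(f"region {name!r}: mixing proportions must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.n_clusters * self.cells_per_cluster


@dataclass
class SimTruth:
    """Planted ground truth for one synthetic experiment."""

    true_label: dict[str, int]                # cell id -> cluster id
    planted_markers: dict[int, list[str]]     # cluster id -> marker genes
    planted_hvgs: list[str] = field(default_factory=list)
    low_quality_cells: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "true_label": self.true_label,
            "planted_markers": {str(k): v for k, v in self.planted_markers.items()},
            "planted_hvgs": self.planted_hvgs,
            "low_quality_cells": self.low_quality_cells,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            true_label={str(k): int(v) for k, v in d["true_label"].items()},
            planted_markers={int(k): list(v) for k, v in d["planted_markers"].items()},
            planted_hvgs=list(d.get("planted_hvgs", [])),
            low_quality_cells=list(d.get("low_quality_cells", [])),
        )


def _gamma_poisson(rng: np.random.Generator, mu: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """NB(mu, var = mu + mu^2 d) counts via a gamma-Poisson mixture."""
    lam = np.where(mu > 0, rng.gamma(np.maximum(1.0 / disp, 1e-12), mu * disp), 0.0)
    return rng.poisson(lam)


def generate_count_matrix(config: SimConfig) -> tuple[ad.AnnData, SimTruth]:
    """Draw a cells x genes UMI count matrix with planted structure.

    Returns the counts as AnnData (``obs``: region, embryo, raw_reads,
    mapping_ratio) together with the :class:`SimTruth` that downstream
    recovery tests compare against.  Identical config (including seed)
    yields a bit-identical matrix.
    """
    rng = np.random.default_rng(config.seed)
    n_cells, n_genes = config.n_cells, config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)])
    cell_ids = np.array([f"C{i:05d}" for i in range(n_cells)])

    # baseline relative abundances, shared by all clusters
    base = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=n_genes)

    # disjoint marker blocks, then optional overdispersed genes from the rest
    perm = rng.permutation(n_genes)
    markers: dict[int, list[str]] = {}
    used = 0
    for k in range(config.n_clusters):
        idx = perm[used:used + config.n_markers_per_cluster]
        markers[k] = [str(g) for g in gene_ids[idx]]
        used += config.n_markers_per_cluster
    hvg_idx = perm[used:used + config.n_planted_hvgs]
    planted_hvgs = [str(g) for g in gene_ids[hvg_idx]]

    # per-cluster expression profiles (normalized to sum to 1)
    profiles = np.tile(base, (config.n_clusters, 1))
    if config.marker_fold > 1:
        for k in range(config.n_clusters):
            idx = perm[k * config.n_markers_per_cluster:(k + 1) * config.n_markers_per_cluster]
            profiles[k, idx] *= config.marker_fold
    profiles /= profiles.sum(axis=1, keepdims=True)

    disp = np.full(n_genes, config.nb_dispersion)

    # cluster and region assignment
    if config.regions is None:
        labels = np.repeat(np.arange(config.n_clusters), config.cells_per_cluster)
        region = np.full(n_cells, "R0")
    else:
        names = list(config.regions)
        region = np.array(names)[np.arange(n_cells) % len(names)]
        labels = np.empty(n_cells, dtype=int)
        for name in names:
            mask = region == name
            labels[mask] = rng.choice(config.n_clusters, size=mask.sum(),
                                      p=np.asarray(config.regions[name], dtype=float))

    # library sizes: lognormal factors with unit mean around the target
    sd = config.library_log_sd
    lib = config.mean_library_size * rng.lognormal(mean=-sd * sd / 2.0, sigma=sd, size=n_cells)
    mapping_ratio = rng.uniform(0.35, 0.85, size=n_cells)

    n_low = int(round(config.frac_low_quality * n_cells))
    low_idx = rng.choice(n_cells, size=n_low, replace=False)
    mode = rng.integers(0, 3, size=n_low)  # 0: tiny library, 1: poor mapping, 2: both
    for i, m in zip(low_idx, mode):
        if m in (0, 2):
            lib[i] = rng.uniform(2_000, 0.75 * QC_MIN_UMIS)
        if m in (1, 2):
            mapping_ratio[i] = rng.uniform(0.02, 0.9 * QC_MIN_MAP_RATIO)

    mu = lib[:, None] * profiles[labels]
    if len(hvg_idx) and config.hvg_bio_cv2 > 0:
        # planted overdispersed genes: an extra mean-preserving per-cell
        # lognormal factor adding hvg_bio_cv2 of squared biological CV.
        # At the defaults (0.5 on top of 1/mu + 0.1) this inflates a
        # typically expressed gene's count variance roughly tenfold.
        s2 = np.log1p(config.hvg_bio_cv2)
        z = rng.normal(0.0, np.sqrt(s2), size=(n_cells, len(hvg_idx)))
        mu[:, hvg_idx] *= np.exp(z - s2 / 2.0)
    counts = _gamma_poisson(rng, mu, disp[None, :])

    raw_reads = np.round(lib * (1.0 + config.umi_dup_rate) / mapping_ratio).astype(np.int64)
    obs = pd.DataFrame(
        {
            "region": region,
            "embryo": "sim",
            "raw_reads": raw_reads,
            "mapping_ratio": mapping_ratio,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = ad.AnnData(
        X=counts.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene")),
    )
    truth = SimTruth(
        true_label={str(c): int(l) for c, l in zip(cell_ids, labels)},
        planted_markers=markers,
        planted_hvgs=planted_hvgs,
        low_quality_cells=sorted(str(c) for c in cell_ids[low_idx]),
    )
    return adata, truth


def _random_umis(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length))
    return _BASES[codes].view(f"U{length}").ravel()


def generate_tagged_reads(counts: ad.AnnData, config: SimConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """Expand a count matrix into tagged reads ``(barcode, umi, gene)``.

    Each molecule gets a random UMI of ``config.umi_length`` bases and is
    re-emitted as a duplicate read with probability ``config.umi_dup_rate``
    per copy (geometric copy count).  UMI collisions within a (cell, gene)
    can occur naturally, as on a real plate.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    X = np.asarray(counts.X)
    cell_idx, gene_idx = np.nonzero(X)
    n_mol_per_entry = X[cell_idx, gene_idx].astype(np.int64)
    n_mol = int(n_mol_per_entry.sum())
    if n_mol == 0:
        return pd.DataFrame({"barcode": [], "umi": [], "gene": []}, dtype=str)

    barcodes = np.repeat(np.asarray(counts.obs_names)[cell_idx], n_mol_per_entry)
    genes = np.repeat(np.asarray(counts.var_names)[gene_idx], n_mol_per_entry)
    umis = _random_umis(rng, n_mol, config.umi_length)

    if config.umi_dup_rate > 0:
        copies = rng.geometric(1.0 - config.umi_dup_rate, size=n_mol)
    else:
        copies = np.ones(n_mol, dtype=np.int64)
    reads = pd.DataFrame(
        {
            "barcode": np.repeat(barcodes, copies),
            "umi": np.repeat(umis, copies),
            "gene": np.repeat(genes, copies),
        }
    )
    return reads


def write_fixture(counts: ad.AnnData, truth: SimTruth, dir_path: str | Path) -> None:
    """Persist a simulated experiment (MTX bundle + metadata + truth JSON)."""
    dir_path = Path(dir_path)
    sio.write_counts(counts, dir_path)
    sio.write_truth(truth, dir_path / "truth.json")
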