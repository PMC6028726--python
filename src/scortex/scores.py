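"""Cell-cycle classification and regional scoring statistics.

Cell-cycle phase is rule-based: a cell is quiescent when both its G1/S and
G2/M scores (mean expression over the respective gene set) are below 2;
otherwise it is proliferative and assigned to the set with the higher score
(exact ties go to G1/S).

The regional suite covers: interneuron dominance from marker-positive cell
ratios, the fraction of excitatory neurons expressing an upper-layer marker
(a maturation proxy), a synapse gene-set score, per-cell gene-set enrichment
by a ranking-recovery AUC, and within- vs cross-region correlation
heterogeneity tested by the rank-sum statistic.
"""

from __future__ import annotations

import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from . import features

logger = logging.getLogger(__name__)

QUIESCENT_CUTOFF = 2.0
POS_THRESHOLD = 1.0
DOMINANCE_HI = 0.6
DOMINANCE_LO = 0.4
MIN_INTERNEURON_SUM = 15
MIN_EXCITATORY = 50
MIN_HET_CELLS = 200


def _present_genes(expr: ad.AnnData, genes: list[str], set_name: str) -> list[str]:
    present = [g for g in genes if g in expr.var_names]
    if not present:
        raise ValueError(f"no gene of set {set_name!r} present in the matrix")
    if len(present) < len(genes):
        logger.warning(
            "gene set %s: %d of %d genes absent from the matrix, dropped",
            set_name, len(genes) - len(present), len(genes),
        )
    return present


def geneset_mean_score(expr: ad.AnnData, genes: list[str],
                       set_name: str = "set") -> pd.Series:
    """Unweighted mean expression of the set's present genes, per cell."""
    present = _present_genes(expr, genes, set_name)
    X = np.asarray(expr[:, present].X, dtype=np.float64)
    return pd.Series(X.mean(axis=1), index=expr.obs_names, name=set_name)


def cellcycle_scores(expr: ad.AnnData, g1s: list[str], g2m: list[str]) -> pd.DataFrame:
    """Per-cell G1/S and G2/M scores plus the phase call."""
    out = pd.DataFrame(
        {
            "g1s_score": geneset_mean_score(expr, g1s, "G1/S"),
            "g2m_score": geneset_mean_score(expr, g2m, "G2/M"),
        }
    )
    out["phase"] = classify_phase(out["g1s_score"], out["g2m_score"])
    return out


def classify_phase(g1s, g2m) -> np.ndarray:
    """quiescent iff both scores < 2; else G2/M iff g2m > g1s, else G1/S."""
    g1s = np.asarray(g1s, dtype=float)
    g2m = np.asarray(g2m, dtype=float)
    phase = np.where(
        (g1s < QUIESCENT_CUTOFF) & (g2m < QUIESCENT_CUTOFF),
        "quiescent",
        np.where(g2m > g1s, "G2/M", "G1/S"),
    )
    return phase


def interneuron_region_ratio(
    expr: ad.AnnData,
    regions: pd.Series | np.ndarray,
    gene_a: str = "LHX6",
    gene_b: str = "CALB2",
    pos_threshold: float = POS_THRESHOLD,
) -> pd.DataFrame:
    """Per-region counts of gene_a+/gene_b+ cells and the gene_a+ ratio.

    ``expr`` should already be restricted to the inhibitory-neuron cells.
    Positivity is strict (expr > threshold); doubly positive cells count in
    both tallies.  A region with no positive cell of either kind gets a NaN
    ratio (reported downstream as insufficient).
    """
    for g in (gene_a, gene_b):
        if g not in expr.var_names:
            raise ValueError(f"gene {g!r} absent from the matrix")
    regions = pd.Series(np.asarray(regions), index=expr.obs_names, name="region")
    a_pos = np.asarray(expr[:, [gene_a]].X, dtype=float).ravel() > pos_threshold
    b_pos = np.asarray(expr[:, [gene_b]].X, dtype=float).ravel() > pos_threshold
    tab = pd.DataFrame({"region": regions.to_numpy(), "n_a": a_pos, "n_b": b_pos})
    out = tab.groupby("region", sort=True).sum()
    total = out["n_a"] + out["n_b"]
    with np.errstate(invalid="ignore"):
        out["ratio"] = np.where(total > 0, out["n_a"] / total, np.nan)
    return out


def classify_region_dominance(
    n_a: int, n_b: int, ratio: float | None = None, min_sum: int = MIN_INTERNEURON_SUM
) -> str:
    """Dominance call for one region from its positive-cell tallies."""
    if n_a + n_b < min_sum:
        return "insufficient"
    if ratio is None:
        ratio = n_a / (n_a + n_b)
    if ratio > DOMINANCE_HI:
        return "A"
    if ratio < DOMINANCE_LO:
        return "B"
    return "balanced"


def region_dominance_table(ratios: pd.DataFrame, label_a: str = "LHX6",
                           label_b: str = "CALB2",
                           min_sum: int = MIN_INTERNEURON_SUM) -> pd.DataFrame:
    """Apply :func:`classify_region_dominance` to an interneuron ratio table."""
    names = {"A": label_a, "B": label_b}
    out = ratios.copy()
    out["dominance"] = [
        names.get(classify_region_dominance(int(r.n_a), int(r.n_b), min_sum=min_sum),
                  classify_region_dominance(int(r.n_a), int(r.n_b), min_sum=min_sum))
        for r in ratios.itertuples()
    ]
    return out


def cux2_maturity_ratio(
    expr: ad.AnnData,
    regions: pd.Series | np.ndarray,
    gene: str = "CUX2",
    pos_threshold: float = POS_THRESHOLD,
    min_n: int = MIN_EXCITATORY,
) -> pd.DataFrame:
    """Fraction of excitatory neurons expressing the maturity marker, per region.

    ``expr`` should be restricted to excitatory neurons; regions with fewer
    than ``min_n`` of them are flagged excluded.
    """
    if gene not in expr.var_names:
        raise ValueError(f"gene {gene!r} absent from the matrix")
    pos = np.asarray(expr[:, [gene]].X, dtype=float).ravel() > pos_threshold
    tab = pd.DataFrame({"region": np.asarray(regions), "pos": pos})
    grp = tab.groupby("region", sort=True)["pos"].agg(n="size", n_pos="sum")
    grp["excluded"] = grp["n"] < min_n
    grp["ratio"] = np.where(grp["excluded"], np.nan, grp["n_pos"] / grp["n"])
    return grp


def synapse_maturity_score(
    expr: ad.AnnData,
    regions: pd.Series | np.ndarray,
    gene_set: list[str],
    min_n: int = MIN_EXCITATORY,
) -> pd.DataFrame:
    """Per-region mean of the per-neuron synapse gene-set score.

    ``expr`` should be restricted to neurons.  Regions with fewer than
    ``min_n`` neurons are flagged excluded.
    """
    per_cell = geneset_mean_score(expr, gene_set, "synapse")
    tab = pd.DataFrame({"region": np.asarray(regions), "score": per_cell.to_numpy()})
    grp = tab.groupby("region", sort=True)["score"].agg(n="size", mean_score="mean")
    grp["excluded"] = grp["n"] < min_n
    grp.loc[grp["excluded"], "mean_score"] = np.nan
    return grp.rename(columns={"mean_score": "score"})


def geneset_enrichment_auc(
    expr: ad.AnnData,
    gene_set: list[str],
    top_frac: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Per-cell ranking-recovery enrichment score in [0, 1].

    Genes are ranked by expression (descending; exact ties broken by a
    seeded random order per cell).  The recovery curve counts set genes
    among the top ``ceil(top_frac * G)`` ranks; the score is the area under
    this curve divided by the maximal achievable area (every set gene at
    the very top).
    """
    present = _present_genes(expr, gene_set, "enrichment")
    X = np.asarray(expr.X, dtype=np.float64)
    G = X.shape[1]
    k = int(np.ceil(top_frac * G))
    m = len(present)
    if m > k:
        logger.warning("gene set larger than the top-rank window (%d > %d)", m, k)
    in_set = np.isin(np.asarray(expr.var_names), present)
    max_area = np.minimum(np.arange(1, k + 1), m).sum()
    rng = np.random.default_rng(seed)
    scores = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        tiebreak = rng.permutation(G)
        order = np.lexsort((tiebreak, -X[i]))
        hits = in_set[order[:k]]
        scores[i] = np.cumsum(hits).sum() / max_area
    return pd.Series(scores, index=expr.obs_names, name="enrichment")


def _pairwise_corr(X: np.ndarray) -> np.ndarray:
    return np.corrcoef(X)


def regional_heterogeneity(
    expr: ad.AnnData,
    subclusters: pd.Series | np.ndarray,
    regions: pd.Series | np.ndarray,
    min_cells: int = MIN_HET_CELLS,
    mean_min: float = 1.0,
    disp_min: float = 1.0,
) -> pd.DataFrame:
    """Within- vs cross-region cell-cell correlation comparisons.

    For each sub-cluster with more than ``min_cells`` cells, highly variable
    genes are chosen on that sub-cluster (mean > 1, dispersion > 1) and
    cell-cell Pearson correlations computed over them.  For every ordered
    region pair (A, B), the off-diagonal within-A correlation distribution
    is compared to the A-vs-B cross distribution by a two-sided rank-sum
    test (exact for small tie-free samples, normal approximation with tie
    correction otherwise).
    """
    subclusters = np.asarray(subclusters)
    regions = np.asarray(regions)
    rows = []
    for sub in np.unique(subclusters):
        mask = subclusters == sub
        if mask.sum() <= min_cells:
            continue
        sub_expr = expr[mask]
        hvgs = features.select_hvg_dispersion(sub_expr, mean_min, disp_min)
        if len(hvgs) < 2:
            logger.warning("sub-cluster %s: fewer than 2 HVGs, skipped", sub)
            continue
        X = np.asarray(sub_expr[:, hvgs].X, dtype=np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = _pairwise_corr(X)  # NaN rows for cells constant over the HVGs
        regs = regions[mask]
        reg_names = np.unique(regs)
        for ra in reg_names:
            ia = np.nonzero(regs == ra)[0]
            if len(ia) < 2:
                logger.info("sub-cluster %s region %s: <2 cells, skipped", sub, ra)
                continue
            block = corr[np.ix_(ia, ia)]
            within = block[np.triu_indices(len(ia), k=1)]  # excludes the self pairs
            within = within[~np.isnan(within)]
            for rb in reg_names:
                if rb == ra:
                    continue
                ib = np.nonzero(regs == rb)[0]
                if len(ib) < 1:
                    continue
                cross = corr[np.ix_(ia, ib)].ravel()
                cross = cross[~np.isnan(cross)]
                if len(within) == 0 or len(cross) == 0:
                    continue
                stat, p = mannwhitneyu(within, cross, alternative="two-sided",
                                       method="auto")
                rows.append(
                    (sub, ra, rb, len(within), len(cross),
                     float(np.median(within)), float(np.median(cross)), float(p))
                )
    return pd.DataFrame(
        rows,
        columns=["subcluster", "region_a", "region_b", "n_within", "n_cross",
                 "median_within", "median_cross", "pvalue"],
    )
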