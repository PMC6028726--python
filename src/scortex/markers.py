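"""Marker detection by ROC "classification power".

For a gene and two cell groups, the one-vs-rest AUC is
P(X > Y) + 0.5 * P(X = Y) over all between-group pairs (the rank-sum
statistic rescaled), and the classification power rescales it onto
[0, 1] with 0 = random and 1 = perfect: power = 2 * |AUC - 0.5|.
A gene is a marker when its linear-scale fold change is >= 2 or <= 0.5
and its power is >= 0.4.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import rankdata

FC_LO = 0.5
FC_HI = 2.0
POWER_MIN = 0.4
PSEUDOCOUNT = 0.01


def auc_classification_power(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC of group ``x`` against group ``y`` and its classification power."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    auc = float(_auc_matrix(x[:, None], y[:, None])[0])
    return auc, 2.0 * abs(auc - 0.5)


def _auc_matrix(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Per-column AUC of ``xa`` (na x G) vs ``xb`` (nb x G) via midranks."""
    na = xa.shape[0]
    ranks = rankdata(np.vstack([xa, xb]), axis=0, method="average")
    r_a = ranks[:na].sum(axis=0)
    return (r_a - na * (na + 1) / 2.0) / (na * xb.shape[0])


def find_markers(
    expr: ad.AnnData,
    labels: pd.Series | np.ndarray,
    cluster,
    fc_lo: float = FC_LO,
    fc_hi: float = FC_HI,
    power_min: float = POWER_MIN,
    eps: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """One-vs-rest markers of ``cluster``.

    Fold change is computed on the de-logged linear scale,
    (mean(2^expr - 1) + eps) / (mean_rest + eps).  Passing genes are sorted
    by power descending, ties by \\|log2 fold change\\| descending, then gene id.
    """
    labels = np.asarray(labels)
    in_mask = labels == cluster
    if in_mask.sum() == 0:
        raise ValueError(f"cluster {cluster!r} not present in labels")
    if in_mask.sum() < 2 or (~in_mask).sum() < 2:
        raise ValueError("need at least 2 cells inside and outside the cluster")
    X = np.asarray(expr.X, dtype=np.float64)
    lin = np.power(2.0, X) - 1.0
    fc = (lin[in_mask].mean(axis=0) + eps) / (lin[~in_mask].mean(axis=0) + eps)
    auc = _auc_matrix(X[in_mask], X[~in_mask])
    power = 2.0 * np.abs(auc - 0.5)

    passing = ((fc >= fc_hi) | (fc <= fc_lo)) & (power >= power_min)
    out = pd.DataFrame(
        {
            "gene": np.asarray(expr.var_names)[passing],
            "cluster": cluster,
            "fold_change": fc[passing],
            "auc": auc[passing],
            "power": power[passing],
        }
    )
    out["_abs_lfc"] = np.abs(np.log2(out["fold_change"]))
    out = (
        out.sort_values(["power", "_abs_lfc", "gene"], ascending=[False, False, True])
        .drop(columns="_abs_lfc")
        .reset_index(drop=True)
    )
    return out


def find_all_markers(expr: ad.AnnData, labels, **kwargs) -> pd.DataFrame:
    """Concatenate :func:`find_markers` over every cluster present in ``labels``."""
    labels = np.asarray(labels)
    frames = [find_markers(expr, labels, c, **kwargs) for c in np.unique(labels)]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["gene", "cluster", "fold_change", "auc", "power"])


def count_degs(expr: ad.AnnData, labels, group_a, **kwargs) -> int:
    """Number of genes separating two groups (either direction; used as the
    split-acceptance evidence in the recursive clustering)."""
    return len(find_markers(expr, labels, group_a, **kwargs))
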