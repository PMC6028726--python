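"""Highly variable gene (HVG) selection.

Two schemes are provided, both computed on log2(TPM/10 + 1) expression:

* ``select_hvg_cv2`` — fit the squared coefficient of variation
  CV^2 = sigma^2 / mu^2 against 1/mu by least squares (the classic
  inverse-in-mean trend of technical noise) and keep genes whose CV^2
  exceeds the fitted curve by more than one residual standard error.
* ``select_hvg_dispersion`` — keep genes with mean expression > 1 and
  dispersion (variance / mean) > 1, both strict.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd


def expression_prefilter(expr: ad.AnnData, min_expr: float = 1.0,
                         min_cells: int = 3) -> np.ndarray:
    """Boolean mask of genes with expression > ``min_expr`` in >= ``min_cells`` cells."""
    X = np.asarray(expr.X)
    return (X > min_expr).sum(axis=0) >= min_cells


def select_hvg_cv2(expr: ad.AnnData, prefilter: bool = False) -> tuple[list[str], pd.DataFrame]:
    """CV^2-vs-mean HVG selection.

    ``expr`` holds log2(TPM/10 + 1) values; the moments are taken on the
    de-logged linear scale (2^expr - 1), where the inverse-in-mean trend of
    sampling noise (CV^2 ~ 1/mu) actually holds and the fit is meaningful.
    Genes with zero mean are excluded from the fit and never selected.
    Returns the selected gene list and a per-gene stats table
    (mean, variance, cv2, fitted_cv2, selected).
    """
    X = np.asarray(expr.X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    genes = np.asarray(expr.var_names)
    if prefilter:
        mask = expression_prefilter(expr)
        X = X[:, mask]
        genes = genes[mask]
    X = np.power(2.0, X) - 1.0

    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    var[var <= mu**2 * 1e-24] = 0.0  # de-logging jitter on constant genes
    with np.errstate(divide="ignore", invalid="ignore"):
        cv2 = np.where(mu > 0, var / mu**2, np.nan)

    pos = mu > 0
    if pos.sum() < 10:
        raise ValueError("need at least 10 genes with positive mean expression")
    coef, fit_pos, resid_se = fit_inverse_cv2(mu[pos], cv2[pos])
    fitted = np.full_like(cv2, np.nan)
    fitted[pos] = fit_pos

    selected = np.zeros(len(genes), dtype=bool)
    selected[pos] = (var[pos] > 0) & (cv2[pos] > fitted[pos] + resid_se)

    stats = pd.DataFrame(
        {
            "mean": mu,
            "variance": var,
            "cv2": cv2,
            "fitted_cv2": fitted,
            "selected": selected,
        },
        index=pd.Index(genes, name="gene"),
    )
    stats.attrs["coef"] = (float(coef[0]), float(coef[1]))
    stats.attrs["resid_se"] = resid_se
    return [str(g) for g in genes[selected]], stats


def fit_inverse_cv2(mu: np.ndarray, cv2: np.ndarray) -> tuple[tuple[float, float], np.ndarray, float]:
    """Least-squares fit of cv2 = a0 + a1 / mu.

    Returns ``((a0, a1), fitted, residual_se)`` with the residual standard
    error computed on n - 2 degrees of freedom.
    """
    mu = np.asarray(mu, dtype=float)
    cv2 = np.asarray(cv2, dtype=float)
    inv_mu = 1.0 / mu
    if np.allclose(inv_mu, inv_mu[0]):
        raise ValueError("degenerate fit: all gene means equal")
    A = np.column_stack([np.ones(mu.size), inv_mu])
    coef, *_ = np.linalg.lstsq(A, cv2, rcond=None)
    fitted = A @ coef
    dof = max(mu.size - 2, 1)
    resid_se = float(np.sqrt(((cv2 - fitted) ** 2).sum() / dof))
    return (float(coef[0]), float(coef[1])), fitted, resid_se


def select_hvg_dispersion(expr: ad.AnnData, mean_min: float = 1.0,
                          disp_min: float = 1.0) -> list[str]:
    """Genes with mean expression > ``mean_min`` and variance/mean > ``disp_min``."""
    X = np.asarray(expr.X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mu > 0, var / mu, 0.0)
    keep = (mu > mean_min) & (disp > disp_min)
    return [str(g) for g in np.asarray(expr.var_names)[keep]]
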