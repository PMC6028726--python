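"""Shared helpers for the test suite (brute-force oracles, toy builders)."""

import anndata as ad
import numpy as np
import pandas as pd


def toy_counts(values, cells=None, genes=None, **obs_cols):
    values = np.asarray(values, dtype=np.int64)
    n, g = values.shape
    obs = pd.DataFrame(index=pd.Index(cells or [f"c{i}" for i in range(n)],
                                      name="cell_id"))
    for k, v in obs_cols.items():
        obs[k] = v
    return ad.AnnData(
        X=values,
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes or [f"g{j}" for j in range(g)],
                                        name="gene")),
    )


def brute_force_auc(x, y):
    """All-pairs P(X > Y) + 0.5 P(X = Y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    wins = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                wins += 1.0
            elif xi == yj:
                wins += 0.5
    return wins / (len(x) * len(y))


def brute_force_dedup(reads):
    """Distinct-(barcode, gene, umi) tuples grouped by (barcode, gene)."""
    seen = set()
    counts = {}
    for bc, umi, gene in zip(reads["barcode"], reads["umi"], reads["gene"]):
        key = (bc, gene, umi)
        if key in seen:
            continue
        seen.add(key)
        counts[(bc, gene)] = counts.get((bc, gene), 0) + 1
    return counts
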