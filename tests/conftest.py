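import anndata as ad
import numpy as np
import pandas as pd
import pytest

from scortex import SimConfig, generate_count_matrix, normalize


@pytest.fixture(scope="session")
def k3_sim():
    """Three well-separated planted clusters, 100 cells each."""
    cfg = SimConfig(n_clusters=3, cells_per_cluster=100, n_genes=500,
                    n_markers_per_cluster=15, marker_fold=8, seed=11)
    counts, truth = generate_count_matrix(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def k3_expr(k3_sim):
    _, counts, _ = k3_sim
    return normalize(counts)


def make_expr(values, genes=None, cells=None):
    """Small dense expression AnnData from a cells x genes array."""
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return ad.AnnData(
        X=values,
        obs=pd.DataFrame(index=pd.Index(cells or [f"c{i}" for i in range(n)], name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes or [f"g{j}" for j in range(g)], name="gene")),
    )
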