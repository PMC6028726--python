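"""End-to-end pipeline: counts -> QC -> normalization -> recursive clustering
-> markers -> regional report, with deterministic text outputs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as clu
from . import markers as mk
from . import quantify, scores, simulate

FLOAT_FMT = "%.6g"


def run_pipeline(
    config: simulate.SimConfig,
    outdir: str | Path,
    reps: int = 10,
    n_trees: int = 50,
    min_cluster_size: int = clu.MIN_CLUSTER_SIZE,
    min_deg: int = clu.MIN_DEG,
    gene_sets: dict[str, list[str]] | None = None,
    qc_kwargs: dict | None = None,
) -> dict[str, Path]:
    """Simulate one experiment and run every stage, writing text reports.

    Identical ``config`` (including its seed) produces byte-identical
    output files.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts, truth = simulate.generate_count_matrix(config)
    filtered, qc_log = quantify.qc_filter_cells(counts, **(qc_kwargs or {}))
    expr = quantify.normalize(filtered)

    tree = clu.recursive_cluster(
        expr,
        min_cluster_size=min_cluster_size,
        min_deg=min_deg,
        reps=reps,
        n_trees=n_trees,
        seed=config.seed,
    )
    assign = tree.assignments()

    kept = assign.loc[~assign["abandoned"], "cell_id"].tolist()
    labels = assign.set_index("cell_id").loc[kept, "leaf_label"].to_numpy()
    if len(np.unique(labels)) >= 2:
        marker_tab = mk.find_all_markers(expr[kept], labels)
    else:
        marker_tab = pd.DataFrame(columns=["gene", "cluster", "fold_change", "auc", "power"])

    report: dict = {"n_cells_input": int(counts.n_obs),
                    "n_cells_qc": int(filtered.n_obs),
                    "n_leaves": int(len(tree.leaves())),
                    "n_abandoned": int(assign["abandoned"].sum())}
    regions = expr.obs.loc[kept, "region"]
    comp = (
        pd.crosstab(regions, labels).sort_index(axis=0).sort_index(axis=1)
    )
    report["region_composition"] = {
        str(r): {str(c): int(v) for c, v in row.items()} for r, row in comp.iterrows()
    }
    if regions.nunique() > 1:
        het = scores.regional_heterogeneity(expr[kept], labels, regions.to_numpy())
        report["heterogeneity"] = [
            {k: (round(v, 10) if isinstance(v, float) else (int(v) if isinstance(v, (np.integer,)) else v))
             for k, v in rec.items()}
            for rec in het.to_dict(orient="records")
        ]
    if gene_sets:
        for name, genes in gene_sets.items():
            s = scores.geneset_mean_score(expr[kept], genes, name)
            report[f"set_score_mean:{name}"] = round(float(s.mean()), 10)

    paths = {
        "qc_log": outdir / "qc_log.tsv",
        "clusters": outdir / "clusters.tsv",
        "tree": outdir / "tree.json",
        "markers": outdir / "markers.tsv",
        "report": outdir / "region_report.json",
    }
    qc_log.to_csv(paths["qc_log"], sep="\t", index=False, float_format=FLOAT_FMT)
    assign.to_csv(paths["clusters"], sep="\t", index=False, float_format=FLOAT_FMT)
    with open(paths["tree"], "w") as fh:
        json.dump(tree.to_dict(), fh, indent=1, sort_keys=True)
    marker_tab.to_csv(paths["markers"], sep="\t", index=False, float_format=FLOAT_FMT)
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return paths
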