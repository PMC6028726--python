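"""Recursive binary partitioning with random-forest vote refinement.

Each round works on one group of cells: (1) select highly variable genes on
that group (CV^2-vs-mean fit), (2) cut an average-linkage hierarchy on the
1 - Pearson correlation distance into two subgroups, (3) run a 10-fold
random-forest cross-validation to pick discriminating feature genes and
internal vote probabilities, (4) retrain on the confidently assigned cells
(vote probability > 0.6) and re-predict the rest, (5) finalize vote
probabilities over ``reps`` repeats of 10-fold cross-validation and abandon
cells voted below 0.55, (6) accept the split only when both refined
subgroups are large enough and separated by enough differentially expressed
genes, then recurse into each side.

Everything is seeded: identical input and seed give an identical tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from . import features, markers

VOTE_TRAIN = 0.6
VOTE_ABANDON = 0.55
MIN_CLUSTER_SIZE = 20
MIN_DEG = 10
FEATURE_CAP = 200


class UnstableSplitError(RuntimeError):
    """Raised when a class has no confidently voted training cells."""


class NoSplitError(RuntimeError):
    """Raised when a group is too small to bisect."""


@dataclass
class SplitResult:
    """Outcome of one refined bisection."""

    left: list[str]
    right: list[str]
    feature_genes: list[str]
    vote_prob: pd.Series          # final vote probability per (non-)abandoned cell
    abandoned: list[str]
    n_deg: int = 0

    def to_dict(self) -> dict:
        return {
            "left": self.left,
            "right": self.right,
            "feature_genes": self.feature_genes,
            "abandoned": self.abandoned,
            "n_deg": self.n_deg,
        }


@dataclass
class ClusterNode:
    cells: list[str]
    stop_reason: str = ""          # "" for internal nodes
    split: SplitResult | None = None
    children: list["ClusterNode"] = field(default_factory=list)
    leaf_label: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_dict(self) -> dict:
        d: dict = {"n_cells": len(self.cells)}
        if self.is_leaf:
            d["leaf_label"] = self.leaf_label
            d["stop_reason"] = self.stop_reason
            d["cells"] = self.cells
        else:
            d["split"] = self.split.to_dict() if self.split else None
            d["children"] = [c.to_dict() for c in self.children]
        return d


@dataclass
class ClusterTree:
    root: ClusterNode

    def leaves(self) -> list[ClusterNode]:
        out: list[ClusterNode] = []

        def walk(node: ClusterNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return out

    def abandoned(self) -> list[str]:
        out: list[str] = []

        def walk(node: ClusterNode) -> None:
            if node.split is not None:
                out.extend(node.split.abandoned)
            for c in node.children:
                walk(c)

        walk(self.root)
        return out

    def assignments(self) -> pd.DataFrame:
        """Per-cell table: leaf label (-1 when abandoned), vote prob, abandoned flag."""
        rows = []
        votes: dict[str, float] = {}

        def walk(node: ClusterNode) -> None:
            if node.split is not None:
                for cell, v in node.split.vote_prob.items():
                    votes[cell] = float(v)
            for c in node.children:
                walk(c)

        walk(self.root)
        for leaf in self.leaves():
            for cell in leaf.cells:
                rows.append((cell, leaf.leaf_label, votes.get(cell, 1.0), False))
        for cell in self.abandoned():
            rows.append((cell, -1, votes.get(cell, np.nan), True))
        df = pd.DataFrame(rows, columns=["cell_id", "leaf_label", "vote_prob", "abandoned"])
        return df.sort_values("cell_id").reset_index(drop=True)

    def to_dict(self) -> dict:
        return self.root.to_dict()


def bisect_cells(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Top split of an average-linkage hierarchy on 1 - Pearson distance.

    ``X`` is cells x features.  Returns boolean masks of the two groups.
    """
    n = X.shape[0]
    if n < 2:
        raise NoSplitError("need at least 2 cells to bisect")
    if n == 2:
        return np.array([True, False]), np.array([False, True])
    dist = pdist(X, metric="correlation")
    dist = np.nan_to_num(dist, nan=1.0)  # constant cells have undefined correlation
    groups = fcluster(linkage(dist, method="average"), t=2, criterion="maxclust")
    return groups == 1, groups == 2


def _oof_votes(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    rs: int,
    collect_importance: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Out-of-fold vote fraction for each cell's current label, one 10-fold pass."""
    n_splits = min(10, int(np.bincount(y).min()))
    if n_splits < 2:
        raise UnstableSplitError("a class has fewer than 2 cells")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=rs)
    votes = np.empty(len(y))
    importances = np.zeros(X.shape[1]) if collect_importance else None
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            class_weight="balanced",
            random_state=rs + fold,
            n_jobs=1,
        ).fit(X[tr], y[tr])
        proba = rf.predict_proba(X[te])
        cols = {c: j for j, c in enumerate(rf.classes_)}
        votes[te] = proba[np.arange(len(te)), [cols[c] for c in y[te]]]
        if collect_importance:
            importances += rf.feature_importances_
    if collect_importance:
        importances /= n_splits
    return votes, importances


def rf_refine(
    expr_sub: np.ndarray,
    gene_names: np.ndarray,
    cell_names: np.ndarray,
    initial: np.ndarray,
    seed: int,
    reps: int = 100,
    n_trees: int = 100,
    vote_train: float = VOTE_TRAIN,
    vote_abandon: float = VOTE_ABANDON,
    feature_cap: int = FEATURE_CAP,
) -> SplitResult:
    """Refine a two-group labelling of ``expr_sub`` (cells x genes).

    Implements steps (3)-(5): 10-fold RF feature selection, confident-cell
    retraining, and ``reps`` x 10-fold vote-probability finalization.
    """
    y = np.asarray(initial, dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("initial labels must contain exactly two groups")
    rs = int(np.random.SeedSequence(seed).generate_state(1)[0] % 2**31)

    # (3) feature selection + internal vote probabilities from one 10-fold pass
    votes0, imp = _oof_votes(expr_sub, y, n_trees, rs, collect_importance=True)
    thresh = imp.mean() + imp.std()
    feat = np.nonzero(imp > thresh)[0]
    if len(feat) == 0:
        feat = np.argsort(imp)[::-1][:10]
    elif len(feat) > feature_cap:
        feat = feat[np.argsort(imp[feat])[::-1][:feature_cap]]
    feat = np.sort(feat)
    Xf = expr_sub[:, feat]

    # (4) train on confidently voted cells, predict the rest
    train = votes0 > vote_train
    refined = y.copy()
    if (~train).any():
        for cls in (0, 1):
            if not np.any(train & (y == cls)):
                raise UnstableSplitError(f"no confident training cells for class {cls}")
        clf = RandomForestClassifier(
            n_estimators=n_trees, class_weight="balanced",
            random_state=rs + 101, n_jobs=1,
        ).fit(Xf[train], y[train])
        refined[~train] = clf.predict(Xf[~train])
    if len(np.unique(refined)) != 2 or np.bincount(refined).min() < 2:
        raise UnstableSplitError("refinement collapsed one class")

    # (5) vote probabilities over `reps` repeats of 10-fold CV
    vote_sum = np.zeros(len(refined))
    for rep in range(reps):
        v, _ = _oof_votes(Xf, refined, n_trees, rs + 1000 + 17 * rep)
        vote_sum += v
    vote_prob = vote_sum / reps

    keep = vote_prob >= vote_abandon
    cells = np.asarray(cell_names)
    left = [str(c) for c in cells[keep & (refined == 0)]]
    right = [str(c) for c in cells[keep & (refined == 1)]]
    return SplitResult(
        left=left,
        right=right,
        feature_genes=[str(g) for g in np.asarray(gene_names)[feat]],
        vote_prob=pd.Series(vote_prob, index=cells),
        abandoned=[str(c) for c in cells[~keep]],
    )


def _attempt_split(
    expr: ad.AnnData,
    cells: list[str],
    seed: int,
    reps: int,
    n_trees: int,
    min_cluster_size: int,
    min_deg: int,
) -> tuple[SplitResult | None, str]:
    """One round on one group; returns (split, "") or (None, stop_reason)."""
    if len(cells) < 2 * min_cluster_size:
        return None, "min-size"
    sub = expr[cells]
    try:
        hvgs, _ = features.select_hvg_cv2(sub, prefilter=True)
    except ValueError:
        return None, "degenerate-features"
    if len(hvgs) < 2:
        return None, "degenerate-features"
    X = np.asarray(sub[:, hvgs].X, dtype=np.float64)
    left_mask, right_mask = bisect_cells(X)
    if min(left_mask.sum(), right_mask.sum()) < min_cluster_size:
        return None, "rejected: min-size"
    try:
        split = rf_refine(
            X,
            np.asarray(hvgs),
            np.asarray(sub.obs_names),
            right_mask.astype(int),
            seed=seed,
            reps=reps,
            n_trees=n_trees,
        )
    except UnstableSplitError:
        return None, "rejected: unstable-split"
    if min(len(split.left), len(split.right)) < min_cluster_size:
        return None, "rejected: min-size"
    kept = split.left + split.right
    lab = pd.Series(0, index=kept)
    lab[split.right] = 1
    split.n_deg = markers.count_degs(expr[kept], lab.to_numpy(), 0)
    if split.n_deg < min_deg:
        return None, "rejected: too-few-DEGs"
    return split, ""


def recursive_cluster(
    expr: ad.AnnData,
    cells: list[str] | None = None,
    min_cluster_size: int = MIN_CLUSTER_SIZE,
    min_deg: int = MIN_DEG,
    reps: int = 100,
    n_trees: int = 100,
    seed: int = 0,
) -> ClusterTree:
    """Apply bisection + refinement recursively; leaves are the final sub-clusters.

    A split is accepted iff both refined children have at least
    ``min_cluster_size`` cells and at least ``min_deg`` genes differ between
    them by the fold-change/power criterion; otherwise the node is a leaf.
    Leaves are labelled depth-first starting at 1.
    """
    if cells is None:
        cells = [str(c) for c in expr.obs_names]
    root_seq = np.random.SeedSequence(seed)

    def build(node_cells: list[str], seq: np.random.SeedSequence) -> ClusterNode:
        node_seed = int(seq.generate_state(1)[0] % 2**31)
        split, reason = _attempt_split(
            expr, node_cells, node_seed, reps, n_trees, min_cluster_size, min_deg
        )
        if split is None:
            return ClusterNode(cells=node_cells, stop_reason=reason)
        left_seq, right_seq = seq.spawn(2)
        node = ClusterNode(cells=node_cells, split=split)
        node.children = [build(split.left, left_seq), build(split.right, right_seq)]
        return node

    tree = ClusterTree(root=build(list(cells), root_seq))
    for i, leaf in enumerate(tree.leaves(), start=1):
        leaf.leaf_label = i
    return tree
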