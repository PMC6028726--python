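"""Cell-cycle rules, regional ratios, enrichment AUC and heterogeneity."""

import numpy as np
import pandas as pd
import pytest

from scortex import SimConfig, generate_count_matrix, normalize
from scortex.scores import (
    cellcycle_scores,
    classify_phase,
    classify_region_dominance,
    cux2_maturity_ratio,
    geneset_enrichment_auc,
    geneset_mean_score,
    interneuron_region_ratio,
    region_dominance_table,
    regional_heterogeneity,
    synapse_maturity_score,
)
from conftest import make_expr

# hand-written truth table on the 5 x 5 score grid
GRID = {0.0: {}, 1.9: {}, 2.0: {}, 2.1: {}, 3.0: {}}
for _g1s, _row in [
    (0.0, ["quiescent", "quiescent", "G2/M", "G2/M", "G2/M"]),
    (1.9, ["quiescent", "quiescent", "G2/M", "G2/M", "G2/M"]),
    (2.0, ["G1/S", "G1/S", "G1/S", "G2/M", "G2/M"]),
    (2.1, ["G1/S", "G1/S", "G1/S", "G1/S", "G2/M"]),
    (3.0, ["G1/S", "G1/S", "G1/S", "G1/S", "G1/S"]),
]:
    GRID[_g1s] = dict(zip([0.0, 1.9, 2.0, 2.1, 3.0], _row))


class TestCellCycle:
    def test_phase_grid_truth_table(self):
        for g1s, row in GRID.items():
            for g2m, expected in row.items():
                assert classify_phase([g1s], [g2m])[0] == expected, (g1s, g2m)

    def test_scores_are_set_means(self):
        expr = make_expr([[3.0, 1.0, 7.0], [0.0, 0.0, 5.0]])
        out = cellcycle_scores(expr, ["g0", "g1"], ["g2"])
        assert out["g1s_score"].tolist() == [2.0, 0.0]
        assert out["g2m_score"].tolist() == [7.0, 5.0]
        assert out["phase"].tolist() == ["G2/M", "G2/M"]

    def test_missing_set_gene_dropped_with_warning(self, caplog):
        expr = make_expr([[3.0, 1.0]])
        with caplog.at_level("WARNING"):
            s = geneset_mean_score(expr, ["g0", "absent"], "S")
        assert s.iloc[0] == 3.0
        assert "absent" in caplog.text or "dropped" in caplog.text

    def test_no_set_gene_present_errors(self):
        with pytest.raises(ValueError, match="no gene"):
            geneset_mean_score(make_expr([[1.0]]), ["nope"], "S")


class TestInterneuronRatio:
    def _expr(self, lhx6, calb2, regions):
        X = np.column_stack([lhx6, calb2])
        e = make_expr(X, genes=["LHX6", "CALB2"])
        return e, np.asarray(regions)

    def test_positivity_strict(self):
        e, r = self._expr([1.0, 1.01], [0.0, 0.0], ["A", "A"])
        out = interneuron_region_ratio(e, r)
        assert out.loc["A", "n_a"] == 1  # expr exactly 1.0 is not positive

    def test_ratio_and_double_positive(self):
        lhx6 = [2.0] * 10 + [0.0] * 5 + [2.0]
        calb2 = [0.0] * 10 + [2.0] * 5 + [2.0]
        e, r = self._expr(lhx6, calb2, ["A"] * 16)
        out = interneuron_region_ratio(e, r)
        assert out.loc["A", "n_a"] == 11 and out.loc["A", "n_b"] == 6
        assert out.loc["A", "ratio"] == pytest.approx(11 / 17)

    def test_no_positive_cells_insufficient(self):
        e, r = self._expr([0.0, 0.5], [0.0, 0.9], ["A", "A"])
        out = interneuron_region_ratio(e, r)
        assert np.isnan(out.loc["A", "ratio"])
        tab = region_dominance_table(out)
        assert tab.loc["A", "dominance"] == "insufficient"


class TestDominance:
    TOY = [
        # (n_a, n_b) -> expected label
        ((10, 4), "insufficient"),   # sum 14 < 15
        ((12, 8), "balanced"),       # ratio exactly 0.60
        ((61, 39), "LHX6"),          # ratio 0.61
        ((39, 61), "CALB2"),         # ratio 0.39
        ((8, 12), "balanced"),       # ratio exactly 0.40
        ((20, 0), "LHX6"),           # ratio 1.0
    ]

    @pytest.mark.parametrize("tallies, expected", TOY)
    def test_toy_table(self, tallies, expected):
        n_a, n_b = tallies
        got = classify_region_dominance(n_a, n_b)
        assert {"A": "LHX6", "B": "CALB2"}.get(got, got) == expected

    def test_labels_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_a, n_b = rng.integers(0, 60, 2)
            lab = classify_region_dominance(int(n_a), int(n_b))
            assert lab in {"A", "B", "balanced", "insufficient"}


class TestMaturity:
    def test_cux2_ratio_and_exclusion(self):
        vals = np.r_[np.full(15, 2.0), np.zeros(45), np.full(49, 2.0)]
        expr = make_expr(vals[:, None], genes=["CUX2"])
        regions = np.array(["big"] * 60 + ["small"] * 49)
        out = cux2_maturity_ratio(expr, regions)
        assert out.loc["big", "ratio"] == pytest.approx(0.25)
        assert bool(out.loc["small", "excluded"]) is True
        assert np.isnan(out.loc["small", "ratio"])

    def test_all_zero_ratio_zero(self):
        expr = make_expr(np.zeros((60, 1)), genes=["CUX2"])
        out = cux2_maturity_ratio(expr, np.array(["A"] * 60))
        assert out.loc["A", "ratio"] == 0.0

    def test_synapse_score_mean_of_means(self):
        X = np.array([[1.0, 1.0], [3.0, 3.0]] * 30)
        expr = make_expr(X, genes=["s1", "s2"])
        out = synapse_maturity_score(expr, np.array(["A"] * 60), ["s1", "s2"])
        assert out.loc["A", "score"] == pytest.approx(2.0)

    def test_synapse_small_region_excluded_and_empty_set_errors(self):
        X = np.ones((10, 2))
        expr = make_expr(X, genes=["s1", "s2"])
        out = synapse_maturity_score(expr, np.array(["A"] * 10), ["s1"])
        assert bool(out.loc["A", "excluded"]) is True
        with pytest.raises(ValueError, match="no gene"):
            synapse_maturity_score(expr, np.array(["A"] * 10), ["nope"])


class TestEnrichmentAUC:
    def test_set_at_top_scores_one(self):
        X = np.array([np.r_[np.full(2, 9.0), np.linspace(5, 1, 38)]])
        expr = make_expr(X)
        s = geneset_enrichment_auc(expr, ["g0", "g1"], top_frac=0.25, seed=0)
        assert s.iloc[0] == pytest.approx(1.0)

    def test_set_at_bottom_scores_near_zero(self):
        X = np.array([np.r_[np.zeros(2), np.linspace(9, 1, 98)]])
        expr = make_expr(X, genes=[f"g{j}" for j in range(100)])
        s = geneset_enrichment_auc(expr, ["g0", "g1"], top_frac=0.05, seed=0)
        assert s.iloc[0] == 0.0

    def test_hand_enumerated_recovery_curve(self):
        # 10 genes, set {g0, g2}; ordering g0 > g1 > g2 > rest; window = 5
        X = np.array([[10.0, 9.0, 8.0, 7, 6, 5, 4, 3, 2, 1]])
        expr = make_expr(X)
        s = geneset_enrichment_auc(expr, ["g0", "g2"], top_frac=0.5, seed=0)
        # recovery curve over ranks 1..5: 1,1,2,2,2 (area 8); max 1,2,2,2,2 (area 9)
        assert s.iloc[0] == pytest.approx(8 / 9)

    def test_monotone_in_set_gene_expression(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 5, size=(1, 50))
        gene_set = ["g3", "g17"]
        base = geneset_enrichment_auc(make_expr(X.copy()), gene_set, seed=1).iloc[0]
        for bump in (0.5, 2.0, 5.0):
            X2 = X.copy()
            X2[0, 3] += bump
            s = geneset_enrichment_auc(make_expr(X2), gene_set, seed=1).iloc[0]
            assert s >= base - 1e-12

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, size=(5, 40)).astype(float)  # heavy ties
        a = geneset_enrichment_auc(make_expr(X), ["g0", "g1", "g2"], seed=7)
        b = geneset_enrichment_auc(make_expr(X), ["g0", "g1", "g2"], seed=7)
        pd.testing.assert_series_equal(a, b)


class TestHeterogeneity:
    def _null_expr(self, seed, n_cells=60):
        cfg = SimConfig(n_clusters=1, cells_per_cluster=n_cells, n_genes=300,
                        n_markers_per_cluster=0, mean_library_size=30_000,
                        n_planted_hvgs=80, hvg_bio_cv2=3.0, seed=seed)
        counts, _ = generate_count_matrix(cfg)
        return normalize(counts)

    def test_self_pairs_excluded(self):
        expr = self._null_expr(1)
        regions = np.array(["A"] * 30 + ["B"] * 30)
        out = regional_heterogeneity(expr, np.zeros(60, int), regions, min_cells=50)
        row = out[(out.region_a == "A") & (out.region_b == "B")].iloc[0]
        assert row["n_within"] == 30 * 29 // 2
        assert row["n_cross"] == 30 * 30
        assert row["median_within"] < 1.0

    def test_invariant_to_cell_order(self):
        expr = self._null_expr(2)
        regions = np.array(["A", "B"] * 30)
        out1 = regional_heterogeneity(expr, np.zeros(60, int), regions, min_cells=50)
        rng = np.random.default_rng(0)
        perm = rng.permutation(60)
        out2 = regional_heterogeneity(expr[perm].copy(), np.zeros(60, int),
                                      regions[perm], min_cells=50)
        m1 = out1.set_index(["region_a", "region_b"])["pvalue"]
        m2 = out2.set_index(["region_a", "region_b"])["pvalue"]
        assert np.allclose(m1, m2.reindex(m1.index))

    def test_noisier_region_less_correlated(self):
        """Adding per-cell noise to one region lowers its within-region
        correlation, and the rank-sum test notices."""
        lowered = 0
        for seed in range(3):
            expr = self._null_expr(seed + 10)
            X = np.asarray(expr.X)
            rng = np.random.default_rng(seed)
            X[30:] = X[30:] + rng.normal(0, 2.0, size=X[30:].shape)
            noisy = make_expr(np.clip(X, 0, None), genes=list(expr.var_names))
            regions = np.array(["clean"] * 30 + ["noisy"] * 30)
            out = regional_heterogeneity(noisy, np.zeros(60, int), regions,
                                         min_cells=50)
            out = out.set_index(["region_a", "region_b"])
            if (out.loc[("noisy", "clean"), "median_within"]
                    < out.loc[("clean", "noisy"), "median_within"]):
                lowered += 1
        assert lowered >= 2

    def test_small_subclusters_skipped(self):
        expr = self._null_expr(3, n_cells=40)
        regions = np.array(["A", "B"] * 20)
        out = regional_heterogeneity(expr, np.zeros(40, int), regions,
                                     min_cells=200)
        assert len(out) == 0
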