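import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from patchrep import (
    ExpressionMatrix,
    RunConfig,
    build_adjacency,
    compute_tom,
    cut_modules,
    filter_genes,
    gene_set_score,
    normalize_log,
    qc_filter_cells,
    score_modules,
    select_hvg,
    test_module_association,
)
from patchrep.expression_modules import GeneModule


def make_matrix(counts, gene_names=None, cell_ids=None, mito=None, meta=None):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    gene_names = gene_names or [f"G{i}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i}" for i in range(n_cells)]
    mito = mito if mito is not None else [g.startswith("MT-")
                                          for g in gene_names]
    base = pd.DataFrame({"cell_id": cell_ids, "cluster": "0",
                         "doublet_flag": False, "n_heavy_chains": 1,
                         "n_light_chains": 1}).set_index("cell_id")
    if meta is not None:
        for col, vals in meta.items():
            base[col] = vals
    return ExpressionMatrix(sparse.csr_matrix(counts), gene_names, cell_ids,
                            mito, base)


class TestQcFilterCells:
    def _toy(self, **meta):
        # two genes, mito first; columns tuned per test
        counts = np.array([[0, 300], [2000, 2000]])
        return make_matrix(counts, gene_names=["MT-CO1", "ACTB"], meta=meta)

    def test_mito_over_ten_percent_removed(self):
        m = self._toy()
        # cell 1: 300/2300 = 13% mito
        filtered, report = qc_filter_cells(m, RunConfig(min_genes=1))
        assert report.removed["high_mito"] == ["c1"]
        assert "c1" not in filtered.cell_ids

    def test_boundary_cells_retained(self):
        # exactly 10% mito, exactly 1200 UMIs: both strict rules pass
        counts = np.array([[120], [1080]])
        m = make_matrix(counts, gene_names=["MT-CO1", "ACTB"])
        filtered, report = qc_filter_cells(m, RunConfig(min_genes=1))
        assert filtered.n_cells == 1
        assert all(not ids for ids in report.removed.values())

    def test_doublet_and_multichain_rules(self):
        counts = np.tile([[0], [3000]], (1, 3))
        m = make_matrix(counts, gene_names=["MT-CO1", "ACTB"],
                        meta={"doublet_flag": [False, True, False],
                              "n_heavy_chains": [1, 1, 2]})
        filtered, report = qc_filter_cells(m, RunConfig(min_genes=1))
        assert report.removed["doublet"] == ["c1"]
        assert report.removed["multi_chain"] == ["c2"]
        assert filtered.cell_ids.tolist() == ["c0"]

    def test_all_pass_is_identity(self):
        m = self._toy()
        m = m.subset_cells(np.array([False, True]))
        cfg = RunConfig(min_genes=1, mito_max_fraction=0.5)
        filtered, report = qc_filter_cells(m, cfg)
        assert filtered.n_cells == 1
        assert report.retained == ["c1"]

    def test_missing_metadata_column_named(self):
        m = self._toy()
        m.cell_meta.drop(columns=["doublet_flag"], inplace=True)
        with pytest.raises(KeyError, match="doublet_flag"):
            qc_filter_cells(m, RunConfig())

    def test_rule_order_equals_conjunction(self, default_expression):
        m, _ = default_expression
        cfg = RunConfig()
        filtered, report = qc_filter_cells(m, cfg)
        mito, umi, genes = m.mito_fraction(), m.total_umi(), \
            m.n_genes_detected()
        keep = ((mito <= cfg.mito_max_fraction) & (umi >= cfg.min_umi)
                & (genes >= cfg.min_genes))
        assert set(filtered.cell_ids) == set(m.cell_ids[keep])


class TestFilterGenes:
    def test_nine_vs_ten_cell_boundary(self):
        counts = np.zeros((2, 12), dtype=int)
        counts[0, :9] = 1   # detected in 9 cells: removed
        counts[1, :10] = 1  # detected in 10 cells: kept
        m = make_matrix(counts)
        out = filter_genes(m, RunConfig())
        assert out.gene_names.tolist() == ["G1"]

    def test_all_zero_gene_removed_dense_gene_kept(self):
        counts = np.vstack([np.zeros(15, dtype=int),
                            np.ones(15, dtype=int)])
        out = filter_genes(make_matrix(counts), RunConfig())
        assert out.gene_names.tolist() == ["G1"]


class TestNormalizeLog:
    def test_hand_toy(self):
        counts = np.array([[1, 2], [0, 2], [1, 0]])
        m = make_matrix(counts)
        norm = normalize_log(m)
        # totals 2 and 4, median 3; scale factors 1.5 and 0.75
        expected = np.log1p(np.array([[1.5, 1.5], [0.0, 1.5], [1.5, 0.0]]))
        np.testing.assert_allclose(norm, expected)

    def test_proportional_cells_identical(self):
        counts = np.array([[2, 6], [4, 12], [0, 0], [2, 6]])
        norm = normalize_log(make_matrix(counts))
        np.testing.assert_allclose(norm[:, 0], norm[:, 1])

    def test_zero_total_cell_rejected(self):
        counts = np.array([[1, 0], [1, 0]])
        with pytest.raises(ValueError, match="zero-total"):
            normalize_log(make_matrix(counts))


class TestSelectHvg:
    def test_dominant_dispersion_ranked_first(self, rng):
        x = rng.normal(1.0, 0.1, size=(10, 50)).clip(min=0)
        x[3] = rng.normal(1.0, 3.0, size=50).clip(min=0)
        names = [f"G{i}" for i in range(10)]
        assert select_hvg(x, names, 1)[0] == "G3"

    def test_n_equal_gene_count_returns_all(self):
        x = np.random.default_rng(0).random((5, 20))
        assert sorted(select_hvg(x, list("ABCDE"), 5)) == list("ABCDE")

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_hvg(np.ones((3, 4)), ["a", "b", "c"], 4)

    def test_tie_break_is_lexicographic(self):
        x = np.tile(np.array([0.0, 1.0, 0.0, 1.0]), (3, 1))
        assert select_hvg(x, ["zz", "aa", "mm"], 2) == ["aa", "mm"]

    def test_module_genes_enriched_in_top_n(self, default_expression):
        m, truth = default_expression
        cfg = RunConfig(min_genes=1)
        filtered, _ = qc_filter_cells(m, cfg)
        filtered = filter_genes(filtered, cfg)
        norm = normalize_log(filtered)
        hvgs = set(select_hvg(norm, filtered.gene_names, 300))
        module_genes = {g for g, mod in truth.module_of.items() if mod > 0}
        recovery = len(module_genes & hvgs) / len(module_genes)
        assert recovery >= 0.9


class TestAdjacency:
    def test_perfect_correlation_gives_one(self, rng):
        v = rng.random(30)
        a = build_adjacency(np.vstack([v, 2 * v + 1]), power=6)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 0] == 0.0

    def test_anticorrelation_unsigned(self, rng):
        v = rng.random(30)
        a = build_adjacency(np.vstack([v, -v]), power=6)
        assert a[0, 1] == pytest.approx(1.0)

    def test_independent_genes_near_zero(self, rng):
        x = rng.normal(size=(30, 1000))
        a = build_adjacency(x, power=6)
        off = a[~np.eye(30, dtype=bool)]
        assert off.mean() < 0.01

    def test_zero_variance_gene_zeroed_with_warning(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.warns(UserWarning, match="zero-variance"):
            a = build_adjacency(x, power=6)
        assert a[0, 1] == 0.0


class TestTom:
    def test_all_zero_adjacency_gives_identity(self):
        tom = compute_tom(np.zeros((4, 4)))
        np.testing.assert_allclose(tom, np.eye(4))

    def test_hand_computed_three_gene_example(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 0.0)
        tom = compute_tom(a)
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)
        np.testing.assert_allclose(np.diag(tom), 1.0)

    def test_symmetry_and_range(self, rng):
        r = rng.random((20, 20))
        a = np.abs((r + r.T) / 2) ** 6
        np.fill_diagonal(a, 0.0)
        tom = compute_tom(a)
        np.testing.assert_allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0


class TestCutModules:
    def test_singletons_when_k_equals_genes(self):
        tom = np.eye(5)
        mods = cut_modules(tom, list("ABCDE"), 5)
        assert sorted(m.genes[0] for m in mods) == list("ABCDE")
        assert all(len(m.genes) == 1 for m in mods)

    def test_planted_blocks_recovered(self, rng):
        f1, f2 = rng.normal(size=50), rng.normal(size=50)
        x = np.vstack([np.tile(f1, (4, 1)), np.tile(f2, (5, 1))])
        x += rng.normal(scale=1e-9, size=x.shape)
        names = [f"A{i}" for i in range(4)] + [f"B{i}" for i in range(5)]
        tom = compute_tom(build_adjacency(x, 6))
        mods = cut_modules(tom, names, 2)
        got = {frozenset(m.genes) for m in mods}
        assert got == {frozenset(names[:4]), frozenset(names[4:])}

    def test_partition_property(self, rng):
        x = rng.random((12, 40))
        tom = compute_tom(build_adjacency(x, 6))
        mods = cut_modules(tom, [f"G{i}" for i in range(12)], 4)
        all_genes = [g for m in mods for g in m.genes]
        assert sorted(all_genes) == sorted(f"G{i}" for i in range(12))
        assert [m.module_id for m in mods] == [1, 2, 3, 4]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            cut_modules(np.eye(3), list("ABC"), 4)


class TestScoreModules:
    def test_single_gene_single_cell_unit_score(self):
        x = np.array([[0.0, 5.0, 0.0]])
        scores = score_modules(x, ["G0"], [GeneModule(1, ["G0"])])
        np.testing.assert_allclose(scores[1], [0.0, 1.0, 0.0])

    def test_identical_genes_give_inverse_sqrt_n(self):
        n = 16
        x = np.tile(np.ones(n), (3, 1))
        scores = score_modules(x, ["A", "B", "C"],
                               [GeneModule(1, ["A", "B", "C"])])
        np.testing.assert_allclose(scores[1], 1 / np.sqrt(n))

    def test_scores_in_unit_interval_and_zero_gene_zero(self, rng):
        x = rng.random((6, 30))
        x[2] = 0.0
        mods = [GeneModule(1, ["G0", "G2"]),
                GeneModule(2, ["G1", "G3", "G4", "G5"])]
        scores = score_modules(x, [f"G{i}" for i in range(6)], mods)
        assert (scores.to_numpy() >= 0).all()
        assert (scores.to_numpy() <= 1).all()

    def test_modules_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            score_modules(np.ones((2, 3)), ["A", "B"],
                          [GeneModule(1, ["A"])])


class TestModuleAssociation:
    def test_constant_scores_zero_with_warning(self):
        scores = pd.DataFrame({1: np.ones(10)})
        labels = ["a"] * 5 + ["b"] * 5
        with pytest.warns(UserWarning, match="constant"):
            out = test_module_association(scores, labels)
        assert (out.percent_deviance_difference == 0).all()

    def test_perfect_separation_gives_hundred(self):
        labels = ["a"] * 6 + ["b"] * 6
        scores = pd.DataFrame({1: [1.0] * 6 + [0.0] * 6})
        out = test_module_association(scores, labels)
        row = out[out.cluster_id == "a"].iloc[0]
        assert row.percent_deviance_difference == pytest.approx(100.0)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="two"):
            test_module_association(pd.DataFrame({1: [1.0, 2.0]}), ["a", "a"])

    def test_matches_squared_correlation_oracle(self, rng):
        # Gaussian deviance = RSS, so the statistic must equal
        # 100 x squared point-biserial correlation
        for _ in range(30):
            n = int(rng.integers(20, 100))
            y = rng.normal(size=n)
            labels = rng.choice(["a", "b", "c"], size=n)
            if len(set(labels)) < 2:
                continue
            out = test_module_association(pd.DataFrame({1: y}), labels)
            for _, row in out.iterrows():
                ind = (labels == row.cluster_id).astype(float)
                oracle = 100 * np.corrcoef(y, ind)[0, 1] ** 2
                assert row.percent_deviance_difference == \
                    pytest.approx(oracle, abs=1e-10)

    def test_statistic_bounded_and_deviances_ordered(self, rng):
        y = rng.normal(size=60)
        labels = rng.choice(["x", "y"], size=60)
        out = test_module_association(pd.DataFrame({1: y}), labels)
        assert ((out.percent_deviance_difference >= 0)
                & (out.percent_deviance_difference <= 100)).all()
        assert (out.deviance_fit <= out.deviance_null + 1e-12).all()


class TestGeneSetScore:
    def test_hand_toy(self):
        norm = np.array([[1.0, 3.0], [2.0, 4.0]])
        out = gene_set_score(norm, ["g1", "g2"], {"s": ["g1", "g2"]},
                             ["A", "B"])
        a = out[out.cluster_id == "A"].iloc[0]
        assert a.mean_expression == pytest.approx(1.5)
        assert a.mean_rest == pytest.approx(3.5)
        assert a.log2_fold_change == pytest.approx(np.log2(1.5 / 3.5), abs=1e-6)

    def test_exclusive_expression_sign(self):
        norm = np.zeros((2, 6))
        norm[:, :3] = 5.0
        labels = ["A"] * 3 + ["B"] * 3
        out = gene_set_score(norm, ["g1", "g2"], {"s": ["g1"]}, labels)
        assert out[out.cluster_id == "A"].log2_fold_change.iloc[0] > 0
        assert out[out.cluster_id == "B"].log2_fold_change.iloc[0] < 0

    def test_identical_expression_zero_fold_change(self):
        norm = np.ones((2, 6))
        out = gene_set_score(norm, ["g1", "g2"], {"s": ["g1", "g2"]},
                             ["A"] * 3 + ["B"] * 3)
        np.testing.assert_allclose(out.log2_fold_change, 0.0, atol=1e-9)

    def test_empty_intersection_names_set(self):
        with pytest.raises(ValueError, match="oxphos"):
            gene_set_score(np.ones((2, 4)), ["g1", "g2"],
                           {"oxphos": ["nope"]}, ["A", "A", "B", "B"])
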