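"""Tests for single-cell QC, composition, signature scoring and DEG filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from organoquant.sc import (
    CORTICAL_SIGNATURE,
    HIPPOCAMPAL_SIGNATURE,
    CountMatrix,
    QCThresholds,
    composition,
    compute_cdr,
    compute_cell_metrics,
    deg_filter,
    qc_filter,
    signature_score,
    two_group_gene_test,
)
from organoquant.simulate import CountsSimConfig, generate_count_matrix


def small_matrix(counts, genes=None, cells=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{i}" for i in range(counts.shape[1])]
    return CountMatrix(counts=counts, gene_symbols=genes, cell_barcodes=cells)


class TestCellMetrics:
    def test_all_counts_in_mito_genes_gives_100_percent(self):
        m = small_matrix([[5], [7]], genes=["MT-A", "MT-B"])
        metrics = compute_cell_metrics(m)
        assert metrics["mito_percent"].iloc[0] == 100.0

    def test_no_mito_genes_warns_and_zeroes(self):
        m = small_matrix([[5], [7]], genes=["A", "B"])
        with pytest.warns(UserWarning, match="mitochondrial"):
            metrics = compute_cell_metrics(m)
        assert (metrics["mito_percent"] == 0).all()

    def test_zero_umi_cell_flagged(self):
        m = small_matrix([[0, 3], [0, 4]], genes=["MT-A", "B"])
        metrics = compute_cell_metrics(m)
        assert bool(metrics["zero_umi"].iloc[0])
        assert metrics["mito_percent"].iloc[0] == 0.0

    def test_matches_brute_force_per_cell_loops(self, rng):
        counts = rng.integers(0, 20, size=(50, 200))
        genes = [f"MT-{i}" if i < 7 else f"G{i}" for i in range(50)]
        m = small_matrix(counts, genes=genes)
        metrics = compute_cell_metrics(m)
        for j in range(200):
            col = counts[:, j]
            assert metrics["total_umi"].iloc[j] == col.sum()
            assert metrics["n_features"].iloc[j] == (col > 0).sum()
            expected_mito = 100.0 * col[:7].sum() / col.sum() if col.sum() else 0.0
            assert metrics["mito_percent"].iloc[j] == pytest.approx(expected_mito)


class TestQCFilter:
    thresholds = QCThresholds()

    def make_metrics(self, rows):
        return pd.DataFrame(rows, columns=["total_umi", "n_features", "mito_percent"])

    def test_umi_above_cap_discarded(self):
        metrics = self.make_metrics([(26_000, 3_000, 5.0)])
        assert not qc_filter(metrics, self.thresholds).iloc[0]

    def test_boundary_equal_cells_kept(self):
        # strict inequalities: equality on every boundary keeps the cell
        metrics = self.make_metrics(
            [(25_000, 200, 12.0), (5_000, 200, 12.0), (24_999, 201, 11.9)]
        )
        assert qc_filter(metrics, self.thresholds).all()

    def test_each_rule_triggers(self):
        metrics = self.make_metrics(
            [(25_001, 500, 1.0), (4_999, 500, 1.0), (10_000, 199, 1.0), (10_000, 500, 12.01)]
        )
        assert not qc_filter(metrics, self.thresholds).any()

    def test_matches_brute_force_predicate(self, rng):
        metrics = pd.DataFrame(
            {
                "total_umi": rng.integers(0, 40_000, size=1000),
                "n_features": rng.integers(0, 3000, size=1000),
                "mito_percent": rng.uniform(0, 30, size=1000),
            }
        )
        kept = qc_filter(metrics, self.thresholds)
        for i in range(1000):
            r = metrics.iloc[i]
            expected = not (
                r.total_umi > 25_000
                or r.total_umi < 5_000
                or r.n_features < 200
                or r.mito_percent > 12
            )
            assert kept.iloc[i] == expected

    def test_idempotent(self, rng):
        metrics = pd.DataFrame(
            {
                "total_umi": rng.integers(0, 40_000, size=500),
                "n_features": rng.integers(0, 3000, size=500),
                "mito_percent": rng.uniform(0, 30, size=500),
            }
        )
        kept = qc_filter(metrics, self.thresholds)
        again = qc_filter(metrics[kept], self.thresholds)
        assert again.all()


class TestCDR:
    def test_equal_features_gives_zero(self):
        metrics = pd.DataFrame({"n_features": [100, 100, 100]})
        assert (compute_cdr(metrics) == 0).all()

    def test_two_point_z_score(self):
        metrics = pd.DataFrame({"n_features": [100, 300]})
        cdr = compute_cdr(metrics)
        np.testing.assert_allclose(cdr, [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_matches_direct_formula(self, rng):
        x = rng.integers(100, 5000, size=200).astype(float)
        metrics = pd.DataFrame({"n_features": x})
        expected = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(compute_cdr(metrics), expected, atol=1e-12)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            compute_cdr(pd.DataFrame({"n_features": [10]}))


class TestComposition:
    def test_single_sample_fractions(self):
        labels = pd.Series(["A", "A", "B", "B"], index=list("wxyz"))
        samples = pd.Series(["s1"] * 4, index=list("wxyz"))
        groups = pd.Series({"s1": "g1"})
        with pytest.warns(UserWarning):
            table = composition(labels, samples, groups)
        assert table.fractions.loc["s1", "A"] == 0.5
        assert table.fractions.loc["s1", "B"] == 0.5

    def test_identical_groups_null_comparison(self):
        cells, labels, samples = [], [], []
        for s in range(6):
            for i, t in enumerate(["A", "A", "B", "B"]):
                cells.append(f"s{s}c{i}")
                labels.append(t)
                samples.append(f"s{s}")
        labels = pd.Series(labels, index=cells)
        samples = pd.Series(samples, index=cells)
        groups = pd.Series({f"s{s}": ("g1" if s < 3 else "g2") for s in range(6)})
        table = composition(labels, samples, groups)
        for _, row in table.comparisons.iterrows():
            assert row["t"] == 0.0
            assert row["p"] == 1.0

    def test_fractions_match_counting_oracle_and_sum_to_one(self, rng):
        n = 600
        cells = [f"c{i}" for i in range(n)]
        labels = pd.Series(rng.choice(["A", "B", "C"], size=n), index=cells)
        samples = pd.Series(rng.choice([f"s{i}" for i in range(6)], size=n), index=cells)
        groups = pd.Series({f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)})
        table = composition(labels, samples, groups)
        np.testing.assert_allclose(table.fractions.sum(axis=1), 1.0, atol=1e-12)
        for s in table.fractions.index:
            in_s = samples == s
            for t in table.fractions.columns:
                assert table.fractions.loc[s, t] == pytest.approx(
                    ((labels == t) & in_s).sum() / in_s.sum()
                )

    def test_invariant_to_cell_order(self, rng):
        n = 200
        cells = [f"c{i}" for i in range(n)]
        labels = pd.Series(rng.choice(["A", "B"], size=n), index=cells)
        samples = pd.Series(rng.choice(["s1", "s2", "s3", "s4"], size=n), index=cells)
        groups = pd.Series({"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"})
        t1 = composition(labels, samples, groups)
        perm = rng.permutation(n)
        t2 = composition(labels.iloc[perm], samples.iloc[perm], groups)
        pd.testing.assert_frame_equal(t1.fractions, t2.fractions)


class TestSignatureScore:
    def test_shipped_lists_have_13_symbols_each(self):
        assert len(CORTICAL_SIGNATURE) == 13
        assert len(HIPPOCAMPAL_SIGNATURE) == 13
        assert CORTICAL_SIGNATURE[:2] == ("TNNC1", "MYL4")
        assert HIPPOCAMPAL_SIGNATURE[:2] == ("ZBTB20", "GLIS3")
        assert not set(CORTICAL_SIGNATURE) & set(HIPPOCAMPAL_SIGNATURE)

    def test_all_zero_variance_scores_zero_with_warning(self):
        m = small_matrix(np.ones((2, 5), dtype=int), genes=["TNNC1", "MYL4"])
        with pytest.warns(UserWarning, match="zero variance"):
            scores = signature_score(m, CORTICAL_SIGNATURE)
        assert (scores == 0).all()

    def test_no_signature_gene_present_rejected(self, rng):
        m = small_matrix(rng.integers(0, 5, size=(3, 4)))
        with pytest.raises(ValueError):
            signature_score(m, CORTICAL_SIGNATURE)

    def test_high_expressing_population_scores_higher(self):
        n_genes = 100
        symbols = list(CORTICAL_SIGNATURE) + [f"G{i}" for i in range(n_genes - 13)]
        cfg = CountsSimConfig(
            n_genes=n_genes, n_mito_genes=5,
            cells_per_type={"lo": 150, "hi": 150},
            de_genes=tuple((i, 2.0, "hi") for i in range(13)),
            gene_symbols=tuple(symbols[:-5] + [f"MT-{i}" for i in range(5)]),
            seed=17,
        )
        counts, labels, _ = generate_count_matrix(cfg)
        scores = signature_score(counts, CORTICAL_SIGNATURE)
        hi = scores[(labels == "hi").to_numpy()]
        lo = scores[(labels == "lo").to_numpy()]
        assert hi.mean() > lo.mean()

    def test_invariant_to_adding_constant_nonsignature_gene(self, rng):
        counts = rng.integers(0, 10, size=(20, 30))
        genes = ["TNNC1", "MYL4"] + [f"G{i}" for i in range(18)]
        m1 = small_matrix(counts, genes=genes)
        s1 = signature_score(m1, ["TNNC1", "MYL4"])
        # appending an all-zero extra gene leaves per-cell totals unchanged
        m2 = small_matrix(
            np.vstack([counts, np.zeros((1, 30), dtype=int)]), genes=genes + ["CONST"]
        )
        s2 = signature_score(m2, ["TNNC1", "MYL4"])
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestDEGFilter:
    def test_standard_thresholds_applied(self):
        records = pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "log2_fold_change": [0.30, 0.25, 0.30],
                "p_raw": [0.049 / 1000, 0.001, 0.10],
            }
        )
        out = deg_filter(records, n_tests=1000)
        assert bool(out.loc[0, "significant"])  # p_bonf = 0.049, lfc 0.30
        assert not out.loc[1, "significant"]  # lfc boundary 0.25 exactly
        assert not out.loc[2, "significant"]  # p_bonf = 1 after capping

    def test_bonferroni_capped_and_ordered(self, rng):
        p = rng.uniform(0, 1, size=100)
        records = pd.DataFrame({"gene": range(100), "log2_fold_change": 1.0, "p_raw": p})
        out = deg_filter(records, n_tests=500)
        np.testing.assert_allclose(out["p_bonferroni"], np.minimum(1.0, p * 500))
        assert (out["p_bonferroni"] >= out["p_raw"]).all()

    def test_matches_brute_force_predicate(self, rng):
        records = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(1000)],
                "log2_fold_change": rng.normal(0, 0.5, size=1000),
                "p_raw": rng.uniform(0, 1, size=1000),
            }
        )
        out = deg_filter(records, n_tests=1000)
        for _, r in out.iterrows():
            expected = (min(1.0, r.p_raw * 1000) < 0.05) and (abs(r.log2_fold_change) > 0.25)
            assert bool(r.significant) == expected

    def test_significant_set_shrinks_with_more_tests(self, rng):
        records = pd.DataFrame(
            {
                "gene": range(200),
                "log2_fold_change": rng.normal(0, 1, size=200),
                "p_raw": rng.uniform(0, 0.1, size=200),
            }
        )
        sizes = [
            deg_filter(records, n_tests=n)["significant"].sum() for n in (200, 400, 1600, 6400)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            deg_filter(pd.DataFrame({"gene": ["a"], "log2_fold_change": [1.0], "p_raw": [1.5]}), 1)


class TestTwoGroupGeneTest:
    def make_counts(self, x1, x2):
        counts = np.concatenate([x1, x2], axis=1)
        m = small_matrix(counts)
        groups = pd.Series(
            ["g1"] * x1.shape[1] + ["g2"] * x2.shape[1], index=m.cell_barcodes
        )
        return m, groups

    def test_null_p_values_roughly_uniform(self, rng):
        x = rng.integers(0, 20, size=(500, 60))
        m, groups = self.make_counts(x[:, :30], x[:, 30:])
        res = two_group_gene_test(m, groups)
        assert 0.3 <= np.median(res["p_raw"]) <= 0.7

    def test_fully_separated_gene_extreme_p(self, rng):
        g1 = np.vstack([rng.integers(5, 20, size=(1, 50)), rng.integers(0, 20, size=(4, 50))])
        g2 = np.vstack([np.zeros((1, 50), dtype=int), rng.integers(0, 20, size=(4, 50))])
        m, groups = self.make_counts(g1, g2)
        res = two_group_gene_test(m, groups)
        assert res["p_raw"].iloc[0] < 1e-6

    def test_constant_gene_gives_p_one(self):
        # constant counts and equal per-cell totals: constant after
        # normalisation as well, so the rank-sum carries no information
        x = np.tile(np.array([[5], [3], [7]]), (1, 40))
        m, groups = self.make_counts(x[:, :20], x[:, 20:])
        res = two_group_gene_test(m, groups)
        assert res["statistic"].iloc[0] == 0.0
        assert res["p_raw"].iloc[0] == 1.0

    def test_agrees_with_scipy_on_tie_free_data(self, rng):
        # two genes: a permutation gene plus a constant ballast gene so the
        # per-cell normalisation is strictly monotone and tie-free
        v = rng.permutation(100) + 1
        counts = np.vstack([v, np.full(100, 1000)])
        m, groups = self.make_counts(counts[:, :50], counts[:, 50:])
        res = two_group_gene_test(m, groups)
        expr = np.log1p(v / (v + 1000) * 1e4)  # what the pipeline ranks
        ref_stat, ref_p = stats.ranksums(expr[:50], expr[50:])
        assert res["p_raw"].iloc[0] == pytest.approx(ref_p, rel=1e-6)
        assert res["statistic"].iloc[0] == pytest.approx(ref_stat, rel=1e-6)

    def test_empty_group_rejected(self, rng):
        m = small_matrix(rng.integers(0, 5, size=(3, 4)))
        groups = pd.Series(["g1"] * 4, index=m.cell_barcodes)
        with pytest.raises(ValueError):
            two_group_gene_test(m, groups)


class TestCountMatrixContainer:
    def test_duplicate_identifiers_rejected(self, rng):
        with pytest.raises(ValueError):
            small_matrix(rng.integers(0, 5, size=(2, 2)), genes=["a", "a"])
        with pytest.raises(ValueError):
            small_matrix(rng.integers(0, 5, size=(2, 2)), cells=["c", "c"])

    def test_subset_cells_preserves_columns(self, rng):
        m = small_matrix(rng.integers(0, 9, size=(5, 6)))
        sub = m.subset_cells(["c3", "c1"])
        np.testing.assert_array_equal(
            np.asarray(sub.counts.todense()), np.asarray(m.counts.todense())[:, [3, 1]]
        )
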