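import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_matrix
from lncnet.array_io import ExpressionMatrix
from lncnet.diffexpr import (
    TINY_P,
    bh_adjust,
    differential_expression,
    group_fold_change,
    hierarchical_cluster,
    summarize_de,
    top_table,
    two_group_ttest,
    volcano_filter,
)


def swap_groups(matrix: ExpressionMatrix) -> ExpressionMatrix:
    flipped = {s: ("treated" if g == "control" else "control") for s, g in matrix.groups.items()}
    return ExpressionMatrix(values=matrix.values, groups=flipped, scale=matrix.scale)


class TestFoldChange:
    def test_up_and_down_arithmetic(self):
        m = make_matrix(np.array([[5.0, 5.0, 10.0, 10.0], [10.0, 10.0, 5.0, 5.0]]), 2, 2, scale="linear")
        assert group_fold_change(m, "P0") == (2.0, "Up")
        assert group_fold_change(m, "P1") == (2.0, "Down")

    def test_equal_means_tie_breaks_up(self):
        m = make_matrix(np.array([[3.0, 5.0, 4.0, 4.0]]), 2, 2, scale="linear")
        assert group_fold_change(m, "P0") == (1.0, "Up")

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(11)
        m = make_matrix(np.exp(rng.normal(2, 1, size=(5, 8))), 4, 4, scale="linear")
        de, de_sw = differential_expression(m), differential_expression(swap_groups(m))
        np.testing.assert_allclose(de["fold_change"], de_sw["fold_change"], rtol=1e-12)
        np.testing.assert_allclose(de["p_value"], de_sw["p_value"], rtol=1e-9)
        flipped = de["regulation"].map({"Up": "Down", "Down": "Up"})
        assert (de_sw["regulation"] == flipped).all()


class TestTTest:
    def test_pooled_closed_form(self):
        # A=[1..5] vs B=[2..6]: t = -1, df = 8, two-sided p ~ 0.3466
        m = make_matrix(np.array([[2.0, 3, 4, 5, 6, 1, 2, 3, 4, 5]]), 5, 5)
        assert two_group_ttest(m, "P0") == pytest.approx(0.34659350708733416, abs=1e-10)

    def test_identical_groups_p_one(self):
        m = make_matrix(np.array([[1.0, 2, 3, 1, 2, 3]]), 3, 3)
        assert two_group_ttest(m, "P0") == 1.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(4, 10)), 5, 5)
        for p in m.probe_ids:
            assert two_group_ttest(m, p) == pytest.approx(two_group_ttest(swap_groups(m), p), rel=1e-9)

    def test_zero_variance_policies(self):
        equal = make_matrix(np.array([[2.0, 2, 2, 2]]), 2, 2)
        assert two_group_ttest(equal, "P0") == 1.0
        shifted = make_matrix(np.array([[2.0, 2, 5, 5]]), 2, 2)
        assert two_group_ttest(shifted, "P0") == TINY_P

    def test_welch_variant_differs_under_unequal_variance(self):
        # unbalanced groups with very different spreads: pooled and Welch diverge
        m = make_matrix(np.array([[0.0, 0.1, -0.1, 1.0, 3.0, 5.0, 7.0, 9.0]]), 3, 5)
        assert two_group_ttest(m, "P0", "welch") != two_group_ttest(m, "P0", "pooled")
        with pytest.raises(ValueError, match="variant"):
            two_group_ttest(m, "P0", "bayes")


class TestVolcanoFilter:
    TABLE = pd.DataFrame(
        {
            "fold_change": [2.5, 2.5, 2.0, 3.0, 2.5, 1.5],
            "p_value": [0.01, 0.06, 0.01, 0.05, 0.01, 0.001],
            "regulation": ["Up", "Up", "Up", "Down", "Down", "Up"],
        },
        index=[f"P{i}" for i in range(6)],
    )

    def test_enumerated_example_with_boundaries_excluded(self):
        up, down = volcano_filter(self.TABLE)
        assert up == {"P0"} and down == {"P4"}

    def test_empty_table(self):
        up, down = volcano_filter(self.TABLE.iloc[:0])
        assert up == set() and down == set()

    def test_partition_identity(self):
        up, down = volcano_filter(self.TABLE)
        s = summarize_de(up, down)
        assert s["total"] == s["up"] + s["down"] == len(up | down)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_comprehension(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        table = pd.DataFrame(
            {
                "fold_change": np.round(1 + rng.exponential(1.5, n), 2),
                "p_value": np.round(rng.uniform(0, 0.2, n), 3).clip(1e-6),
                "regulation": rng.choice(["Up", "Down"], n),
            },
            index=[f"P{i}" for i in range(n)],
        )
        up, down = volcano_filter(table)
        brute_up = {
            p
            for p in table.index
            if table.at[p, "fold_change"] > 2.0
            and table.at[p, "p_value"] < 0.05
            and table.at[p, "regulation"] == "Up"
        }
        brute_down = {
            p
            for p in table.index
            if table.at[p, "fold_change"] > 2.0
            and table.at[p, "p_value"] < 0.05
            and table.at[p, "regulation"] == "Down"
        }
        assert up == brute_up and down == brute_down


class TestBH:
    def test_monotone_after_sort(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        fdr = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-15).all()
        assert (fdr >= p - 1e-15).all() and (fdr <= 1).all()


class TestTopTable:
    def test_sort_and_tie_breaks(self, default_dataset):
        _, annotation, _, _ = default_dataset
        probes = annotation.probe_ids[:4]
        de = pd.DataFrame(
            {
                "fold_change": [5.0, 3.0, 8.0, 5.0],
                "regulation": ["Up"] * 4,
                "p_value": [0.01, 0.02, 0.03, 0.001],
                "fdr": [0.05] * 4,
                "mean_control": [1.0] * 4,
                "mean_treated": [5.0] * 4,
            },
            index=probes,
        )
        out = top_table(de, annotation, 4, 0)
        assert list(out["Fold change"]) == [8.0, 5.0, 5.0, 3.0]
        # FC tie resolved by smaller p first
        tied = out[out["Fold change"] == 5.0]
        assert list(tied["P-value"]) == [0.001, 0.01]
        assert list(out.columns) == [
            "Probe name",
            "Regulation",
            "Seqname",
            "Gene Symbol",
            "RNA length",
            "chrom",
            "Fold change",
            "P-value",
        ]

    def test_zero_up_gives_empty_block(self, default_dataset):
        _, annotation, _, _ = default_dataset
        de = differential_expression(default_dataset[0])
        out = top_table(de, annotation, 0, 3)
        assert (out["Regulation"] == "Down").all() and len(out) == 3


class TestHierarchicalCluster:
    def test_identical_pair_merges_first_at_zero_height(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = make_matrix(np.vstack([x, x, -x + 5]), 2, 2)
        order = hierarchical_cluster(m, axis="rows")
        first_merge = order.row_linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0, abs=1e-12)

    def test_one_dim_euclidean_average_linkage(self):
        # points {0, 1, 10, 11}: the tight pairs must merge before anything else
        m = make_matrix(np.array([[0.0, 0], [1.0, 1], [10.0, 10], [11.0, 11]]), 1, 1, prefix="X")
        order = hierarchical_cluster(m, axis="rows", metric="euclidean", standardize=False)
        Z = order.row_linkage
        merged = [{int(Z[i][0]), int(Z[i][1])} for i in range(2)]
        assert {0, 1} in merged and {2, 3} in merged

    def test_leaf_order_is_permutation_and_heights_monotone(self, default_dataset):
        matrix, _, _, truth = default_dataset
        sub = matrix.subset(sorted(truth.de_probe_ids()))
        order = hierarchical_cluster(sub)
        assert sorted(order.row_order) == sorted(sub.probe_ids)
        assert sorted(order.col_order) == sorted(sub.sample_ids)
        assert (np.diff(order.row_linkage[:, 2]) >= -1e-12).all()

    def test_constant_rows_dropped_with_warning(self, caplog):
        m = make_matrix(np.array([[1.0, 2, 3, 4], [2.0, 2, 2, 2], [4.0, 3, 2, 1]]), 2, 2)
        with caplog.at_level("WARNING"):
            order = hierarchical_cluster(m, axis="rows")
        assert order.dropped_rows == ["P1"]
        assert "P1" not in order.row_order
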