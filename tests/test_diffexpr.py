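"""Expression summarization, SAM d statistic, selection and clustering."""

import numpy as np
import pandas as pd
import pytest

from sepmap.diffexpr import (
    cluster_fold_changes,
    differential_expression,
    sam_statistic,
    select_changed_genes,
    summarize_gene_expression,
)
from sepmap.synthdata import SimulationConfig, gen_probe_dataset, sample_columns
from tests.conftest import TG, WT, make_probe_table


class TestSummarization:
    def test_single_probe_returns_its_log2(self):
        table = make_probe_table({}, genes={"g1": [[8.0] * 6]})
        expr = summarize_gene_expression(table, TG + WT)
        assert expr.loc["g1"].to_numpy() == pytest.approx(np.log2(8.0))

    def test_median_of_three_probes(self):
        table = make_probe_table(
            {}, genes={"g1": [[2.0 ** 5] * 6, [2.0 ** 7] * 6, [2.0 ** 9] * 6]}
        )
        expr = summarize_gene_expression(table, TG + WT)
        assert expr.loc["g1"].to_numpy() == pytest.approx(7.0)

    def test_inclusion_and_skip_probes_are_excluded(self):
        table = make_probe_table(
            {"ev1": {"inclusion": [[10000] * 6], "skip": [[10000] * 6]}},
            genes={"gene_of_ev1": [[2.0 ** 6] * 6]},
        )
        expr = summarize_gene_expression(table, TG + WT)
        assert expr.loc["gene_of_ev1"].to_numpy() == pytest.approx(6.0)

    def test_gene_without_constitutive_probes_skipped(self, caplog):
        table = make_probe_table(
            {"ev1": {"inclusion": [[10] * 6], "skip": [[10] * 6]}},
            genes={"g2": [[16.0] * 6]},
        )
        expr = summarize_gene_expression(table, TG + WT)
        assert list(expr.index) == ["g2"]
        assert "without constitutive probes" in caplog.text


class TestSamStatistic:
    def test_equal_means_give_zero(self):
        a = np.array([[1.0, 2.0, 3.0]])
        d = sam_statistic(a, a.copy(), s0=0.5)
        assert d == pytest.approx(0.0)

    def test_hand_value_with_known_s_and_s0(self):
        # groups with means 2 and 1 and pooled SE exactly 0.5
        delta = np.sqrt(0.375)  # per-group variance 0.375 -> s = 0.5
        a = np.array([[2 - delta, 2.0, 2 + delta]])
        b = np.array([[1 - delta, 1.0, 1 + delta]])
        d = sam_statistic(a, b, s0=0.5)
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(5, 1, (30, 3)), rng.normal(5, 1, (30, 3))
        assert sam_statistic(a, b, s0=0.2) == pytest.approx(-sam_statistic(b, a, s0=0.2))

    def test_shift_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(5, 1, (30, 3)), rng.normal(5, 1, (30, 3))
        d0 = sam_statistic(a, b)
        d1 = sam_statistic(a + 3.7, b + 3.7)
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_zero_variance_needs_nonzero_s0(self):
        a = np.array([[1.0, 1.0, 1.0]])
        b = np.array([[2.0, 2.0, 2.0]])
        with pytest.raises(ValueError, match="s0"):
            sam_statistic(a, b, s0=0.0)


class TestSelection:
    @pytest.mark.parametrize(
        "log2fc, q, selected",
        [
            (1.0, 0.01, True),   # 2-fold boundary included
            (-1.0, 0.049, True),
            (0.9, 0.0, False),
            (3.0, 0.2, False),
            (3.0, 0.05, False),  # q strictly below 0.05
        ],
    )
    def test_two_fold_q_rule(self, log2fc, q, selected):
        calls = pd.DataFrame({"log2fc": [log2fc], "q": [q]}, index=["g"])
        assert (len(select_changed_genes(calls)) == 1) is selected

    def test_planted_de_genes_recovered_end_to_end(self):
        cfg = SimulationConfig(
            n_genes=200, n_events=10, frac_de_genes=0.1, de_log2fc=2.0,
            frac_changed_events=0, seed=12,
        )
        table, truth = gen_probe_dataset(cfg)
        tg, wt = sample_columns(cfg)
        calls = differential_expression(table, tg, wt)
        de_true = set(truth.gene_log2fc[truth.gene_log2fc != 0].index)
        selected = set(calls[calls["selected"]].index)
        assert de_true == selected


class TestClustering:
    def test_identical_rows_merge_first_at_distance_zero(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0], [4.0, 1.0, -2.0, 0.0]],
            index=["a", "b", "c"],
        )
        result = cluster_fold_changes(mat)
        assert result.linkage[0, 2] == pytest.approx(0.0)
        assert sorted(result.linkage[0, :2]) == [0, 1]

    def test_row_and_its_negation_sit_at_distance_two(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [-1.0, -2.0, -3.0, -4.0]],
                           index=["a", "b"])
        result = cluster_fold_changes(mat)
        assert result.linkage[0, 2] == pytest.approx(2.0)

    def test_four_comparison_profile_clusters_by_direction(self):
        # mimics up- vs down-regulated genes across four muscle/age contrasts
        rng = np.random.default_rng(3)
        pattern = np.array([2.0, 0.3, 1.5, 0.2])  # stronger in vastus than biceps
        up = pattern + rng.normal(0, 0.1, (5, 4))
        down = -pattern + rng.normal(0, 0.1, (5, 4))
        mat = pd.DataFrame(
            np.vstack([up, down]),
            index=[f"up{i}" for i in range(5)] + [f"down{i}" for i in range(5)],
            columns=["V4w", "B4w", "V13w", "B13w"],
        )
        result = cluster_fold_changes(mat)
        order = result.leaf_order
        half = set(order[:5])
        assert half == {f"up{i}" for i in range(5)} or half == {
            f"down{i}" for i in range(5)
        }

    def test_permutation_equivariance_of_topology(self):
        rng = np.random.default_rng(4)
        mat = pd.DataFrame(rng.normal(0, 1, (8, 4)),
                           index=[f"g{i}" for i in range(8)])
        res1 = cluster_fold_changes(mat)
        perm = rng.permutation(8)
        res2 = cluster_fold_changes(mat.iloc[perm])

        def merge_sets(result):
            n = len(result.labels)
            clusters = {i: frozenset([result.labels[i]]) for i in range(n)}
            merges = set()
            for k, (i, j, _, _) in enumerate(result.linkage):
                merged = clusters[int(i)] | clusters[int(j)]
                clusters[n + k] = merged
                merges.add(merged)
            return merges

        assert merge_sets(res1) == merge_sets(res2)

    def test_constant_row_placed_at_distance_one(self, caplog):
        mat = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["a", "b"])
        result = cluster_fold_changes(mat)
        assert result.linkage[0, 2] == pytest.approx(1.0)
        assert "constant" in caplog.text

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            cluster_fold_changes(pd.DataFrame([[1.0, 2.0]], index=["a"]))
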