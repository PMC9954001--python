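"""DEG filter rules, heatmap gene selection, UPGMA oracle equivalence, ddCt."""

import itertools

import numpy as np
import pandas as pd
import pytest

import combiscreen as cs
from combiscreen.simulate import ExpressionTable


def expr_from_log2(log2_matrix, groups):
    values = pd.DataFrame(
        2.0 ** np.asarray(log2_matrix, dtype=float),
        index=[f"g{i}" for i in range(len(log2_matrix))],
        columns=list(groups.keys()),
    )
    return ExpressionTable(values, pd.Series(groups))


class TestDifferentialExpression:
    def test_planted_effect_passes_rule1(self):
        expr = cs.simulate_expression(100, {"V": 5, "T": 5}, de_genes=20,
                                      log2fc=2.0, sigma=0.1, seed=0)
        deg = cs.differential_expression(expr, "V", "T").set_index("gene")
        assert (deg.loc[expr.de_genes, "passed_rule"] == "fc_and_p").all()

    def test_fc_gate_is_strict(self):
        # strong p but |log2FC| < 1 must not pass
        rng = np.random.default_rng(1)
        base = rng.normal(10, 0.01, size=(1, 10))
        mat = base.copy()
        mat[0, 5:] += 0.9
        groups = {f"V{i}": "V" for i in range(5)} | {f"T{i}": "T" for i in range(5)}
        expr = expr_from_log2(np.repeat(mat, 1, axis=0), groups)
        deg = cs.differential_expression(expr, "V", "T")
        assert deg["p_value"].iloc[0] < 0.05
        assert deg["passed_rule"].iloc[0] == "none"

    def test_na_intensity_rule_fires_on_undefined_ratio(self):
        groups = {"V1": "V", "V2": "V", "T1": "T", "T2": "T"}
        values = pd.DataFrame(
            {
                "V1": [0.0, 0.0, 500.0],
                "V2": [0.0, 0.0, 500.0],
                "T1": [1200.0, 800.0, 600.0],
                "T2": [1200.0, 800.0, 600.0],
            },
            index=["hit", "below_cutoff", "defined"],
        )
        expr = ExpressionTable(values, pd.Series(groups))
        deg = cs.differential_expression(expr, "V", "T").set_index("gene")
        assert deg.loc["hit", "passed_rule"] == "na_intensity"
        assert deg.loc["below_cutoff", "passed_rule"] == "none"
        assert deg.loc["defined", "passed_rule"] != "na_intensity"

    def test_relaxing_thresholds_never_removes_genes(self):
        expr = cs.simulate_expression(200, {"V": 4, "T": 4}, de_genes=30,
                                      log2fc=1.3, sigma=0.4, seed=3)
        strict = cs.differential_expression(expr, "V", "T", fc_threshold=1.0, alpha=0.05)
        loose = cs.differential_expression(expr, "V", "T", fc_threshold=0.5, alpha=0.2)
        strict_hits = set(strict.loc[strict.passed_rule == "fc_and_p", "gene"])
        loose_hits = set(loose.loc[loose.passed_rule == "fc_and_p", "gene"])
        assert strict_hits <= loose_hits

    def test_null_false_positive_fraction_small(self):
        fracs = []
        for seed in range(20):
            expr = cs.simulate_expression(200, {"V": 5, "T": 5}, de_genes=0,
                                          sigma=0.1, seed=seed)
            deg = cs.differential_expression(expr, "V", "T")
            fracs.append((deg.passed_rule == "fc_and_p").mean())
        assert max(fracs) <= 0.05

    def test_bh_adjustment_is_more_conservative(self):
        expr = cs.simulate_expression(300, {"V": 4, "T": 4}, de_genes=10,
                                      log2fc=1.2, sigma=0.5, seed=9)
        raw = cs.differential_expression(expr, "V", "T")
        adj = cs.differential_expression(expr, "V", "T", adjust=True)
        assert (adj.passed_rule == "fc_and_p").sum() <= (raw.passed_rule == "fc_and_p").sum()

    def test_unknown_group_rejected(self):
        expr = cs.simulate_expression(10, {"V": 3, "T": 3}, 0, seed=0)
        with pytest.raises(ValueError):
            cs.differential_expression(expr, "V", "nope")


class TestHeatmapGenes:
    def test_direct_sort_by_range(self):
        values = pd.DataFrame(
            {"s1": [100.0, 0.0, 50.0], "s2": [600.0, 1500.0, 150.0]},
            index=["A", "B", "C"],
        )
        assert cs.select_heatmap_genes(values, 2) == ["B", "A"]

    def test_constant_gene_selected_last(self):
        values = pd.DataFrame(
            {"s1": [5.0, 1.0], "s2": [5.0, 2.0]}, index=["flat", "varying"]
        )
        assert cs.select_heatmap_genes(values, 1) == ["varying"]

    def test_k_equals_n_returns_all_in_range_order(self):
        values = pd.DataFrame(
            {"s1": [0.0, 0.0, 0.0], "s2": [3.0, 1.0, 2.0]}, index=["a", "b", "c"]
        )
        assert cs.select_heatmap_genes(values, 3) == ["a", "c", "b"]

    def test_invariances(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.random((20, 6)) * 1000,
                              index=[f"g{i}" for i in range(20)])
        base = cs.select_heatmap_genes(values, 7)
        assert cs.select_heatmap_genes(values[values.columns[::-1]], 7) == base
        assert cs.select_heatmap_genes(values + 123.0, 7) == base

    def test_bad_k(self):
        values = pd.DataFrame({"s1": [1.0]}, index=["a"])
        with pytest.raises(ValueError):
            cs.select_heatmap_genes(values, 0)
        with pytest.raises(ValueError):
            cs.select_heatmap_genes(values, 2)


class TestMeanCenter:
    def test_rows_have_zero_mean(self):
        values = pd.DataFrame({"s1": [16.0, 4.0], "s2": [64.0, 4.0]}, index=["a", "b"])
        centered = cs.mean_center(values)
        np.testing.assert_allclose(centered.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(centered.loc["a"], [-1.0, 1.0])

    def test_without_log_transform(self):
        values = pd.DataFrame({"s1": [4.0], "s2": [6.0]}, index=["a"])
        centered = cs.mean_center(values, log2_transform=False)
        np.testing.assert_allclose(centered.loc["a"], [-1.0, 1.0])

    def test_single_sample_row_is_zero(self):
        values = pd.DataFrame({"s1": [8.0]}, index=["a"])
        assert cs.mean_center(values).loc["a", "s1"] == 0.0


def naive_upgma(matrix: np.ndarray) -> list[tuple[frozenset, float]]:
    """O(n^3) UPGMA on euclidean distances: merge sets + heights oracle."""
    n = len(matrix)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {
        (i, j): float(np.linalg.norm(matrix[i] - matrix[j]))
        for i in range(n) for j in range(i + 1, n)
    }

    def d(ci, cj):
        return float(np.mean([dist[tuple(sorted((a, b)))] for a in clusters[ci] for b in clusters[cj]]))

    merges = []
    next_id = n
    while len(clusters) > 1:
        pairs = list(itertools.combinations(sorted(clusters), 2))
        best = min(pairs, key=lambda p: d(*p))
        h = d(*best)
        members = clusters.pop(best[0]) + clusters.pop(best[1])
        clusters[next_id] = members
        merges.append((frozenset(members), h))
        next_id += 1
    return merges


def tree_merges(tree: cs.LinkageTree) -> list[tuple[frozenset, float]]:
    n = len(tree.labels)
    members = {i: [i] for i in range(n)}
    out = []
    for k, (i, j, h, _) in enumerate(tree.merges):
        merged = members[int(i)] + members[int(j)]
        members[n + k] = merged
        out.append((frozenset(merged), float(h)))
    return out


class TestUpgma:
    def test_identical_rows_merge_first_at_zero(self):
        values = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]],
            index=["a", "b", "c"],
        )
        tree = cs.average_linkage_cluster(values)
        assert tree.heights[0] == pytest.approx(0.0)

    def test_n_minus_one_merges_and_monotone_heights(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(size=(8, 5)))
        tree = cs.average_linkage_cluster(values)
        assert tree.merges.shape[0] == 7
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            mat = rng.normal(size=(6, 4))
            tree = cs.average_linkage_cluster(pd.DataFrame(mat))
            got = tree_merges(tree)
            expected = naive_upgma(mat)
            for (ms, hs), (mo, ho) in zip(got, expected):
                assert ms == mo
                assert hs == pytest.approx(ho, rel=1e-9)

    def test_correlation_metric_drops_constant_rows(self):
        values = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
            index=["flat", "up", "down"],
        )
        tree = cs.average_linkage_cluster(values, distance="correlation")
        assert tree.dropped == ["flat"]
        assert len(tree.labels) == 2

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            cs.average_linkage_cluster(pd.DataFrame([[1.0, 2.0]]))


class TestDdct:
    def ct_table(self, target_v, target_t, ref_v, ref_t):
        rows = []
        for gene, group, vals in [
            ("X", "vehicle", target_v), ("X", "treated", target_t),
            ("R", "vehicle", ref_v), ("R", "treated", ref_t),
        ]:
            rows += [{"gene": gene, "group": group, "replicate": i, "ct": v}
                     for i, v in enumerate(vals)]
        return pd.DataFrame(rows)

    def test_identity_and_doubling(self):
        ct = self.ct_table([25, 25], [25, 25], [18, 18], [18, 18])
        assert cs.ddct_fold_change(ct, "X", "R", "vehicle", "treated").fold_change == pytest.approx(1.0)
        ct = self.ct_table([25, 25], [24, 24], [18, 18], [18, 18])
        assert cs.ddct_fold_change(ct, "X", "R", "vehicle", "treated").fold_change == pytest.approx(2.0)

    def test_self_referenced_gene_is_unity_with_interval_containing_one(self):
        ct = self.ct_table([25.1, 24.9, 25.0], [23.8, 24.2, 24.0], [18, 18, 18], [18, 18, 18])
        res = cs.ddct_fold_change(ct, "X", "X", "vehicle", "treated")
        assert res.fold_change == pytest.approx(1.0)
        lo, hi = res.fold_interval
        assert lo <= 1.0 <= hi

    def test_propagated_sd_matches_monte_carlo(self):
        rng = np.random.default_rng(3)
        ct = self.ct_table(
            25 + rng.normal(0, 0.2, 4), 23 + rng.normal(0, 0.3, 4),
            18 + rng.normal(0, 0.1, 4), 18 + rng.normal(0, 0.15, 4),
        )
        res = cs.ddct_fold_change(ct, "X", "R", "vehicle", "treated")
        # resample each group mean from its observed spread
        draws = {}
        for gene, group in itertools.product(["X", "R"], ["vehicle", "treated"]):
            vals = ct.loc[(ct.gene == gene) & (ct.group == group), "ct"]
            draws[(gene, group)] = rng.normal(
                vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals)), size=100_000
            )
        mc = (draws[("X", "treated")] - draws[("R", "treated")]) - (
            draws[("X", "vehicle")] - draws[("R", "vehicle")]
        )
        assert res.propagated_sd == pytest.approx(float(mc.std(ddof=1)), rel=0.05)

    def test_missing_reference_rejected(self):
        ct = self.ct_table([25], [25], [18], [18])
        with pytest.raises(ValueError, match="reference"):
            cs.ddct_fold_change(ct[ct.gene != "R"], "X", "R", "vehicle", "treated")

    def test_single_replicate_gives_point_estimate_only(self):
        ct = self.ct_table([25.0], [24.0], [18.0], [18.0])
        with pytest.warns(UserWarning):
            res = cs.ddct_fold_change(ct, "X", "R", "vehicle", "treated")
        assert res.fold_change == pytest.approx(2.0)
        assert res.propagated_sd is None
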