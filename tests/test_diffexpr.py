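"""Welch testing, BH adjustment, DEG calling and partitioning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from endonet import (
    SyntheticConfig,
    bh_adjust,
    call_degs,
    generate_expression_matrix,
    log2_fold_change,
    partition_degs,
    welch_t_test,
)
from endonet.data import ExpressionMatrix, StudyDesign


def bh_stepup_oracle(p):
    """Brute-force BH step-up definition, written independently."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [None] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


class TestWelch:
    def test_identical_groups_are_null(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_closed_form_example(self):
        t, df, p = welch_t_test([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0214, abs=2e-4)

    def test_swapping_groups_negates_t(self):
        t1, _, p1 = welch_t_test([1, 5, 2, 8], [3, 3, 4])
        t2, _, p2 = welch_t_test([3, 3, 4], [1, 5, 2, 8])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means(self):
        t, _, p = welch_t_test([2.0, 2.0], [1.0, 1.0])
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(11)
        ps = [welch_t_test(rng.normal(size=3), rng.normal(size=3))[2]
              for _ in range(2000)]
        assert stats.kstest(ps, "uniform").pvalue > 1e-3


class TestBH:
    def test_stepup_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_stepup_oracle_on_all_permutations(self, n):
        pool = [0.001, 0.01, 0.04, 0.2, 0.5, 0.9][:n]
        for perm in itertools.permutations(pool):
            np.testing.assert_allclose(
                bh_adjust(list(perm)), bh_stepup_oracle(perm), atol=1e-12
            )

    def test_monotone_in_p(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


def _matrix_from_stage_means(stage_values, design, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for means in stage_values:
        row = np.repeat(means, design.replicates_per_stage).astype(float)
        rows.append(row + rng.normal(0, noise, row.size))
    df = pd.DataFrame(
        rows, index=[f"g{i}" for i in range(len(rows))], columns=design.sample_ids()
    )
    return ExpressionMatrix(df, design.stage_of_sample())


class TestCallDegs:
    design = StudyDesign(("D12", "D15", "D30"), 3, "D12")

    def test_log2_fold_change_is_stage_mean_difference(self):
        expr = _matrix_from_stage_means([[4.0, 6.0, 4.0]], self.design)
        assert log2_fold_change(expr, "g0", "D15", "D12") == pytest.approx(2.0)
        assert log2_fold_change(expr, "g0", "D12", "D15") == pytest.approx(-2.0)
        assert log2_fold_change(expr, "g0", "D30", "D12") == pytest.approx(0.0)

    def test_separation_limit_calls_exactly_the_planted_genes(self):
        # noiseless limit: planted effects give p=0, flat genes give p=1
        expr = _matrix_from_stage_means(
            [[4, 8, 4], [4, 4, 4], [4, 4, 1]], self.design, noise=0.0, seed=1
        )
        degs = call_degs(expr, "D12")
        called = set(zip(degs.gene_id, degs.later_stage))
        assert called == {("g0", "D15"), ("g2", "D30")}
        directions = dict(zip(zip(degs.gene_id, degs.later_stage), degs.direction))
        assert directions[("g0", "D15")] == "up"
        assert directions[("g2", "D30")] == "down"

    def test_alpha_zero_empty(self):
        expr = _matrix_from_stage_means([[4, 8, 4]], self.design, noise=1e-3)
        assert call_degs(expr, "D12", alpha=0.0).empty

    def test_unknown_baseline_rejected(self):
        expr = _matrix_from_stage_means([[4, 8, 4]], self.design)
        with pytest.raises(ValueError):
            call_degs(expr, "D999")

    def test_five_comparisons_for_six_stages(self):
        expr, _ = generate_expression_matrix(config=SyntheticConfig(seed=4))
        degs = call_degs(expr, "D12")
        assert set(degs.later_stage) == {"D15", "D30", "D60", "D90", "D114"}
        assert (degs.fdr_adjusted_p >= degs.p_value - 1e-15).all()
        assert ((degs.log2_fold_change > 0) == (degs.direction == "up")).all()

    def test_matches_scalar_welch(self):
        expr = _matrix_from_stage_means(
            [[4, 5, 6], [3, 3.2, 2.8]], self.design, noise=0.5, seed=2
        )
        degs = call_degs(expr, "D12", alpha=1.0000001)
        from endonet import welch_t_test

        for _, row in degs.iterrows():
            a = expr.values.loc[row.gene_id, expr.samples_of_stage(row.later_stage)]
            b = expr.values.loc[row.gene_id, expr.samples_of_stage("D12")]
            t, df, p = welch_t_test(a, b)
            assert row.t_statistic == pytest.approx(t, rel=1e-9)
            assert row.welch_df == pytest.approx(df, rel=1e-9)
            assert row.p_value == pytest.approx(p, rel=1e-9)


class TestPartition:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "later_stage", "baseline_stage", "direction"]
        ).assign(log2_fold_change=1.0)

    def test_single_stage_gene_in_its_stage_set(self):
        part = partition_degs(self._records([("gA", "D15", "D12", "up")]))
        assert part.stage_specific[("D15", "up")] == {"gA"}
        assert part.total_unique == 1

    def test_multi_stage_gene_goes_to_shared(self):
        part = partition_degs(
            self._records(
                [("gA", "D60", "D12", "up"), ("gA", "D90", "D12", "up"),
                 ("gB", "D60", "D12", "down")]
            )
        )
        assert part.shared == {"gA"}
        assert all("gA" not in s for s in part.stage_specific.values())
        assert part.stage_specific[("D60", "down")] == {"gB"}
        assert part.total_unique == 2

    def test_disjoint_union_counts(self):
        part = partition_degs(
            self._records(
                [("g1", "D15", "D12", "up"), ("g2", "D30", "D12", "down"),
                 ("g3", "D60", "D12", "up")]
            )
        )
        sets = list(part.stage_specific.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])
        assert part.total_unique == 3
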