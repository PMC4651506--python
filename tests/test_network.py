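"""Adjacency, connectivity, scale-free fit, TOM, modules and hubs."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from endonet import (
    CoexpressionNetwork,
    connectivity,
    detect_modules,
    pearson_adjacency,
    pick_soft_threshold,
    scale_free_fit,
    signed_scaled_connectivity,
    tom,
)
from endonet.network import BACKGROUND


def random_adjacency(n, rng):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=genes, columns=genes)


def tom_oracle(a):
    """Triple-loop topological overlap, written independently."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            omega[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return omega


class TestAdjacency:
    def test_power_law_values(self):
        df = pd.DataFrame(
            [[0.0, 1.0, 2.0, 4.0], [0.0, 2.0, 4.0, 8.0], [1.0, -1.0, 2.0, -3.0]],
            index=list("abc"), columns=list("wxyz"),
        )
        r, a = pearson_adjacency(df, beta=3)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert a.loc["a", "b"] == pytest.approx(1.0)  # |r|=1 -> a=1
        assert np.all(np.diag(a.to_numpy()) == 0.0)

    def test_printed_formula_arithmetic(self):
        # |r^2|^beta at r=0.5, beta=3 -> 0.25^3
        r = np.array([[1.0, 0.5], [0.5, 1.0]])
        from endonet.network import _power_adjacency

        a = _power_adjacency(r.copy(), 3, "r2")
        assert a[0, 1] == pytest.approx(0.015625)
        a_conv = _power_adjacency(r.copy(), 3, "abs")
        assert a_conv[0, 1] == pytest.approx(0.125)

    def test_constant_gene_excluded_with_warning(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [0.0, 1.0, 0.5]],
            index=list("abc"),
        )
        with pytest.warns(UserWarning, match="constant"):
            r, a = pearson_adjacency(df, beta=2)
        assert list(r.index) == ["a", "c"]

    def test_connectivity_brute_force(self):
        rng = np.random.default_rng(0)
        a = random_adjacency(10, rng)
        k = connectivity(a)
        for i, g in enumerate(a.index):
            expected = sum(a.iloc[i, j] for j in range(10) if j != i)
            assert k[g] == pytest.approx(expected, abs=1e-12)

    def test_uncorrelated_and_complete_graph_limits(self):
        n = 5
        a = pd.DataFrame(np.ones((n, n)) - np.eye(n))
        assert (connectivity(a) == n - 1).all()
        assert (connectivity(a * 0.0) == 0.0).all()


class TestScaleFree:
    def test_exact_power_law_recovered(self):
        # counts ~ k^-2 at k = 1, 2, 5, 10 -> log p vs log k exactly linear
        k = np.repeat([1.0, 2.0, 5.0, 10.0], [100, 25, 4, 1])
        r2, slope = scale_free_fit(k, n_bins=10)
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert slope == pytest.approx(-2.0, abs=1e-9)

    def test_uniform_connectivity_degenerate(self):
        with pytest.raises(ValueError, match="bin"):
            scale_free_fit(np.full(50, 3.0))

    def test_scale_free_network_beats_random_graph(self):
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(10):
            k_sf = (1.0 - rng.uniform(size=400)) ** (-1.0 / 1.5)  # Pareto tail
            k_er = rng.binomial(400, 0.05, size=400).astype(float) + 1.0
            r2_sf, _ = scale_free_fit(k_sf)
            r2_er, _ = scale_free_fit(k_er)
            wins += r2_sf > r2_er
        assert wins >= 8

    def test_single_candidate_returned(self, default_dataset):
        expr, _ = default_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pick_soft_threshold(expr.values.iloc[:100], beta_candidates=[4])
        assert fit.chosen_beta == 4.0

    def test_mean_connectivity_decreases_with_beta(self, default_dataset):
        expr, _ = default_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pick_soft_threshold(expr.values)
        assert (np.diff(fit.mean_connectivity) < 0).all()

    def test_some_beta_reaches_target_on_modular_data(self, default_dataset):
        expr, _ = default_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = pick_soft_threshold(expr.values, beta_candidates=range(1, 21))
        assert max(fit.r_squared) >= 0.8


class TestTOM:
    def test_triangle_hand_value(self):
        a = pd.DataFrame(np.ones((3, 3)) - np.eye(3))
        omega = tom(a)
        # (l + a) / (min k + 1 - a) = (1 + 1) / (2 + 1 - 1) = 1
        np.testing.assert_allclose(omega.to_numpy(), 1.0)

    def test_disconnected_pair_is_zero(self):
        a = pd.DataFrame(np.zeros((4, 4)))
        a.iloc[0, 1] = a.iloc[1, 0] = 0.0
        omega = tom(a)
        assert omega.iloc[0, 1] == 0.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = random_adjacency(8, rng)
        np.testing.assert_allclose(
            tom(a).to_numpy(), tom_oracle(a.to_numpy()), atol=1e-12
        )

    def test_symmetry_and_bounds_fuzz(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            a = random_adjacency(int(rng.integers(3, 12)), rng)
            omega = tom(a).to_numpy()
            assert np.allclose(omega, omega.T, atol=1e-12)
            assert omega.min() >= 0.0 and omega.max() <= 1.0
            assert np.all(np.diag(omega) == 1.0)


class TestModules:
    def _block_tom(self):
        # two perfect blocks, zero cross-adjacency
        n = 8
        a = np.zeros((n, n))
        a[:4, :4] = 1.0
        a[4:, 4:] = 1.0
        np.fill_diagonal(a, 0.0)
        genes = [f"g{i}" for i in range(n)]
        return tom(pd.DataFrame(a, index=genes, columns=genes))

    def test_two_separated_blocks(self):
        labels, _ = detect_modules(self._block_tom(), cut_height=0.94,
                                   min_module_size=3)
        assert labels.nunique() == 2
        assert len(set(labels.iloc[:4])) == 1 and len(set(labels.iloc[4:])) == 1

    def test_zero_cut_height_all_background(self):
        with pytest.warns(UserWarning, match="minimum module size"):
            labels, _ = detect_modules(self._block_tom(), cut_height=0.0,
                                       min_module_size=3)
        assert (labels == BACKGROUND).all()

    def test_gene_order_invariance(self, default_dataset):
        expr, _ = default_dataset
        sub = expr.values.iloc[:300]
        _, a = pearson_adjacency(sub, beta=6)
        omega = tom(a)
        labels, _ = detect_modules(omega, min_module_size=10)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(sub))
        omega_p = omega.iloc[perm, perm]
        labels_p, _ = detect_modules(omega_p, min_module_size=10)
        assert adjusted_rand_score(
            labels.loc[omega.index], labels_p.loc[omega.index]
        ) == pytest.approx(1.0)

    def test_planted_module_recovery(self, default_dataset, fitted_network):
        _, truth = default_dataset
        net = fitted_network
        planted = np.array(truth.module_labels(net.modules_.index))
        mask = planted != "background"
        ari = adjusted_rand_score(planted[mask], net.modules_.to_numpy()[mask])
        assert len(net.module_sizes_) == 5
        assert ari >= 0.8


class TestHubs:
    def test_scaled_k_maximum_is_exactly_one(self, fitted_network):
        ht = fitted_network.hub_table_
        for _, grp in ht[ht.module != BACKGROUND].groupby("module"):
            assert grp.scaled_k_positive.max() == 1.0
            assert grp.scaled_k_negative.max() == 1.0
            assert (grp.scaled_k_positive == 1.0).sum() == 1

    def test_planted_hubs_top_ranked(self, default_dataset, fitted_network):
        _, truth = default_dataset
        ht = fitted_network.hub_table_
        for _, grp in ht[ht.module != BACKGROUND].groupby("module"):
            assert grp.scaled_k_positive.idxmax() in truth.hub_flags

    def test_negative_only_gene_has_zero_positive_k(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        df = pd.DataFrame(
            [x, -x + rng.normal(0, 0.01, 12), x + rng.normal(0, 0.01, 12)],
            index=list("abc"),
        )
        r, a = pearson_adjacency(df, beta=2)
        modules = pd.Series(["m1"] * 3, index=list("abc"))
        table = signed_scaled_connectivity(a, r, modules, edge_threshold=0.0)
        assert table.loc["b", "k_positive"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["b", "k_negative"] > 0

    def test_background_genes_never_hubs(self, fitted_network):
        ht = fitted_network.hub_table_
        assert not ht.loc[ht.module == BACKGROUND, "is_hub"].any()
        # hub rule: scaled K > 0.9 and > 10 connected partners
        hubs = ht[ht.is_hub]
        assert (np.maximum(hubs.scaled_k_positive, hubs.scaled_k_negative) > 0.9).all()
        assert (hubs.connected_nodes > 10).all()
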