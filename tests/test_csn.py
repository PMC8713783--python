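import numpy as np
import pytest
from scipy.stats import norm

from loccsn import (
    NeighborhoodState,
    average_network,
    compute_cell_network,
    compute_group_networks,
    find_neighborhood,
    local_test_statistic,
    threshold_adjacency,
)
from loccsn.csn import CellNetworkSet

from conftest import make_expr
from oracle import oracle_neighborhood, oracle_network


def make_state(n_x, n_y, n_xy):
    return NeighborhoodState(
        cell_index=0, gene_x=0, gene_y=1, w_x=1.0, w_y=1.0,
        bin_x=None, bin_y=None, n_x=n_x, n_y=n_y, n_xy=n_xy,
        iterations=1, converged=True,
    )


class TestLocalStatistic:
    def test_hand_computed_value(self):
        # N=10, all three counts 5: rho=0.25, sigma^2=625/90000, z=3 exactly
        ts = local_test_statistic(make_state(5, 5, 5), 10, 1.0, 1.0)
        assert ts.rho == pytest.approx(0.25, abs=0)
        assert ts.sigma**2 == pytest.approx(625 / 90000, rel=1e-15)
        assert ts.z == pytest.approx(3.0, rel=1e-15)

    def test_product_of_marginals_gives_zero(self):
        # n_xy = n_x n_y / N exactly -> rho = 0 -> z = 0
        ts = local_test_statistic(make_state(4, 5, 2), 10, 1.0, 1.0)
        assert ts.rho == 0.0 and ts.z == 0.0

    def test_zero_expression_center_gives_zero(self):
        ts = local_test_statistic(make_state(5, 5, 5), 10, 0.0, 1.0)
        assert ts.z == 0.0
        ts = local_test_statistic(make_state(5, 5, 5), 10, 1.0, 0.0)
        assert ts.z == 0.0

    def test_degenerate_window_gives_zero(self):
        # a marginal window covering all N cells has sigma = 0 -> z = 0
        ts = local_test_statistic(make_state(10, 5, 5), 10, 1.0, 1.0)
        assert ts.sigma == 0.0 and ts.z == 0.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            local_test_statistic(make_state(3, 3, 5), 10, 1.0, 1.0)


class TestFindNeighborhood:
    def test_constant_gene_gives_full_bin(self):
        # identical x for all cells: any width >= 0 admits |diff| = 0
        vals = np.vstack([np.full(12, 3.0), np.linspace(1, 2, 12)])
        nb = find_neighborhood(make_expr(vals), j=5, x=0, y=1)
        assert nb.n_x == 12

    def test_identical_pair_shares_bins(self):
        v = np.linspace(0.5, 3.0, 20)
        nb = find_neighborhood(make_expr(np.vstack([v, v])), j=7, x=0, y=1)
        np.testing.assert_array_equal(nb.bin_x, nb.bin_y)
        assert nb.n_xy == nb.n_x

    def test_center_always_in_own_bins(self, small_positive_expr):
        for j in (0, 11, 29):
            nb = find_neighborhood(small_positive_expr, j, 0, 1)
            assert j in nb.bin_x and j in nb.bin_y
            assert nb.n_xy <= min(nb.n_x, nb.n_y)

    def test_matches_stepwise_oracle(self, rng):
        x = rng.standard_normal(50) + 3
        y = rng.standard_normal(50) + 3
        em = make_expr(np.vstack([x, y]))
        for j in range(0, 50, 7):
            nb = find_neighborhood(em, j, 0, 1, q0=0.1, max_iter=10)
            bx, by, conv = oracle_neighborhood(x, y, j, q0=0.1, max_iter=10)
            assert nb.bin_x.tolist() == bx
            assert nb.bin_y.tolist() == by
            assert nb.converged == conv

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            find_neighborhood(make_expr(np.ones((2, 2))), 0, 0, 1)

    @pytest.mark.parametrize("kwargs", [{"q0": 0.0}, {"q0": 1.5},
                                        {"max_iter": 0}])
    def test_invalid_parameters_rejected(self, small_positive_expr, kwargs):
        with pytest.raises(ValueError):
            find_neighborhood(small_positive_expr, 0, 0, 1, **kwargs)


class TestCellNetwork:
    def test_matches_oracle_entrywise(self, small_positive_expr):
        for j in (0, 13, 29):
            got = compute_cell_network(small_positive_expr, j)
            want = oracle_network(small_positive_expr.values, j)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_zero_center_expression_zeroes_all_pairs(self, rng):
        vals = np.exp(rng.standard_normal((3, 20)))
        vals[1, 4] = 0.0  # cell 4 silent in gene 1
        m = compute_cell_network(make_expr(vals), 4)
        assert not m[1].any() and not m[:, 1].any()

    def test_all_zero_gene_gives_zero_pairs_everywhere(self, rng):
        vals = np.exp(rng.standard_normal((3, 15)))
        vals[2] = 0.0
        em = make_expr(vals)
        for j in range(15):
            m = compute_cell_network(em, j)
            assert not m[2].any() and not m[:, 2].any()

    def test_symmetric_zero_diagonal(self, small_positive_expr):
        m = compute_cell_network(small_positive_expr, 3)
        np.testing.assert_array_equal(m, m.T)
        assert not m.diagonal().any()


class TestGroupNetworks:
    def test_group_isolation(self, rng):
        vals = np.exp(rng.standard_normal((3, 40)))
        labels = ["A"] * 20 + ["B"] * 20
        em = make_expr(vals, cell_type=labels)
        ref = compute_group_networks(em)["A"]
        vals2 = vals.copy()
        vals2[:, 20:] = np.exp(2 * rng.standard_normal((3, 20)) + 1)
        em2 = make_expr(vals2, cell_type=labels)
        np.testing.assert_array_equal(
            compute_group_networks(em2)["A"].z, ref.z
        )

    def test_single_group_equals_per_cell_computation(self, rng):
        vals = np.exp(rng.standard_normal((3, 15)))
        em = make_expr(vals, cell_type=["all"] * 15)
        nets = compute_group_networks(em)["all"]
        for j in (0, 7, 14):
            np.testing.assert_allclose(
                nets.z_matrix(j), compute_cell_network(em, j), atol=0
            )

    def test_duplicating_unrelated_group_changes_nothing(self, rng):
        # metamorphic: N in sigma is the group size, never the total
        vals = np.exp(rng.standard_normal((3, 30)))
        em1 = make_expr(vals[:, :15], cell_type=["A"] * 15)
        both = make_expr(vals, cell_type=["A"] * 15 + ["B"] * 15)
        np.testing.assert_array_equal(
            compute_group_networks(em1)["A"].z,
            compute_group_networks(both)["A"].z,
        )

    def test_tiny_group_skipped_with_warning(self, rng):
        vals = np.exp(rng.standard_normal((2, 12)))
        em = make_expr(vals, cell_type=["A"] * 10 + ["B"] * 2)
        with pytest.warns(UserWarning, match="skipped"):
            nets = compute_group_networks(em)
        assert set(nets) == {"A"}

    def test_pseudotime_bin_grouping(self, rng):
        vals = np.exp(rng.standard_normal((2, 20)))
        bins = np.asarray(["early"] * 10 + ["late"] * 10)
        em = make_expr(vals)
        nets = compute_group_networks(em, group_by="pseudotime_bin",
                                      pseudotime_bins=bins)
        assert set(nets) == {"early", "late"}
        assert nets["early"].n_cells == 10


class TestThresholdAndAverage:
    def make_nets(self, z_rows):
        z = np.asarray(z_rows, dtype=float)
        g = 3
        return CellNetworkSet([f"g{i}" for i in range(g)],
                              [f"c{i}" for i in range(z.shape[0])], z)

    def test_threshold_upper_alpha_quantile(self):
        nets = self.make_nets([[3.0, 1.0, 1.7]])
        adj = threshold_adjacency(nets, alpha=0.05).adjacency
        # cutoff is ~1.6449: z=3 and z=1.7 pass, z=1.0 does not
        np.testing.assert_array_equal(adj, [[1, 0, 1]])

    def test_zero_statistic_never_an_edge(self):
        nets = self.make_nets([[0.0, 0.0, 0.0]])
        for alpha in (0.01, 0.05, 0.4):
            assert not threshold_adjacency(nets, alpha).adjacency.any()

    def test_stricter_alpha_nested(self, rng):
        nets = self.make_nets(rng.standard_normal((20, 3)) * 2)
        e01 = threshold_adjacency(nets, 0.01).adjacency
        e05 = threshold_adjacency(nets, 0.05).adjacency
        assert np.all(e01 <= e05)

    def test_two_sided_mode(self):
        nets = self.make_nets([[-3.0, 3.0, 0.0]])
        one = threshold_adjacency(nets, 0.05).adjacency
        two = threshold_adjacency(nets, 0.05, two_sided=True).adjacency
        np.testing.assert_array_equal(one, [[0, 1, 0]])
        np.testing.assert_array_equal(two, [[1, 1, 0]])

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            threshold_adjacency(self.make_nets([[1.0, 0, 0]]), alpha=1.5)

    def test_average_is_rejection_fraction(self):
        nets = self.make_nets([[3.0, 0, 0], [0.0, 0, 0], [3.0, 0, 0]])
        avg = average_network(threshold_adjacency(nets, 0.05))
        assert avg.matrix[0, 1] == pytest.approx(2 / 3)
        assert avg.matrix[1, 0] == avg.matrix[0, 1]
        assert not avg.matrix.diagonal().any()

    def test_average_invariant_to_cell_order(self, rng):
        z = rng.standard_normal((10, 3)) * 2
        a = average_network(threshold_adjacency(self.make_nets(z), 0.05))
        perm = rng.permutation(10)
        b = average_network(threshold_adjacency(self.make_nets(z[perm]), 0.05))
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_average_requires_adjacency(self):
        with pytest.raises(ValueError):
            average_network(self.make_nets([[1.0, 0, 0]]))


class TestSubsetGenes:
    def test_subset_matches_recomputation(self, rng):
        vals = np.exp(rng.standard_normal((5, 20)))
        em = make_expr(vals, cell_type=["all"] * 20)
        full = compute_group_networks(em)["all"]
        keep = [0, 2, 4]
        sub = full.subset_genes(keep)
        em_sub = make_expr(vals[keep], cell_type=["all"] * 20)
        direct = compute_group_networks(em_sub)["all"]
        np.testing.assert_allclose(sub.z, direct.z, atol=0)
        assert sub.gene_ids == ["g0", "g2", "g4"]
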