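import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp

import _graph_oracle as oracle
from plinet.network import (
    DEFAULT_SPARSITY_GRID,
    WeightedNetwork,
    auc_over_sparsity,
    characteristic_path_length,
    global_efficiency,
    is_connected,
    local_efficiency,
    proportional_threshold,
    sparsity_sweep,
    weighted_clustering,
    weighted_shortest_paths,
)


def net_from(w):
    return WeightedNetwork(weights=np.asarray(w, dtype=float), sparsity=1.0)


TRIANGLE = [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
PATH3 = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]  # A - B - C
STAR4 = [[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]]


class TestProportionalThreshold:
    def test_sparsity_one_keeps_everything(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        assert np.allclose(proportional_threshold(m, 1.0).weights, m)

    def test_keeps_exactly_the_largest(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(size=(4, 4))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        out = proportional_threshold(m, 0.5).weights  # keep round(0.5*6)=3
        iu, ju = np.triu_indices(4, 1)
        kept = out[iu, ju]
        expected = np.sort(m[iu, ju])[-3:]
        assert np.count_nonzero(kept) == 3
        assert set(np.round(kept[kept > 0], 12)) == set(np.round(expected, 12))

    def test_sparsity_15pct_on_60_nodes_keeps_266_edges(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(size=(60, 60))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        out = proportional_threshold(m, 0.15).weights
        assert np.count_nonzero(out[np.triu_indices(60, 1)]) == 266

    def test_ties_break_toward_lower_edge_index(self):
        m = np.ones((4, 4)) - np.eye(4)  # all weights equal
        out = proportional_threshold(m, 0.5).weights
        iu, ju = np.triu_indices(4, 1)
        kept = np.flatnonzero(out[iu, ju] > 0)
        assert list(kept) == [0, 1, 2]  # the three lowest edge indices

    def test_invalid_inputs(self):
        m = np.zeros((3, 3))
        with pytest.raises(ValueError):
            proportional_threshold(m, 0.0)
        with pytest.raises(ValueError):
            proportional_threshold(np.arange(9.0).reshape(3, 3), 0.5)


class TestShortestPaths:
    def test_unit_triangle(self):
        lengths = weighted_shortest_paths(net_from(TRIANGLE))
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(lengths[off], 1.0)

    def test_three_node_path(self):
        lengths = weighted_shortest_paths(net_from(PATH3))
        assert lengths[0, 2] == pytest.approx(2.0)

    def test_disconnected_pairs_are_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        lengths = weighted_shortest_paths(net_from(w))
        assert np.isinf(lengths[0, 2]) and np.isinf(lengths[1, 3])
        assert not is_connected(net_from(w))


class TestMetricHandValues:
    def test_characteristic_path_length(self):
        assert characteristic_path_length(net_from(TRIANGLE)) == pytest.approx(1.0)
        assert characteristic_path_length(net_from(PATH3)) == pytest.approx(4.0 / 3.0)
        half = 0.5 * np.array(TRIANGLE)
        assert characteristic_path_length(net_from(half)) == pytest.approx(2.0)

    def test_clustering(self):
        assert weighted_clustering(net_from(TRIANGLE)) == pytest.approx(1.0)
        assert weighted_clustering(net_from(STAR4)) == 0.0
        tri = [[0, 1, 0.5], [1, 0, 0.5], [0.5, 0.5, 0]]
        assert weighted_clustering(net_from(tri)) == pytest.approx(0.25 ** (1 / 3))

    def test_global_efficiency(self):
        assert global_efficiency(net_from(TRIANGLE)) == pytest.approx(1.0)
        assert global_efficiency(net_from(np.zeros((4, 4)))) == 0.0
        assert global_efficiency(net_from(PATH3)) == pytest.approx(5.0 / 6.0)

    def test_local_efficiency(self):
        assert local_efficiency(net_from(TRIANGLE)) == pytest.approx(1.0)
        assert local_efficiency(net_from(STAR4)) == 0.0


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_all_metrics_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        w = oracle.random_weighted_graph(rng, n)
        net = net_from(w)
        assert characteristic_path_length(net) == pytest.approx(
            oracle.brute_characteristic_path_length(w), abs=1e-10)
        assert weighted_clustering(net) == pytest.approx(
            oracle.brute_clustering(w), abs=1e-10)
        assert global_efficiency(net) == pytest.approx(
            oracle.brute_global_efficiency(w), abs=1e-10)
        assert local_efficiency(net) == pytest.approx(
            oracle.brute_local_efficiency(w), abs=1e-10)


class TestScalingLaws:
    def make_connected(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            w = oracle.random_weighted_graph(rng, 6, density=0.7)
            if is_connected(net_from(w)):
                return w

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_weight_scaling(self, seed):
        w = self.make_connected(seed)
        lam = 2.5
        assert characteristic_path_length(net_from(lam * w)) == pytest.approx(
            characteristic_path_length(net_from(w)) / lam)
        assert global_efficiency(net_from(lam * w)) == pytest.approx(
            lam * global_efficiency(net_from(w)))
        assert weighted_clustering(net_from(lam * w)) == pytest.approx(
            lam * weighted_clustering(net_from(w)))

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_adding_edge_never_lengthens_paths(self, seed):
        w = self.make_connected(seed)
        before = weighted_shortest_paths(net_from(w))
        w2 = w.copy()
        i, j = np.argwhere(w == 0)[0] if (w == 0).any() else (0, 1)
        w2[i, j] = w2[j, i] = max(w2[i, j], 0.5)
        after = weighted_shortest_paths(net_from(w2))
        assert (after <= before + 1e-12).all()

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_global_efficiency_at_least_inverse_path_length(self, seed):
        w = self.make_connected(seed)
        net = net_from(w)
        assert global_efficiency(net) >= 1.0 / characteristic_path_length(net) - 1e-12


class TestSweepAndAuc:
    def test_default_grid_has_16_levels(self):
        rng = np.random.default_rng(12)
        m = rng.uniform(0.1, 1.0, size=(10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        profile = sparsity_sweep(m)
        assert len(profile.grid) == 16
        for metric, values in profile.values.items():
            assert values.shape == (16,)
            assert np.isfinite(values[~profile.disconnected]).all()

    def test_equal_weights_give_constant_clustering(self):
        m = 0.5 * (np.ones((8, 8)) - np.eye(8))
        profile = sparsity_sweep(m, grid=(0.5, 0.75, 1.0))
        # thresholding equal weights keeps k edges; Cw varies only via k,
        # but the surviving weights are all 0.5 so AUC is finite & defined
        assert np.isfinite(profile.values["Cw"]).all()

    def test_auc_constant_identity(self):
        grid = DEFAULT_SPARSITY_GRID
        c = 3.7
        assert auc_over_sparsity(np.full(len(grid), c), grid) == pytest.approx(
            0.15 * c, abs=1e-12)

    def test_auc_linear_ramp(self):
        grid = DEFAULT_SPARSITY_GRID
        ramp = np.linspace(0.0, 1.0, len(grid))
        assert auc_over_sparsity(ramp, grid) == pytest.approx(0.075, abs=1e-12)

    def test_auc_single_trapezoid(self):
        assert auc_over_sparsity([2.0, 4.0], [0.15, 0.16]) == pytest.approx(
            0.01 * 3.0, abs=1e-12)

    def test_auc_needs_two_points(self):
        with pytest.raises(ValueError):
            auc_over_sparsity([1.0], [0.15])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st_hyp.integers(min_value=0, max_value=2**31 - 1),
       st_hyp.floats(min_value=0.05, max_value=1.0))
def test_threshold_edge_count_property(seed, sparsity):
    rng = np.random.default_rng(seed)
    m = rng.uniform(size=(9, 9))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    out = proportional_threshold(m, sparsity)
    n_kept = np.count_nonzero(out.weights[np.triu_indices(9, 1)])
    assert n_kept == int(np.floor(sparsity * 36 + 0.5))
    assert np.allclose(out.weights, out.weights.T)
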