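"""Multiplex embedding dynamics: distances, permutation null, contrasts."""

import numpy as np
import pandas as pd
import pytest

from isnkit.dynamics import (MultiplexNetwork, aggregate_group_networks,
                             contrast_distance_ranks, cosine_distance,
                             embed_and_distance, permutation_significance,
                             repeat_robustness)
from isnkit.lioness import IsnSet


def random_layer(n=15, density=0.3, seed=0):
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    W = np.zeros((n, n))
    W[iu] = rng.random(len(iu[0])) * (rng.random(len(iu[0])) < density)
    W = W + W.T
    nodes = [f"n{k}" for k in range(n)]
    return pd.DataFrame(W, index=nodes, columns=nodes)


def rewired_multiplex(n=20, seed=0, node=0, k_new=4):
    """Layer B equals layer A except node 0's edges are fully re-partnered."""
    A = random_layer(n, seed=seed)
    rng = np.random.default_rng(seed + 1000)
    B = A.copy()
    B.iloc[node, :] = 0.0
    B.iloc[:, node] = 0.0
    targets = rng.choice([i for i in range(n) if i != node and A.iloc[node, i] == 0],
                         size=k_new, replace=False)
    for t in targets:
        w = rng.uniform(0.3, 1.0)
        B.iloc[node, t] = B.iloc[t, node] = w
    nodes = list(A.index)
    return MultiplexNetwork(nodes, A, B)


class TestCosine:
    def test_definition_cases(self):
        assert cosine_distance(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == pytest.approx(0.0)
        assert cosine_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(1.0)
        assert cosine_distance(np.array([1.0, 0.0]), np.array([-1.0, 0.0])) == pytest.approx(2.0)


class TestEmbedding:
    def test_identical_layers_have_small_distances(self):
        A = random_layer(12, seed=1)
        mx = MultiplexNetwork(list(A.index), A, A.copy())
        d = embed_and_distance(mx, dim=3, repeats=10, seed=2)
        # same layer -> only walk-sampling noise separates the two profiles
        assert d.values.mean() < 0.1

    def test_distances_bounded(self):
        mx = rewired_multiplex(seed=3)
        d = embed_and_distance(mx, dim=4, repeats=10, seed=4)
        assert ((d.values >= 0) & (d.values <= 2)).all()

    def test_disjoint_neighbour_sets_give_maximal_distance(self):
        """A node whose (equal-weight) neighbour sets are disjoint between
        layers is the most dynamic node."""
        n = 12
        nodes = [f"n{k}" for k in range(n)]
        base = random_layer(n, density=0.4, seed=5)
        A, B = base.copy(), base.copy()
        A.iloc[0, :] = A.iloc[:, 0] = 0.0
        B.iloc[0, :] = B.iloc[:, 0] = 0.0
        for t in (1, 2):
            A.iloc[0, t] = A.iloc[t, 0] = 1.0
        for t in (3, 4):
            B.iloc[0, t] = B.iloc[t, 0] = 1.0
        mx = MultiplexNetwork(nodes, A, B)
        d = embed_and_distance(mx, dim=4, repeats=20, seed=6)
        assert d.mean(axis=1).idxmax() == "n0"

    def test_scale_invariance(self):
        A = random_layer(10, seed=7)
        B = random_layer(10, seed=8)
        nodes = list(A.index)
        d1 = embed_and_distance(MultiplexNetwork(nodes, A, B), dim=3,
                                repeats=5, seed=9)
        d2 = embed_and_distance(MultiplexNetwork(nodes, 5 * A, 5 * B), dim=3,
                                repeats=5, seed=9)
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-9)

    def test_dim_must_be_below_node_count(self):
        A = random_layer(5, seed=10)
        mx = MultiplexNetwork(list(A.index), A, A)
        with pytest.raises(ValueError, match="dim"):
            embed_and_distance(mx, dim=5)

    def test_negative_weights_rejected(self):
        A = random_layer(6, seed=11)
        B = A.copy()
        B.iloc[0, 1] = B.iloc[1, 0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            MultiplexNetwork(list(A.index), A, B)


class TestPermutation:
    def test_p_values_bounded_below(self):
        mx = rewired_multiplex(seed=12)
        d = embed_and_distance(mx, dim=3, repeats=10, seed=13)
        res = permutation_significance(mx, d, n_perm=100, seed=14, dim=3)
        assert (res.table["p"] >= 1.0 / 101 - 1e-12).all()
        assert (res.table["q"] >= res.table["p"] - 1e-12).all()

    def test_rewired_node_attains_smallest_p(self):
        hits = 0
        for seed in range(5):
            mx = rewired_multiplex(seed=20 + seed)
            d = embed_and_distance(mx, dim=3, repeats=15, seed=seed)
            res = permutation_significance(mx, d, n_perm=100, seed=seed, dim=3)
            hits += res.table.loc["n0", "p"] == res.table["p"].min()
        assert hits >= 4

    def test_identical_layers_not_significant(self):
        any_sig = 0
        for seed in range(5):
            A = random_layer(12, seed=30 + seed)
            mx = MultiplexNetwork(list(A.index), A, A.copy())
            d = embed_and_distance(mx, dim=3, repeats=10, seed=seed)
            res = permutation_significance(mx, d, n_perm=100, seed=seed, dim=3)
            any_sig += res.table["significant"].any()
        assert any_sig == 0

    def test_too_few_permutations_rejected(self):
        mx = rewired_multiplex(seed=40)
        d = embed_and_distance(mx, dim=3, repeats=5, seed=41)
        with pytest.raises(ValueError, match="10 permutations"):
            permutation_significance(mx, d, n_perm=5)


class TestContrast:
    def _result(self, mx, seed):
        d = embed_and_distance(mx, dim=3, repeats=8, seed=seed)
        return permutation_significance(mx, d, n_perm=20, seed=seed, dim=3)

    def test_identical_results_degenerate_ranking(self):
        mx = rewired_multiplex(seed=50)
        r = self._result(mx, 51)
        out = contrast_distance_ranks(r, r)
        assert (out["abs_difference"] == 0).all()
        assert list(out.index) == sorted(out.index)

    def test_symmetry_and_planted_contrast(self):
        mx_changed = rewired_multiplex(seed=60)
        A = mx_changed.layer_a
        mx_null = MultiplexNetwork(list(A.index), A, A.copy())
        ra, rb = self._result(mx_changed, 61), self._result(mx_null, 62)
        ab = contrast_distance_ranks(ra, rb)
        ba = contrast_distance_ranks(rb, ra)
        assert ab.index[0] == "n0"
        pd.testing.assert_series_equal(ab["abs_difference"], ba["abs_difference"])

    def test_disjoint_node_sets_rejected(self):
        mx = rewired_multiplex(seed=70)
        r = self._result(mx, 71)
        r2 = self._result(mx, 72)
        r2.table.index = [f"x{k}" for k in range(len(r2.table))]
        with pytest.raises(ValueError, match="node set"):
            contrast_distance_ranks(r, r2)


class TestAggregation:
    def _isns(self):
        taxa = ["tA", "tB", "tC"]
        edge_index = [("tA", "tB"), ("tA", "tC"), ("tB", "tC")]
        idx = pd.Index([f"i{k}_{tp}" for tp in ("w0", "w24") for k in range(3)],
                       name="sample")
        w = pd.DataFrame(
            [[-0.2, 0.1, 0.3], [0.2, 0.1, 0.3], [0.0, 0.1, 0.3],
             [0.5, 0.0, 0.3], [0.5, 0.0, 0.3], [0.5, 0.0, 0.3]],
            index=idx, columns=["tA|tB", "tA|tC", "tB|tC"])
        isns = IsnSet(edge_index, w)
        meta = pd.DataFrame({
            "trajectory": ["Bact2-Bact2"] * 6,
            "timepoint": ["w0"] * 3 + ["w24"] * 3,
            "individual_id": [f"i{k}" for k in range(3)] * 2,
        }, index=idx)
        return isns, meta, taxa

    def test_cancellation_then_absolute_value(self):
        isns, meta, taxa = self._isns()
        mx = aggregate_group_networks(isns, meta, "Bact2-Bact2", taxa)
        assert mx.layer_a.loc["tA", "tB"] == pytest.approx(0.0)  # (-0.2+0.2+0)/3
        assert mx.layer_a.loc["tA", "tC"] == pytest.approx(0.1)
        assert mx.layer_b.loc["tA", "tB"] == pytest.approx(0.5)
        assert (mx.layer_a.values >= 0).all() and (mx.layer_b.values >= 0).all()

    def test_identical_isns_give_identical_layers(self):
        isns, meta, taxa = self._isns()
        isns.weights.iloc[3:] = isns.weights.iloc[:3].values
        mx = aggregate_group_networks(isns, meta, "Bact2-Bact2", taxa)
        np.testing.assert_allclose(mx.layer_a.values, mx.layer_b.values)

    def test_min_individuals_enforced(self):
        isns, meta, taxa = self._isns()
        with pytest.raises(ValueError, match="individuals"):
            aggregate_group_networks(isns, meta, "Bact2-Bact2", taxa,
                                     min_individuals=5)
        with pytest.raises(ValueError, match="no samples"):
            aggregate_group_networks(isns, meta, "Other-Other", taxa)


def test_repeat_robustness_on_planted_change():
    """Two independent 50-repeat runs rank the nodes consistently."""
    mx = rewired_multiplex(seed=80)
    rho = repeat_robustness(mx, repeats=50, seed_a=1, seed_b=2, dim=3)
    assert rho >= 0.9
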