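import numpy as np
import pytest

from oracles import brute_clustering, brute_path_length

from covnet import (ValidationError, clustering_coefficient, make_null,
                    normalized_topology, path_length)


def _random_graph(rng, n, p=0.5):
    W = np.triu(rng.random((n, n)) * (rng.random((n, n)) < p), 1)
    return W + W.T


def test_clustering_hand_values():
    tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float)
    assert np.allclose(clustering_coefficient(tri), 1.0)
    star = np.zeros((4, 4))
    star[0, 1:] = star[1:, 0] = 1.0
    assert np.allclose(clustering_coefficient(star), 0.0)
    wtri = np.array([[0, 1, 1], [1, 0, 0.125], [1, 0.125, 0]], float)
    C = clustering_coefficient(wtri)
    # node opposite the light edge: (1 * 1 * 0.125)^(1/3) = 0.5
    assert C[0] == pytest.approx(0.5)
    with pytest.raises(ValidationError, match="negative"):
        clustering_coefficient(-tri)


def test_path_length_hand_values():
    path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
    L = path_length(path)
    assert np.allclose(L, [1.5, 1.0, 1.5])
    assert np.nanmean(L) == pytest.approx(4.0 / 3.0)
    # single edge of weight 0.5 -> distance 2; isolated node flagged NaN
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    L = path_length(W)
    assert L[0] == pytest.approx(2.0) and np.isnan(L[2])


def test_oracle_equivalence_small_graphs():
    """Clustering and path length match brute-force oracles to 1e-10."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = rng.integers(4, 9)
        W = _random_graph(rng, int(n))
        assert np.allclose(clustering_coefficient(W), brute_clustering(W),
                           atol=1e-10)
        L = path_length(W)
        Lb = brute_path_length(W)
        ok = np.isfinite(Lb)
        assert np.array_equal(np.isfinite(L), ok)
        assert np.allclose(L[ok], Lb[ok], atol=1e-10)


def test_networkx_cross_check():
    """Independent library check of the Onnela clustering formulation."""
    import networkx as nx
    rng = np.random.default_rng(3)
    W = _random_graph(rng, 12, p=0.4)
    G = nx.from_numpy_array(W)
    ours = clustering_coefficient(W)
    theirs = np.array([nx.clustering(G, weight="weight")[i] for i in range(12)])
    assert np.allclose(ours, theirs, atol=1e-12)


def test_null_preserves_degrees_and_weights():
    rng = np.random.default_rng(21)
    W = _random_graph(rng, 20, p=0.2)
    deg = (W > 0).sum(axis=1)
    weights = np.sort(W[np.triu_indices(20, 1)][W[np.triu_indices(20, 1)] > 0])
    overlaps = []
    for s in range(50):
        Wn = make_null(W, rng)
        assert np.array_equal((Wn > 0).sum(axis=1), deg)
        wn = np.sort(Wn[np.triu_indices(20, 1)][Wn[np.triu_indices(20, 1)] > 0])
        assert np.allclose(wn, weights)
        overlaps.append(np.count_nonzero((W > 0) & (Wn > 0)) /
                        np.count_nonzero(W > 0))
    # rewiring must actually move edges
    assert np.mean(overlaps) < 0.7


def test_complete_graph_null_is_weight_shuffle():
    rng = np.random.default_rng(2)
    n = 5
    W = np.triu(rng.random((n, n)), 1)
    W = W + W.T
    Wn = make_null(W, rng)
    assert np.array_equal((Wn > 0).sum(axis=1), (W > 0).sum(axis=1))
    assert np.allclose(np.sort(Wn[np.triu_indices(n, 1)]),
                       np.sort(W[np.triu_indices(n, 1)]))


def test_normalization_identity_and_sigma_consistency():
    rng = np.random.default_rng(4)
    W = _random_graph(rng, 15, p=0.3)
    topo = normalized_topology(W, n_nulls=20, rng=5, density=0.3)
    # sigma = C_norm / L_norm bit-for-bit
    with np.errstate(invalid="ignore"):
        assert np.array_equal(
            np.nan_to_num(topo.small_world, nan=-1),
            np.nan_to_num(topo.clustering_norm / topo.path_length_norm, nan=-1))
    # a network normalized against itself gives ratios of exactly 1
    C = topo.clustering
    assert np.allclose(C[C > 0] / C[C > 0], 1.0)


def test_lattice_vs_random_normalization_signs():
    """A ring lattice is more clustered and longer-pathed than its rewirings."""
    n = 20
    W = np.zeros((n, n))
    for i in range(n):
        for d in (1, 2):
            j = (i + d) % n
            W[i, j] = W[j, i] = 1.0
    topo = normalized_topology(W, n_nulls=50, rng=7)
    assert topo.global_clustering_norm > 1.0
    assert topo.global_path_length_norm > 1.0
    # an Erdos-Renyi-like graph sits inside its own null ensemble
    rng = np.random.default_rng(8)
    We = _random_graph(rng, 20, p=0.25)
    te = normalized_topology(We, n_nulls=50, rng=9)
    assert 0.8 < te.global_path_length_norm < 1.2
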