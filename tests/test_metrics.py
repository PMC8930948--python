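"""Graph-metric suite: printed-formula examples, limits, and brute-force oracles."""

import numpy as np
import pytest

import oracles
from conftest import cycle_network, make_network, random_network, raster_from_rows
from effconn import (
    DegenerateNetworkWarning,
    SpikeRaster,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    complete_network,
    compute_all,
    connection_strength,
    connectivity_degree,
    firing_rate,
    global_efficiency,
    louvain_modules,
    modularity_degree,
    module_statistics,
    network_strength,
    shortest_paths,
    synchrony_kappa,
    vulnerability,
)
from effconn.random_reference import RandomReferenceConfig, generate_random_networks


def random_raster(n, frames, p, rng):
    return SpikeRaster((rng.random((n, frames)) < p).astype(int))


# ---------------------------------------------------------------------------
# firing rate and synchrony


def test_firing_rate_arithmetic():
    spikes = np.zeros((2, 16398), dtype=int)  # 600 s at 27.33 fps
    spikes[0, :120] = 1
    r = SpikeRaster(spikes, duration_s=600.0)
    per_cell, mean = firing_rate(r)
    assert per_cell[0] == pytest.approx(0.2)
    assert per_cell[1] == 0.0
    assert mean == pytest.approx(0.1)


def test_firing_rate_single_spike_one_second():
    spikes = np.zeros((1, 27), dtype=int)
    spikes[0, 13] = 1
    assert firing_rate(SpikeRaster(spikes, frame_rate=27.0))[1] == pytest.approx(1.0)


def test_kappa_identical_trains_is_one():
    row = [0, 1, 0, 1, 1, 0, 0, 1]
    assert synchrony_kappa(raster_from_rows([row, row])) == pytest.approx(1.0)


def test_kappa_hand_example_disjoint_single_spikes():
    # T=4; A spikes only frame 1, B only frame 2: p_o=0.5, p_e=0.625, kappa=-1/3
    r = raster_from_rows([[0, 1, 0, 0], [0, 0, 1, 0]])
    assert synchrony_kappa(r) == pytest.approx(-1.0 / 3.0)


def test_kappa_silent_pair_contributes_zero():
    r = raster_from_rows([[0, 0, 0, 0], [0, 0, 0, 0]])
    assert synchrony_kappa(r) == 0.0


def test_kappa_matches_bruteforce_on_random_rasters(rng):
    for _ in range(5):
        r = random_raster(6, 50, 0.2, rng)
        assert synchrony_kappa(r) == pytest.approx(oracles.bf_kappa(r.spikes))


def test_kappa_bounded(rng):
    for _ in range(10):
        r = random_raster(5, 30, 0.3, rng)
        assert -1.0 <= synchrony_kappa(r) <= 1.0


# ---------------------------------------------------------------------------
# connection strength


def test_connection_strength_perfect_follow():
    r = raster_from_rows([[1, 0, 1, 0, 1, 0, 1, 0], [0, 1, 0, 1, 0, 1, 0, 1]])
    assert connection_strength(r, 0, 1) == pytest.approx(1.0)


def test_connection_strength_half():
    # source spikes 4 times; target follows exactly twice
    r = raster_from_rows([[1, 0, 1, 0, 1, 0, 1, 0, 0], [0, 1, 0, 0, 0, 1, 0, 0, 0]])
    assert connection_strength(r, 0, 1) == pytest.approx(0.5)


def test_connection_strength_silent_source_warns_zero():
    r = raster_from_rows([[0, 0, 0, 0], [0, 1, 0, 1]])
    with pytest.warns(DegenerateNetworkWarning):
        assert connection_strength(r, 0, 1) == 0.0


# ---------------------------------------------------------------------------
# degree, distances, path lengths, efficiency


def test_connectivity_degree_complete_and_empty():
    assert connectivity_degree(complete_network(6)) == pytest.approx(1.0)
    empty = make_network(np.zeros((4, 4), dtype=int))
    assert connectivity_degree(empty) == 0.0


def test_connectivity_degree_study_average():
    nets = generate_random_networks(RandomReferenceConfig(n_networks=1, seed=5))
    assert nets[0].n_cells == 153 and nets[0].n_edges == 5814
    assert connectivity_degree(nets[0]) == pytest.approx(0.25)


def test_shortest_paths_cycle_and_directionality():
    d = shortest_paths(cycle_network(3)).d_binary
    off = d[~np.eye(3, dtype=bool)]
    assert sorted(set(off)) == [1.0, 2.0]
    # two-node chain: reverse direction unreachable
    chain = make_network([[0, 1], [0, 0]])
    d2 = shortest_paths(chain).d_binary
    assert d2[0, 1] == 1.0 and np.isinf(d2[1, 0])


def test_cpl_complete_graph_is_one(complete5):
    dist = shortest_paths(complete5)
    assert characteristic_path_length(dist, "binary") == pytest.approx(1.0)


def test_cpl_cycle():
    dist = shortest_paths(cycle_network(3))
    assert characteristic_path_length(dist, "binary") == pytest.approx(1.5)


def test_cpl_weighted_uniform_half_weights():
    net = complete_network(4, weight=0.5)
    dist = shortest_paths(net)
    assert characteristic_path_length(dist, "weighted") == pytest.approx(2.0)


def test_efficiency_complete_unit_weights(complete5):
    assert global_efficiency(shortest_paths(complete5)) == pytest.approx(1.0)


def test_efficiency_empty_graph():
    empty = make_network(np.zeros((4, 4), dtype=int))
    assert global_efficiency(shortest_paths(empty)) == 0.0


def test_efficiency_three_node_mixed_weights_vs_bruteforce():
    w = np.array([[0.0, 0.8, 0.2], [0.0, 0.0, 0.5], [0.4, 0.0, 0.0]])
    net = make_network((w > 0).astype(int), w)
    expected = oracles.bf_efficiency(oracles.bf_weighted_distances(w))
    assert global_efficiency(shortest_paths(net)) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# clustering


def test_clustering_complete_graph(complete5):
    assert clustering_coefficient(complete5, "binary") == pytest.approx(1.0)


def test_clustering_directed_three_cycle():
    assert clustering_coefficient(cycle_network(3), "binary") == pytest.approx(0.5)


def test_clustering_weighted_reduces_to_binary_at_unit_weights(rng):
    net = random_network(8, 0.4, rng, weighted=False)
    assert clustering_coefficient(net, "weighted") == pytest.approx(
        clustering_coefficient(net, "binary")
    )


# ---------------------------------------------------------------------------
# modularity and community detection


def two_blocks(k=3):
    n = 2 * k
    a = np.zeros((n, n), dtype=int)
    a[:k, :k] = 1
    a[k:, k:] = 1
    np.fill_diagonal(a, 0)
    return make_network(a)


def test_modularity_single_module_is_zero(rng):
    net = random_network(7, 0.4, rng)
    assert modularity_degree(net, np.zeros(7, dtype=int)) == pytest.approx(0.0)


def test_modularity_two_complete_components_is_half():
    net = two_blocks(3)
    labels = np.array([1, 1, 1, 2, 2, 2])
    assert modularity_degree(net, labels) == pytest.approx(0.5)


def test_louvain_recovers_disconnected_blocks():
    net = two_blocks(4)
    labels, q = louvain_modules(net, n_restarts=10, seed=0)
    assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
    assert labels[0] != labels[4]
    assert q == pytest.approx(0.5)


def test_louvain_recovers_planted_partition(rng):
    from sklearn.metrics import adjusted_rand_score

    n, k = 60, 3
    planted = np.repeat(np.arange(k), n // k)
    p = np.where(planted[:, None] == planted[None, :], 0.9, 0.02)
    a = (rng.random((n, n)) < p).astype(int)
    np.fill_diagonal(a, 0)
    labels, _ = louvain_modules(make_network(a), n_restarts=10, seed=0)
    assert adjusted_rand_score(planted, labels) > 0.9


def test_louvain_q_self_consistent(rng):
    net = random_network(12, 0.3, rng)
    labels, q = louvain_modules(net, n_restarts=5, seed=3)
    assert q == pytest.approx(modularity_degree(net, labels))
    assert q >= 0.0  # never below the single-module baseline


def test_louvain_matches_exhaustive_partition_search(rng):
    for _ in range(8):
        n = int(rng.integers(5, 9))
        net = random_network(n, 0.35, rng)
        if net.n_edges == 0:
            continue
        _, q_best = oracles.bf_best_partition(net.adjacency)
        _, q_louvain = louvain_modules(net, n_restarts=40, seed=7)
        assert q_louvain == pytest.approx(q_best, abs=1e-9)


def test_louvain_edgeless_raises():
    with pytest.raises(ValueError):
        louvain_modules(make_network(np.zeros((3, 3), dtype=int)))


# ---------------------------------------------------------------------------
# betweenness and vulnerability


def test_betweenness_complete_graph_zero(complete5):
    per_node, mean = betweenness_centrality(complete5)
    assert np.allclose(per_node, 0.0) and mean == 0.0


def test_betweenness_three_node_path():
    net = make_network([[0, 1, 0], [0, 0, 1], [0, 0, 0]])
    per_node, _ = betweenness_centrality(net)
    assert per_node[1] == pytest.approx(0.5)
    assert per_node[0] == per_node[2] == 0.0


def test_betweenness_matches_path_enumeration(rng):
    for _ in range(10):
        net = random_network(7, 0.3, rng)
        per_node, _ = betweenness_centrality(net)
        assert np.allclose(per_node, oracles.bf_betweenness(net.adjacency), atol=1e-12)


def test_vulnerability_complete_graph_zero(complete5):
    per_node, mean = vulnerability(complete5)
    assert np.allclose(per_node, 0.0, atol=1e-12) and mean == pytest.approx(0.0)


def test_vulnerability_star_hub_is_one():
    n = 5
    a = np.zeros((n, n), dtype=int)
    a[0, 1:] = 1
    per_node, _ = vulnerability(make_network(a))
    assert per_node[0] == pytest.approx(1.0)


def test_vulnerability_matches_bruteforce(rng):
    for _ in range(5):
        net = random_network(6, 0.5, rng, weighted=True)
        if global_efficiency(shortest_paths(net)) == 0:
            continue
        per_node, _ = vulnerability(net)
        assert np.allclose(per_node, oracles.bf_vulnerability(net.weights), atol=1e-9)


def test_vulnerability_zero_efficiency_raises():
    with pytest.raises(ValueError):
        vulnerability(make_network(np.zeros((3, 3), dtype=int)))


# ---------------------------------------------------------------------------
# network strength and module statistics


def test_network_strength_uniform_and_mixed():
    assert network_strength(complete_network(4, weight=0.41)) == pytest.approx(0.41)
    a = np.array([[0, 1], [1, 0]])
    w = np.array([[0.0, 0.2], [0.6, 0.0]])
    assert network_strength(make_network(a, w)) == pytest.approx(0.4)


def test_network_strength_empty_warns_zero():
    with pytest.warns(DegenerateNetworkWarning):
        assert network_strength(make_network(np.zeros((3, 3), dtype=int))) == 0.0


def test_module_statistics_two_planted_modules():
    net = two_blocks(5)
    labels = np.array([1] * 5 + [2] * 5)
    stats = module_statistics(net, labels)
    assert stats.n_modules == 2
    assert sorted(stats.sizes.tolist()) == [5, 5]


def test_module_statistics_two_cell_reciprocal_module():
    a = np.array([[0, 1], [1, 0]])
    stats = module_statistics(make_network(a), np.array([1, 1]))
    assert stats.within_in_degree[0] == pytest.approx(1.0)
    assert stats.within_out_degree[0] == pytest.approx(1.0)


def test_module_statistics_uniform_rate_matches_network_mean(rng):
    net = two_blocks(10)
    labels = np.array([1] * 10 + [2] * 10)
    r = random_raster(20, 4000, 0.01, rng)
    stats = module_statistics(net, labels, raster=r)
    network_mean = firing_rate(r)[1]
    assert np.allclose(stats.firing_rate, network_mean, rtol=0.25)


# ---------------------------------------------------------------------------
# exhaustive / randomized oracle equivalence


def all_three_node_digraphs():
    nets = []
    for code in range(2**6):
        a = np.zeros((3, 3), dtype=int)
        bits = [(code >> b) & 1 for b in range(6)]
        a[np.nonzero(~np.eye(3, dtype=bool))] = bits
        nets.append(a)
    return nets


def test_oracle_equivalence_exhaustive_three_node():
    for a in all_three_node_digraphs():
        net = make_network(a)
        dist = shortest_paths(net)
        d_oracle = oracles.bf_binary_distances(a)
        assert np.allclose(dist.d_binary, d_oracle, equal_nan=True)
        if np.isfinite(oracles.bf_cpl(d_oracle)):
            assert characteristic_path_length(dist, "binary") == pytest.approx(
                oracles.bf_cpl(d_oracle)
            )
        assert global_efficiency(dist) == pytest.approx(
            oracles.bf_efficiency(oracles.bf_weighted_distances(a.astype(float)))
        )
        assert clustering_coefficient(net, "binary") == pytest.approx(oracles.bf_clustering(a))
        assert np.allclose(betweenness_centrality(net)[0], oracles.bf_betweenness(a))


@pytest.mark.parametrize("n", [4, 5, 6])
def test_oracle_equivalence_random_binary_digraphs(n, rng):
    for _ in range(30):
        net = random_network(n, 0.4, rng)
        a = net.adjacency
        dist = shortest_paths(net)
        d_oracle = oracles.bf_binary_distances(a)
        assert np.allclose(dist.d_binary, d_oracle, equal_nan=True)
        if np.isfinite(oracles.bf_cpl(d_oracle)):
            assert characteristic_path_length(dist, "binary") == pytest.approx(
                oracles.bf_cpl(d_oracle)
            )
        assert clustering_coefficient(net, "binary") == pytest.approx(oracles.bf_clustering(a))
        assert np.allclose(betweenness_centrality(net)[0], oracles.bf_betweenness(a))
        if net.n_edges:
            labels = (rng.random(n) < 0.5).astype(int)
            assert modularity_degree(net, labels) == pytest.approx(
                oracles.bf_modularity(a, labels)
            )


def test_oracle_equivalence_random_weighted_seven_node(rng):
    for _ in range(100):
        net = random_network(7, 0.35, rng, weighted=True)
        w = net.weights
        dist = shortest_paths(net)
        dw_oracle = oracles.bf_weighted_distances(w)
        assert np.allclose(dist.d_weighted, dw_oracle, equal_nan=True)
        assert global_efficiency(dist) == pytest.approx(oracles.bf_efficiency(dw_oracle))
        assert clustering_coefficient(net, "weighted") == pytest.approx(
            oracles.bf_clustering(net.adjacency, w)
        )
        if np.isfinite(oracles.bf_cpl(dw_oracle)):
            assert characteristic_path_length(dist, "weighted") == pytest.approx(
                oracles.bf_cpl(dw_oracle)
            )


def test_modularity_matches_networkx(rng):
    import networkx as nx

    for _ in range(10):
        net = random_network(8, 0.35, rng)
        if net.n_edges == 0:
            continue
        labels, q = louvain_modules(net, n_restarts=10, seed=1)
        g = nx.DiGraph(np.asarray(net.adjacency))
        communities = [set(np.nonzero(labels == m)[0]) for m in np.unique(labels)]
        assert q == pytest.approx(nx.community.modularity(g, communities))


# ---------------------------------------------------------------------------
# invariants


def test_limit_agreement_complete_unit_weight_graph():
    net = complete_network(8)
    dist = shortest_paths(net)
    assert characteristic_path_length(dist, "binary") == pytest.approx(1.0)
    assert characteristic_path_length(dist, "weighted") == pytest.approx(1.0)
    assert global_efficiency(dist) == pytest.approx(1.0)
    assert clustering_coefficient(net) == pytest.approx(1.0)
    assert np.allclose(betweenness_centrality(net)[0], 0.0)
    assert np.allclose(vulnerability(net)[0], 0.0, atol=1e-12)


def test_metric_ranges(rng):
    for _ in range(10):
        net = random_network(9, 0.4, rng, weighted=True)
        assert 0.0 <= connectivity_degree(net) <= 1.0
        assert 0.0 <= clustering_coefficient(net, "binary") <= 1.0
        b, _ = betweenness_centrality(net)
        assert ((b >= 0) & (b <= 1)).all()
        if net.n_edges:
            labels, q = louvain_modules(net, n_restarts=5, seed=0)
            assert q <= 1.0 and q >= 0.0


def test_adding_edge_monotonicity_on_strongly_connected(rng):
    # on graphs where all pairs stay reachable, a new edge cannot lengthen
    # any shortest path, so L never increases and E^w never decreases
    base = cycle_network(6)
    a = base.adjacency.copy()
    dist0 = shortest_paths(base)
    l0 = characteristic_path_length(dist0, "binary")
    e0 = global_efficiency(dist0)
    zeros = np.argwhere((a == 0) & ~np.eye(6, dtype=bool))
    i, j = zeros[rng.integers(len(zeros))]
    a[i, j] = 1
    dist1 = shortest_paths(make_network(a))
    assert characteristic_path_length(dist1, "binary") <= l0 + 1e-12
    assert global_efficiency(dist1) >= e0 - 1e-12


# ---------------------------------------------------------------------------
# aggregation


def test_compute_all_on_random_reference_networks():
    nets = generate_random_networks(
        RandomReferenceConfig(n_networks=2, n_cells=40, n_edges=round(0.25 * 40 * 39), seed=2)
    )
    for net in nets:
        m = compute_all(net, louvain_restarts=5, seed=0)
        assert m.connectivity_degree == pytest.approx(0.25)
        assert np.isnan(m.firing_rate_mean)  # no raster supplied
        assert np.isfinite(m.global_efficiency)


def test_compute_all_deterministic(rng):
    net = random_network(15, 0.3, rng, weighted=True)
    spikes = (np.random.default_rng(0).random((15, 200)) < 0.05).astype(int)
    r = SpikeRaster(spikes)
    m1 = compute_all(net, r, louvain_restarts=5, seed=11)
    m2 = compute_all(net, r, louvain_restarts=5, seed=11)
    assert m1.to_dict() == m2.to_dict()
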