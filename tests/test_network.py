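import numpy as np
import pytest

from netnegsel.network import (
    NetworkDataError,
    RawNetwork,
    connected_components,
    load_string_edges,
    network_stats,
    shortest_paths,
    symmetric_normalize,
)

from _oracles import enumerate_shortest, random_connected_graph
from conftest import make_net


def write_edges(tmp_path, text, name="edges.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadStringEdges:
    def test_threshold_scaling_and_isolation(self, tmp_path):
        p = write_edges(
            tmp_path,
            "protein1 protein2 combined_score\n"
            "p1 p2 850\n"
            "p1 p3 699\n"
            "p2 p3 700\n",
        )
        raw = load_string_edges(p, threshold=700)
        assert raw.node_labels == ["p1", "p2", "p3"]
        i = {l: k for k, l in enumerate(raw.node_labels)}
        assert raw.weights[i["p1"], i["p2"]] == pytest.approx(0.85)
        assert raw.weights[i["p1"], i["p3"]] == 0.0  # below threshold
        assert raw.weights[i["p2"], i["p3"]] == pytest.approx(0.70)

    def test_node_isolated_by_threshold_removed(self, tmp_path):
        p = write_edges(tmp_path, "p1 p2 850\np1 p4 699\n")
        raw = load_string_edges(p, threshold=700)
        assert raw.node_labels == ["p1", "p2"]

    def test_empty_file(self, tmp_path):
        raw = load_string_edges(write_edges(tmp_path, ""), threshold=700)
        assert raw.n_nodes == 0

    def test_duplicate_orientations_collapse(self, tmp_path):
        p = write_edges(tmp_path, "p1 p2 850\np2 p1 850\n")
        raw = load_string_edges(p)
        assert raw.n_nodes == 2

    def test_conflicting_scores_error(self, tmp_path):
        p = write_edges(tmp_path, "p1 p2 850\np2 p1 900\n")
        with pytest.raises(NetworkDataError, match="conflicting"):
            load_string_edges(p)

    def test_self_loop_dropped(self, tmp_path):
        raw = load_string_edges(write_edges(tmp_path, "p1 p1 900\np1 p2 800\n"))
        assert np.all(np.diag(raw.weights) == 0)

    def test_malformed_row_reports_line(self, tmp_path):
        with pytest.raises(NetworkDataError, match="line 2"):
            load_string_edges(write_edges(tmp_path, "p1 p2 850\np1 p3\n"))

    def test_gzip_transparent(self, tmp_path):
        import gzip

        p = tmp_path / "edges.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("p1\tp2\t850\n")
        assert load_string_edges(p).n_nodes == 2

    def test_bad_threshold(self, tmp_path):
        with pytest.raises(ValueError):
            load_string_edges(write_edges(tmp_path, "p1 p2 850\n"), threshold=0)


class TestSymmetricNormalize:
    def test_two_node_hand_example(self):
        raw = RawNetwork(["a", "b"], np.array([[0, 0.5], [0.5, 0]]))
        net = symmetric_normalize(raw)
        assert net.w[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("w", [0.1, 0.5, 0.999])
    def test_equal_triangle_is_half(self, w):
        m = np.full((3, 3), w)
        np.fill_diagonal(m, 0)
        net = symmetric_normalize(RawNetwork(list("abc"), m))
        off = net.w[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5)

    def test_unit_row_sum_identity(self):
        m = np.array([[0, 1.0], [1.0, 0]])
        net = symmetric_normalize(RawNetwork(["a", "b"], m))
        assert np.allclose(net.w, m)

    def test_symmetry_range_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 21))
            w = random_connected_graph(rng, n, p=0.6)
            net = symmetric_normalize(RawNetwork([str(i) for i in range(n)], w))
            assert np.max(np.abs(net.w - net.w.T)) == 0.0
            assert net.w.min() >= 0 and net.w.max() <= 1 + 1e-12
            c = float(rng.uniform(0.1, 50))
            scaled = symmetric_normalize(RawNetwork([str(i) for i in range(n)], c * w))
            assert np.allclose(scaled.w, net.w, atol=1e-12)

    def test_isolated_node_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.5
        with pytest.raises(NetworkDataError, match="isolated"):
            symmetric_normalize(RawNetwork(list("abc"), m))


class TestComponentsAndPaths:
    def test_path_one_component(self, path_abc):
        comps = connected_components(path_abc)
        assert comps.n_components == 1
        assert set(comps.members[0]) == {0, 1, 2}

    def test_two_pairs_two_components(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        assert connected_components(make_net(w)).n_components == 2

    def test_path_costs_and_counts(self, path_abc):
        cache = shortest_paths(path_abc)
        assert cache.dist[0, 2] == pytest.approx(1.0)
        assert cache.sigma[0, 2] == 1
        assert cache.sigma_through(1)[0, 2] == 1
        assert np.all(np.diag(cache.dist) == 0)

    def test_square_tie_counting(self):
        w = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[a, b] = w[b, a] = 0.5
        cache = shortest_paths(make_net(w))
        assert cache.sigma[0, 2] == 2
        assert cache.sigma_through(1)[0, 2] == 1
        assert cache.sigma_through(3)[0, 2] == 1

    @pytest.mark.parametrize("mode", ["weight_as_cost", "inverse_weight", "hop"])
    def test_oracle_agreement_random_graphs(self, mode):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            w = random_connected_graph(rng, n, p=0.55)
            cache = shortest_paths(make_net(w), cost_mode=mode)
            dist, sigma, through = enumerate_shortest(w, mode)
            assert np.allclose(cache.dist, dist, atol=1e-9)
            assert np.allclose(cache.sigma, sigma)
            for i in range(n):
                assert np.allclose(cache.sigma_through(i), through[i])

    def test_unknown_cost_mode(self, path_abc):
        with pytest.raises(ValueError, match="cost_mode"):
            shortest_paths(path_abc, cost_mode="nope")

    def test_one_minus_weight_rejects_unit_edges(self, star4):
        with pytest.raises(NetworkDataError):
            shortest_paths(star4, cost_mode="one_minus_weight")


class TestNetworkStats:
    def test_star(self, star4):
        stats = network_stats(star4)
        assert stats.diameter == 2
        assert stats.average_degree == pytest.approx(1.5)
        assert stats.n_components == 1

    def test_triangle(self, triangle):
        stats = network_stats(triangle)
        assert stats.diameter == 1
        assert stats.average_degree == pytest.approx(2.0)

    def test_single_edge_weighted_diameter(self):
        w = np.array([[0, 0.3], [0.3, 0]])
        stats = network_stats(make_net(w))
        assert stats.weighted_diameter == pytest.approx(0.3)
        assert stats.n_nodes == sum(stats.component_sizes)

    def test_diameter_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            w = random_connected_graph(rng, n, p=0.5)
            net = make_net(w)
            stats = network_stats(net)
            dist, _, _ = enumerate_shortest(w, "weight_as_cost")
            hops, _, _ = enumerate_shortest(w, "hop")
            assert stats.weighted_diameter == pytest.approx(
                dist[np.isfinite(dist)].max(), abs=1e-9
            )
            assert stats.diameter == int(hops[np.isfinite(hops)].max())
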