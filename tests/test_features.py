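import numpy as np
import pytest

from netnegsel.annotations import AnnotationRelease
from netnegsel.features import (
    FEATURE_NAMES,
    FeatureBuilder,
    TermContext,
    TermFeatureMatrix,
    annotation_count,
    build_random_walk,
    geometric_centralities,
    local_features,
    normalize_features,
    term_aware_features,
    three_prop,
)
from netnegsel.network import connected_components, shortest_paths

from _oracles import (
    brute_centralities,
    brute_positive_centralities,
    random_connected_graph,
    simulate_walk_endpoints,
)
from conftest import make_net


def ctx_for(net, positives):
    mask = np.zeros(net.n_nodes, dtype=bool)
    mask[positives] = True
    return TermContext(term="t", positives=np.asarray(positives), is_positive=mask)


def release_for(net, y):
    y = np.asarray(y, dtype=np.uint8)
    return AnnotationRelease(
        y=y, terms=[f"T{j}" for j in range(y.shape[1])], node_labels=net.node_labels
    )


class TestLocalFeatures:
    def test_path_center_hand_values(self, path_abc):
        f = local_features(path_abc)
        assert f[1] == pytest.approx([0.5, 0.02, 1.0, 0.0])

    def test_triangle_clustering_is_one(self, triangle):
        assert local_features(triangle)[:, 3] == pytest.approx([1, 1, 1])

    def test_single_neighbor_conventions(self, path_abc):
        f = local_features(path_abc)
        assert f[0, 1] == 0.0  # variance undefined for one neighbor
        assert f[0, 3] == 0.0

    def test_clustering_reduces_to_unweighted(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 12))
            w = random_connected_graph(rng, n, p=0.45)
            w_eq = np.where(w > 0, 0.7, 0.0)  # equal weights
            f4 = local_features(make_net(w_eq))[:, 3]
            g = nx.from_numpy_array(w_eq)
            expected = nx.clustering(g)
            assert f4 == pytest.approx([expected[i] for i in range(n)], abs=1e-12)


class TestAnnotationCount:
    def test_excludes_current_term(self, path_abc):
        rel = release_for(path_abc, [[1, 0, 1, 1], [0, 0, 0, 0], [1, 0, 0, 0]])
        f5 = annotation_count(rel, "T0")
        assert f5 == pytest.approx([2, 0, 0])

    def test_unknown_term_raises(self, path_abc):
        rel = release_for(path_abc, [[1], [0], [0]])
        with pytest.raises(ValueError):
            annotation_count(rel, "nope")


class TestGeometricCentralities:
    def test_star_hand_values(self, star4):
        comps = connected_components(star4)
        paths = shortest_paths(star4, comps)
        g = geometric_centralities(star4, comps, paths)
        assert g[0] == pytest.approx([1 / 3, 16 / 3, 3.0, 3.0])
        assert g[1, 3] == 0.0  # leaves carry no betweenness

    def test_path_harmonic(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        net = make_net(w)
        g = geometric_centralities(net, connected_components(net), shortest_paths(net))
        assert g[0, 2] == pytest.approx(1.5)

    def test_oracle_agreement(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            w = random_connected_graph(rng, n, p=0.5)
            net = make_net(w)
            comps = connected_components(net)
            paths = shortest_paths(net, comps)
            got = geometric_centralities(net, comps, paths)
            assert got == pytest.approx(brute_centralities(w), abs=1e-9)


class TestTermAwareFeatures:
    def test_path_positive_neighborhood(self, path_abc):
        comps = connected_components(path_abc)
        paths = shortest_paths(path_abc, comps)
        f = term_aware_features(path_abc, comps, paths, ctx_for(path_abc, [0]))
        assert f[1, 0] == pytest.approx(0.4)  # f10(b)
        assert f[1, 1] == pytest.approx(0.4)  # f11(b)
        assert f[0, 0] == 0.0  # f10(a): a's only neighbor is unannotated

    def test_star_positive_centralities(self, star4):
        comps = connected_components(star4)
        paths = shortest_paths(star4, comps)
        f = term_aware_features(star4, comps, paths, ctx_for(star4, [1, 2]))
        assert f[0, 3] == pytest.approx(2.0)  # f13(center) = 4 / 2
        assert f[0, 4] == pytest.approx(2.0)  # f14(center)
        assert f[3, 4] == pytest.approx(1.0)  # f14(l3) = 1/2 + 1/2

    def test_component_without_positives_zero(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        w[2, 3] = w[3, 2] = 0.5
        net = make_net(w)
        comps = connected_components(net)
        f = term_aware_features(net, comps, shortest_paths(net), ctx_for(net, [0]))
        assert np.all(f[2:, 2:] == 0.0)

    def test_positive_oracle_agreement(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(4, 8))
            w = random_connected_graph(rng, n, p=0.5)
            net = make_net(w)
            comps = connected_components(net)
            paths = shortest_paths(net, comps)
            k = int(rng.integers(1, n))
            pos = rng.choice(n, size=k, replace=False)
            got = term_aware_features(net, comps, paths, ctx_for(net, pos))[:, 2:]
            assert got == pytest.approx(brute_positive_centralities(w, pos), abs=1e-9)


class TestThreeProp:
    def test_path_hand_values(self, path_abc):
        f = three_prop(path_abc, ctx_for(path_abc, [0]))
        assert f[:, 0] == pytest.approx([0, 0.4, 0])
        assert f[:, 1] == pytest.approx([0.4, 0, 0.4])
        assert f[:, 2] == pytest.approx([0, 0.4, 0])

    def test_single_edge_both_positive(self):
        w = np.array([[0, 0.8], [0.8, 0]])
        net = make_net(w)
        f = three_prop(net, ctx_for(net, [0, 1]))
        assert f[:, 0] == pytest.approx([0.5, 0.5])

    def test_regular_graph_all_positive_uniform(self, triangle):
        f = three_prop(triangle, ctx_for(triangle, [0, 1, 2]))
        assert f == pytest.approx(np.full((3, 3), 1 / 3))

    def test_operator_invariants(self):
        rng = np.random.default_rng(3)
        w = random_connected_graph(rng, 10, p=0.4)
        net = make_net(w)
        op = build_random_walk(net, ctx_for(net, [0, 3]))
        assert op.p.sum(axis=1) == pytest.approx(np.ones(10), abs=1e-12)
        assert op.y.sum() == pytest.approx(1.0)
        p1 = op.propagate(1)
        p2 = op.propagate(2)
        assert op.p @ p1 == pytest.approx(p2, abs=0)
        assert np.all(p1 >= 0) and np.all(p2 >= 0)

    def test_zero_positives_error(self, path_abc):
        with pytest.raises(ValueError, match="3Prop undefined"):
            three_prop(path_abc, ctx_for(path_abc, []))

    def test_monte_carlo_agreement_small(self):
        rng = np.random.default_rng(17)
        w = random_connected_graph(rng, 8, p=0.5)
        net = make_net(w)
        pos = np.array([0, 2])
        exact = three_prop(net, ctx_for(net, pos))
        walks = 5000
        mc = simulate_walk_endpoints(w, pos, walks, seed=5)
        q = exact * len(pos)  # positive-set occupancy probability per start
        se = np.sqrt(q * (1 - q) / walks) / len(pos)
        assert np.all(np.abs(mc - exact) <= 5 * se + 1e-12)


class TestNormalizeAndAssemble:
    def test_column_normalization(self, path_abc):
        mat = TermFeatureMatrix(
            values=np.array([[0.4], [1.0], [0.6]]),
            columns=["f3"],
            term="t",
            node_labels=path_abc.node_labels,
        )
        out = normalize_features(mat)
        assert out.values[:, 0] == pytest.approx([0.2, 0.5, 0.3])
        again = normalize_features(out)
        assert again.values == pytest.approx(out.values)

    def test_zero_column_untouched(self, path_abc):
        mat = TermFeatureMatrix(
            values=np.zeros((3, 1)), columns=["f10"], term="t",
            node_labels=path_abc.node_labels,
        )
        assert np.all(normalize_features(mat).values == 0)

    def test_negative_rejected(self, path_abc):
        mat = TermFeatureMatrix(
            values=np.array([[-1.0], [2.0], [1.0]]), columns=["f1"], term="t",
            node_labels=path_abc.node_labels,
        )
        with pytest.raises(ValueError):
            normalize_features(mat)

    def test_builder_full_matrix_contract(self, tiny_dataset):
        ds = tiny_dataset
        b = FeatureBuilder(ds.net, ds.holdout.older)
        m = b.term_matrix(ds.holdout.terms[0])
        assert m.columns == list(FEATURE_NAMES)
        sums = m.values.sum(axis=0)
        nonzero = sums > 0
        assert sums[nonzero] == pytest.approx(np.ones(nonzero.sum()), abs=1e-9)
        assert np.all(m.values >= 0)

    def test_partial_feature_sets(self, tiny_dataset):
        ds = tiny_dataset
        b = FeatureBuilder(ds.net, ds.holdout.older)
        term = ds.holdout.terms[0]
        m14 = b.term_matrix(term, features=tuple(f"f{i}" for i in range(1, 15)))
        assert len(m14.columns) == 14
        m3 = b.term_matrix(term, features=("f15", "f16", "f17"))
        assert m3.columns == ["f15", "f16", "f17"]
        with pytest.raises(KeyError):
            b.term_matrix(term, features=("f99",))

    def test_term_unaware_columns_invariant_across_terms(self, tiny_dataset):
        ds = tiny_dataset
        b = FeatureBuilder(ds.net, ds.holdout.older)
        t1, t2 = ds.holdout.terms[:2]
        m1 = b.term_matrix(t1, normalized=False)
        m2 = b.term_matrix(t2, normalized=False)
        for f in ("f1", "f2", "f3", "f4", "f6", "f7", "f8", "f9"):
            assert m1.column(f) == pytest.approx(m2.column(f), abs=0)
        assert not np.allclose(m1.column("f10"), m2.column("f10"))
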