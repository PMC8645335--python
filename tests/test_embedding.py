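"""Walk generation, skip-gram embedding, and cosine neighbour ranking."""

import itertools

import networkx as nx
import numpy as np
import pytest

from activemod.embedding import (EmbeddingConfig, EmbeddingSpace, LovTable,
                                 cosine_distance, embed, generate_walks,
                                 load_vectors, rank_neighbors, save_vectors)

SMALL = EmbeddingConfig(dimensions=16, walks_per_node=10, walk_length=40,
                        window=5, epochs=5)


def labelled(graph):
    return nx.relabel_nodes(graph, {i: f"n{i:02d}" for i in graph.nodes()})


class TestWalks:
    def test_structure_on_path_graph(self):
        g = labelled(nx.path_graph(3))
        cfg = EmbeddingConfig(walks_per_node=1, walk_length=3, seed=1)
        walks = generate_walks(g, cfg)
        assert len(walks) == 3
        assert sorted(w[0] for w in walks) == sorted(g.nodes())
        for walk in walks:
            for a, b in zip(walk, walk[1:]):
                assert g.has_edge(a, b)

    def test_uniform_transitions_from_degree_two_node(self):
        # p = q = 1 with unit confidences reduces to a first-order uniform
        # walk: both neighbours of the middle node are equally likely
        g = labelled(nx.path_graph(3))
        cfg = EmbeddingConfig(walks_per_node=10_000, walk_length=2, seed=3)
        walks = generate_walks(g, cfg)
        steps = [w[1] for w in walks if w[0] == "n01"]
        freq = steps.count("n00") / len(steps)
        assert freq == pytest.approx(0.5, abs=0.02)

    def test_return_parameter_discourages_backtracking(self):
        g = labelled(nx.path_graph(3))
        cfg = EmbeddingConfig(walks_per_node=3000, walk_length=3,
                              p=100.0, seed=4)
        walks = generate_walks(g, cfg)
        # from an endpoint the walk must go to the middle; with a huge
        # return parameter it should then almost never come back
        returns = sum(1 for w in walks
                      if len(w) == 3 and w[0] == "n00" and w[2] == "n00")
        total = sum(1 for w in walks if len(w) == 3 and w[0] == "n00")
        assert returns / total < 0.05

    def test_isolated_node_emits_singleton_walks(self):
        g = labelled(nx.path_graph(2))
        g.add_node("n99")
        cfg = EmbeddingConfig(walks_per_node=3, walk_length=5, seed=0)
        walks = generate_walks(g, cfg)
        singles = [w for w in walks if w[0] == "n99"]
        assert len(singles) == 3
        assert all(w == ["n99"] for w in singles)

    def test_walks_deterministic_under_seed(self):
        g = labelled(nx.gnp_random_graph(15, 0.3, seed=2))
        cfg = EmbeddingConfig(walks_per_node=3, walk_length=10, seed=11)
        assert generate_walks(g, cfg) == generate_walks(g, cfg)


class TestEmbed:
    def test_bitwise_deterministic(self):
        g = labelled(nx.gnp_random_graph(20, 0.25, seed=1))
        a = embed(g, SMALL.with_seed(42))
        b = embed(g, SMALL.with_seed(42))
        assert np.array_equal(a.matrix, b.matrix)

    def test_disjoint_cliques_separate(self):
        g = labelled(nx.disjoint_union(nx.complete_graph(10),
                                       nx.complete_graph(10)))
        space = embed(g, SMALL.with_seed(1))
        unit = space.matrix / np.linalg.norm(space.matrix, axis=1,
                                             keepdims=True)
        dist = 1 - unit @ unit.T
        blocks = [set(range(10)), set(range(10, 20))]
        intra, inter = [], []
        for i, j in itertools.combinations(range(20), 2):
            same = any(i in b and j in b for b in blocks)
            (intra if same else inter).append(dist[i, j])
        assert np.mean(intra) < np.mean(inter)

    def test_path_graph_nearest_neighbor_is_adjacent(self):
        # stochastic locality property, averaged over seeds
        accs = []
        for seed in range(5):
            g = labelled(nx.path_graph(30))
            space = embed(g, EmbeddingConfig(dimensions=16, seed=seed))
            ok = sum(g.has_edge(v, space.rank_neighbors(v)[1])
                     for v in space.nodes)
            accs.append(ok / 30)
        assert np.mean(accs) >= 0.8

    def test_block_model_locality(self):
        # same-block nodes should rank closer than cross-block nodes
        wins = 0
        for seed in range(5):
            g = nx.stochastic_block_model([25, 25], [[0.3, 0.02],
                                                     [0.02, 0.3]],
                                          seed=seed)
            g = labelled(g)
            if not nx.is_connected(g):  # keep the benchmark well posed
                g.add_edge("n00", "n25", confidence=1.0)
            space = embed(g, SMALL.with_seed(seed))
            same_ranks, cross_ranks = [], []
            for v in space.nodes:
                block_v = int(v[1:]) < 25
                for rank, u in enumerate(space.rank_neighbors(v)[1:], 1):
                    if (int(u[1:]) < 25) == block_v:
                        same_ranks.append(rank)
                    else:
                        cross_ranks.append(rank)
            wins += np.median(same_ranks) < np.median(cross_ranks)
        assert wins >= 4

    def test_all_nodes_embedded_nonzero(self):
        g = labelled(nx.path_graph(6))
        g.add_node("n99")
        space = embed(g, SMALL.with_seed(0))
        assert len(space) == 7
        assert np.all(np.linalg.norm(space.matrix, axis=1) > 0)


class TestCosineDistance:
    @pytest.mark.parametrize("u,v,expected", [
        ((1, 1), (1, 1), 0.0),
        ((1, 0), (0, 1), 1.0),
        ((1, 0), (-1, 0), 2.0),
    ])
    def test_reference_values(self, u, v, expected):
        assert cosine_distance(u, v) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_self_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            u, v = rng.normal(size=(2, 8))
            assert cosine_distance(u, v) == pytest.approx(
                cosine_distance(v, u), abs=1e-9)
            assert cosine_distance(u, u) == pytest.approx(0, abs=1e-9)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance((0, 0), (1, 0))


class TestRankNeighbors:
    def space(self):
        return EmbeddingSpace(
            nodes=("a", "b", "c", "d"),
            matrix=np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0], [0.9, 0.1]]),
        )

    def test_self_first_and_complete(self):
        space = self.space()
        lov = space.rank_neighbors("a")
        assert lov[0] == "a"
        assert sorted(lov) == ["a", "b", "c", "d"]

    def test_lexicographic_tie_break(self):
        # b and d share a vector, hence identical distance from a
        lov = self.space().rank_neighbors("a")
        assert lov.index("b") < lov.index("d")

    def test_unknown_node(self):
        with pytest.raises(KeyError):
            self.space().rank_neighbors("zz")

    def test_rank_all_agrees_with_per_node_ranking(self):
        space = self.space()
        idx = space.rank_all()
        for i, v in enumerate(space.nodes):
            assert [space.nodes[j] for j in idx[i]] == space.rank_neighbors(v)

    def test_pipeline_ranking_deterministic(self):
        g = labelled(nx.gnp_random_graph(15, 0.3, seed=5))
        lov1 = [embed(g, SMALL.with_seed(7)).rank_neighbors(v)
                for v in sorted(g.nodes())]
        lov2 = [embed(g, SMALL.with_seed(7)).rank_neighbors(v)
                for v in sorted(g.nodes())]
        assert lov1 == lov2


class TestVectorIO:
    def test_roundtrip(self, tmp_path):
        g = labelled(nx.path_graph(5))
        space = embed(g, SMALL.with_seed(3))
        path = save_vectors(space, tmp_path / "vec.tsv")
        again = load_vectors(path)
        assert again.nodes == space.nodes
        assert np.array_equal(again.matrix, space.matrix)
        assert rank_neighbors(again, "n00") == rank_neighbors(space, "n00")


class TestLovTable:
    def test_valid_table(self):
        table = LovTable({"a": ["a", "b"], "b": ["b", "a"]})
        assert table.rank_neighbors("a") == ["a", "b"]

    def test_rejects_bad_first_element(self):
        with pytest.raises(ValueError):
            LovTable({"a": ["b", "a"], "b": ["b", "a"]})
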