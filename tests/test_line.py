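import numpy as np
import pytest

from cmifuse.line import (
    AliasTable,
    EmbeddingMatrix,
    LineModel,
    build_graph,
    exact_objective,
    exact_objective_grad,
    first_order_prob,
    init_line_model,
    line_embed,
    pair_behavior_view,
    second_order_prob,
    train_line,
)
from cmifuse.data_io import InteractionSet, _ordered_index
from cmifuse.synthetic import generate_toy_graph


def grid(pairs, n_c=2, n_m=2):
    return InteractionSet(
        pairs=pairs,
        circ_index=_ordered_index([f"c{i}" for i in range(n_c)]),
        mirna_index=_ordered_index([f"m{i}" for i in range(n_m)]),
    )


class TestBuildGraph:
    def test_vertex_and_edge_counts(self):
        g = build_graph(grid([("c0", "m0"), ("c0", "m1"), ("c1", "m0")]))
        assert g.n_vertices == 4
        assert g.n_edges == 3

    def test_unit_weight_degrees_equal_edge_counts(self):
        g = build_graph(grid([("c0", "m0"), ("c0", "m1"), ("c1", "m0")]))
        assert g.degrees[g.index["c0"]] == 2
        assert g.degrees[g.index["m1"]] == 1

    def test_noise_distribution_normalized(self):
        g = build_graph(generate_toy_graph("star"))
        assert g.noise_distribution.sum() == pytest.approx(1.0, abs=1e-12)

    def test_cold_vertices_recorded(self):
        g = build_graph(grid([("c0", "m0")], n_c=3, n_m=2))
        assert set(g.cold_ids) == {"c1", "c2", "m1"}

    def test_empty_edge_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_graph(grid([]))


class TestAliasTable:
    def test_matches_target_distribution(self):
        weights = np.array([5.0, 1.0, 3.0, 1.0])
        table = AliasTable(weights)
        rng = np.random.default_rng(0)
        draws = table.sample(rng, 100_000)
        freq = np.bincount(draws, minlength=4) / 100_000
        expect = weights / weights.sum()
        se = np.sqrt(expect * (1 - expect) / 100_000)
        assert np.all(np.abs(freq - expect) < 4 * se + 1e-9)


class TestProbabilities:
    def test_sigmoid_of_zero(self):
        assert first_order_prob(np.zeros(4), np.zeros(4)) == 0.5

    def test_sigmoid_of_unit_dot(self):
        e = np.array([1.0, 0.0])
        assert first_order_prob(e, e) == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)

    def test_monotone_in_dot_product(self):
        u = np.array([10.0])
        assert first_order_prob(u, -u) < 1e-8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            first_order_prob(np.zeros(3), np.zeros(4))

    def test_uniform_softmax_with_identical_contexts(self):
        g = build_graph(generate_toy_graph("two_bicliques_bridge"))
        m = init_line_model(g, 4, "second", seed=0)
        m.context_vectors[:] = 1.0
        p = second_order_prob(g, m, "c0", "m0")
        assert p == pytest.approx(1 / g.n_vertices, abs=1e-12)

    def test_two_vertex_softmax_values(self):
        g = build_graph(generate_toy_graph("single_edge"))
        m = init_line_model(g, 2, "second", seed=0)
        # scores (u' . u_c): 1 for m0's context, 0 for c0's own context
        m.vertex_vectors[g.index["c0"]] = [1.0, 0.0]
        m.context_vectors[g.index["m0"]] = [1.0, 0.0]
        m.context_vectors[g.index["c0"]] = [0.0, 0.0]
        e = np.e
        assert second_order_prob(g, m, "c0", "m0") == pytest.approx(
            e / (e + 1), abs=1e-12
        )

    def test_softmax_normalization(self):
        g = build_graph(generate_toy_graph("two_bicliques_bridge"))
        m = init_line_model(g, 4, "second", seed=1)
        m.context_vectors[:] = np.random.default_rng(0).normal(size=m.context_vectors.shape)
        total = sum(second_order_prob(g, m, "c0", v) for v in g.vertex_ids)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestExactObjective:
    def test_single_edge_zero_vectors(self):
        g = build_graph(generate_toy_graph("single_edge"))
        m = LineModel(dim=3, order="first", vertex_vectors=np.zeros((2, 3)))
        assert exact_objective(g, m) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_nonpositive_for_unit_weights(self):
        g = build_graph(generate_toy_graph("two_bicliques_bridge"))
        m = init_line_model(g, 4, "first", seed=0)
        m.vertex_vectors[:] = np.random.default_rng(1).normal(size=m.vertex_vectors.shape)
        assert exact_objective(g, m) <= 0

    def test_linear_in_edge_weights(self):
        toy = generate_toy_graph("star")
        g1 = build_graph(toy)
        g2 = build_graph(toy, weights=2 * np.ones(5))
        m = init_line_model(g1, 4, "first", seed=2)
        assert exact_objective(g2, m) == pytest.approx(2 * exact_objective(g1, m))


@pytest.mark.parametrize("order", ["first", "second"])
def test_analytic_gradient_matches_central_differences(order):
    """Trainer gradient math vs numerical differentiation of the objective."""
    graph = build_graph(generate_toy_graph("two_bicliques_bridge"))
    model = init_line_model(graph, 3, order, seed=5)
    rng = np.random.default_rng(6)
    model.vertex_vectors[:] = rng.normal(0, 0.3, model.vertex_vectors.shape)
    if order == "second":
        model.context_vectors[:] = rng.normal(0, 0.3, model.context_vectors.shape)
    du, dctx = exact_objective_grad(graph, model)
    h = 1e-5
    for arr, grad in ((model.vertex_vectors, du), (model.context_vectors, dctx)):
        if arr is None:
            continue
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                orig = arr[i, j]
                arr[i, j] = orig + h
                lp = exact_objective(graph, model)
                arr[i, j] = orig - h
                lm = exact_objective(graph, model)
                arr[i, j] = orig
                num = (lp - lm) / (2 * h)
                assert abs(num - grad[i, j]) < 1e-4 * max(1.0, abs(num))


class TestTrainLine:
    def test_single_edge_probability_rises(self):
        g = build_graph(generate_toy_graph("single_edge"))
        m = train_line(g, 4, "first", n_samples=2000, seed=0)
        p = first_order_prob(m.vertex_vectors[0], m.vertex_vectors[1])
        assert p > 0.9

    @pytest.mark.parametrize("pattern", ["star", "two_bicliques_bridge"])
    def test_objective_increases_from_initialization(self, pattern):
        # K=1 on these tiny graphs: with |V| <= 8 a large K drowns the
        # positive signal in noise updates that hit true neighbors.
        g = build_graph(generate_toy_graph(pattern))
        init = exact_objective(g, init_line_model(g, 4, "first", seed=3))
        trained = exact_objective(
            g, train_line(g, 4, "first", K=1, n_samples=3000, seed=3)
        )
        assert trained > init

    def test_second_order_objective_increases(self):
        g = build_graph(generate_toy_graph("two_bicliques_bridge"))
        init = exact_objective(g, init_line_model(g, 4, "second", seed=3))
        trained = exact_objective(
            g, train_line(g, 4, "second", K=1, n_samples=4000, seed=3)
        )
        assert trained > init

    def test_output_finite_and_shaped(self):
        g = build_graph(generate_toy_graph("star"))
        m = train_line(g, 6, "second", n_samples=500, seed=1)
        assert m.vertex_vectors.shape == (6, 6)
        assert np.all(np.isfinite(m.vertex_vectors))
        assert np.all(np.isfinite(m.context_vectors))

    def test_deterministic(self):
        g = build_graph(generate_toy_graph("star"))
        a = train_line(g, 4, "first", n_samples=500, seed=7)
        b = train_line(g, 4, "first", n_samples=500, seed=7)
        assert np.array_equal(a.vertex_vectors, b.vertex_vectors)


class TestNoiseDistribution:
    def test_empirical_frequencies_match_degree_power(self):
        g = build_graph(generate_toy_graph("star"))
        rng = np.random.default_rng(0)
        n = 100_000
        draws = g.noise_alias.sample(rng, n)
        freq = np.bincount(draws, minlength=g.n_vertices) / n
        expect = g.noise_distribution
        se = np.sqrt(expect * (1 - expect) / n)
        assert np.all(np.abs(freq - expect) <= 3 * se + 1e-9)


class TestLineEmbed:
    def test_concatenated_dimension_split(self):
        g = build_graph(generate_toy_graph("two_bicliques_bridge"))
        emb = line_embed(g, total_dim=16, samples_per_edge=50, seed=0)
        assert emb.dim == 16
        assert emb.vectors.shape == (8, 16)

    def test_odd_dimension_rejected(self):
        g = build_graph(generate_toy_graph("star"))
        with pytest.raises(ValueError, match="even"):
            line_embed(g, total_dim=7)

    def test_cold_vertices_zero_and_flagged(self):
        s = grid([("c0", "m0")], n_c=2, n_m=2)
        emb = line_embed(build_graph(s), total_dim=8, samples_per_edge=50, seed=0)
        assert emb.is_cold("c1") and emb.is_cold("m1")
        assert np.array_equal(emb.vector("c1"), np.zeros(8))
        assert not emb.is_cold("c0")

    def test_deterministic(self):
        g = build_graph(generate_toy_graph("star"))
        a = line_embed(g, total_dim=8, samples_per_edge=100, seed=9)
        b = line_embed(g, total_dim=8, samples_per_edge=100, seed=9)
        assert np.array_equal(a.vectors, b.vectors)

    def test_relabeling_leaves_vectors_unchanged(self):
        # renaming ids (same insertion order) must not change the numbers
        a = grid([("c0", "m0"), ("c0", "m1"), ("c1", "m1")])
        b = InteractionSet(
            pairs=[("x0", "y0"), ("x0", "y1"), ("x1", "y1")],
            circ_index=_ordered_index(["x0", "x1"]),
            mirna_index=_ordered_index(["y0", "y1"]),
        )
        ea = line_embed(build_graph(a), total_dim=8, samples_per_edge=100, seed=2)
        eb = line_embed(build_graph(b), total_dim=8, samples_per_edge=100, seed=2)
        assert np.array_equal(ea.vectors, eb.vectors)


class TestPairBehaviorView:
    def test_concatenation_and_cold_half(self):
        s = grid([("c0", "m0")], n_c=2, n_m=2)
        emb = line_embed(build_graph(s), total_dim=8, samples_per_edge=50, seed=0)
        v = pair_behavior_view(emb, ("c1", "m0"))
        assert v.shape == (16,)
        assert np.array_equal(v[:8], np.zeros(8))  # cold circ half
        v2 = pair_behavior_view(emb, ("c0", "m0"))
        assert np.array_equal(v[8:], v2[8:])  # shared miRNA half

    def test_unknown_id_rejected(self):
        s = grid([("c0", "m0")])
        emb = line_embed(build_graph(s), total_dim=8, samples_per_edge=50, seed=0)
        with pytest.raises(KeyError):
            pair_behavior_view(emb, ("nope", "m0"))


def test_word2vec_import(tmp_path):
    p = tmp_path / "emb.txt"
    p.write_text("2 3\na 1 2 3\nb 4 5 6\n")
    emb = EmbeddingMatrix.from_word2vec(p)
    assert emb.ids == ["a", "b"]
    assert np.array_equal(emb.vector("b"), [4.0, 5.0, 6.0])
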