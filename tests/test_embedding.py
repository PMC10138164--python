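import networkx as nx
import numpy as np
import pytest

from dynalign import (
    EmbeddingState,
    SGParams,
    TemporalNetwork,
    WalkParams,
    generate_base_network,
    joint_temporal_embedding,
    sample_walks,
    temporal_embedding,
    train_skipgram,
)
from dynalign.embedding import WalkCorpus

from conftest import relabeled_copy


def triangle():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


def test_walks_follow_edges_exhaustively():
    g = triangle()
    corpus = sample_walks(g, WalkParams(walks_per_node=2, walk_length=5), seed=0)
    assert len(corpus) == 6
    for walk in corpus.walks:
        assert len(walk) == 5
        for x, y in zip(walk, walk[1:]):
            assert g.has_edge(x, y)


def test_isolated_nodes_yield_singleton_walks():
    g = nx.Graph()
    g.add_node("lonely")
    g.add_edge("a", "b")
    corpus = sample_walks(g, WalkParams(walks_per_node=3, walk_length=10), seed=1)
    singletons = [w for w in corpus.walks if w == ["lonely"]]
    assert len(singletons) == 3


def test_unbiased_transition_is_uniform_on_a_path():
    # from the middle of a-b-c with p=q=1, both neighbors equally likely
    g = nx.path_graph(["a", "b", "c"])
    corpus = sample_walks(
        g, WalkParams(walks_per_node=1500, walk_length=6), seed=2
    )
    follow = {"a": 0, "c": 0}
    for walk in corpus.walks:
        for x, y in zip(walk, walk[1:]):
            if x == "b":
                follow[y] += 1
    total = follow["a"] + follow["c"]
    assert total >= 10_000
    assert abs(follow["a"] / total - 0.5) <= 0.02


def test_biased_walks_respect_pq_extremes():
    # q -> infinity confines the walk to the previous node's neighborhood;
    # on a star the walk must keep bouncing through the hub
    g = nx.star_graph(["hub", "s1", "s2", "s3"])
    corpus = sample_walks(
        g, WalkParams(walks_per_node=2, walk_length=8, p=0.25, q=4.0), seed=3
    )
    for walk in corpus.walks:
        for x, y in zip(walk, walk[1:]):
            assert g.has_edge(x, y)


def test_empty_graph_warns_and_returns_empty_corpus():
    with pytest.warns(UserWarning):
        corpus = sample_walks(nx.Graph(), WalkParams(), seed=0)
    assert corpus.walks == []


def test_zero_epoch_identity():
    corpus = sample_walks(triangle(), WalkParams(2, 5), seed=4)
    init = EmbeddingState(
        ["a", "b", "c"], np.arange(12, dtype=np.float32).reshape(3, 4)
    )
    out = train_skipgram(corpus, SGParams(dim=4, epochs=0, seed=0), initial=init)
    for tok in "abc":
        np.testing.assert_array_equal(out[tok], init[tok])


def test_training_respects_dimension_contract():
    corpus = sample_walks(triangle(), WalkParams(2, 5), seed=5)
    out = train_skipgram(corpus, SGParams(dim=16, epochs=1, seed=1))
    assert out.dim == 16
    assert sorted(out.tokens) == ["a", "b", "c"]


def test_dimension_mismatch_rejected():
    corpus = sample_walks(triangle(), WalkParams(2, 5), seed=6)
    init = EmbeddingState(["a"], np.zeros((1, 8), dtype=np.float32))
    with pytest.raises(ValueError, match="dimension"):
        train_skipgram(corpus, SGParams(dim=4, epochs=1), initial=init)


def test_nodes_only_in_initial_are_discarded():
    corpus = sample_walks(triangle(), WalkParams(2, 5), seed=7)
    init = EmbeddingState(
        ["a", "ghost"], np.ones((2, 4), dtype=np.float32)
    )
    out = train_skipgram(corpus, SGParams(dim=4, epochs=0), initial=init)
    assert "ghost" not in out
    np.testing.assert_array_equal(out["a"], init["a"])


def test_temporal_embedding_deterministic(small_base, fast_walk_params, fast_sg_params):
    a = temporal_embedding(small_base, fast_walk_params, fast_sg_params)
    b = temporal_embedding(small_base, fast_walk_params, fast_sg_params)
    assert a.tokens == b.tokens
    np.testing.assert_array_equal(a.matrix, b.matrix)


def test_temporal_embedding_single_timepoint_matches_plain_skipgram(
    fast_walk_params,
):
    net = TemporalNetwork(
        "one", frozenset(), frozenset({("a", "b", 0), ("b", "c", 0)})
    )
    emb = temporal_embedding(net, fast_walk_params, SGParams(dim=8, epochs=1, seed=9))
    assert emb.meta["t"] == 0
    assert set(emb.tokens) == {"a", "b", "c"}


def test_temporal_embedding_rejects_empty_network():
    net = TemporalNetwork(
        "empty", frozenset({"a", "b"}), frozenset(), n_timepoints=2
    )
    with pytest.raises(ValueError, match="no trainable content"):
        temporal_embedding(net, WalkParams(), SGParams())


def test_joint_embedding_partitions_and_dimensions(
    small_base, fast_walk_params, fast_sg_params
):
    G, _ = relabeled_copy(small_base)
    embG, embH = joint_temporal_embedding(
        G, small_base, fast_walk_params, fast_sg_params
    )
    assert len(embG) == G.n_nodes
    assert len(embH) == small_base.n_nodes
    assert embG.dim == embH.dim == fast_sg_params.dim
    assert set(embG.tokens) == set(G.nodes)
    assert set(embH.tokens) == set(small_base.nodes)


def test_joint_embedding_requires_equal_timepoints(small_base):
    other = TemporalNetwork(
        "short", frozenset(), frozenset({("a", "b", 0)}), n_timepoints=1
    )
    with pytest.raises(ValueError, match="unequal time points"):
        joint_temporal_embedding(small_base, other)


def test_joint_self_recovery_by_cosine():
    # a node's relabeled twin should rank in the top decile of its
    # cross-network similarities for nearly all nodes; exact top-1
    # recovery is the matcher's job and is tested end to end elsewhere
    H = generate_base_network(50, 2, 5, 0.05, seed=11)
    G, truth = relabeled_copy(H)
    embG, embH = joint_temporal_embedding(
        G, H, WalkParams(5, 20), SGParams(dim=64, epochs=3, seed=5)
    )
    A = embG.matrix / np.linalg.norm(embG.matrix, axis=1, keepdims=True)
    B = embH.matrix / np.linalg.norm(embH.matrix, axis=1, keepdims=True)
    sim = A @ B.T
    col = {c: j for j, c in enumerate(embH.tokens)}
    cutoff = max(1, len(embH.tokens) // 10)
    good = 0
    for i, tok in enumerate(embG.tokens):
        twin = sim[i, col[truth[tok]]]
        good += (sim[i] > twin).sum() < cutoff
    assert good / len(embG.tokens) >= 0.9


def test_state_tsv_round_trip(tmp_path):
    state = EmbeddingState(
        ["n1", "n2"],
        np.array([[0.5, -1.25], [3.0, 2.0]], dtype=np.float32),
        {"t": 4},
    )
    path = tmp_path / "emb.tsv"
    state.to_tsv(path)
    back = EmbeddingState.from_tsv(path)
    assert back.tokens == state.tokens
    np.testing.assert_allclose(back.matrix, state.matrix, rtol=1e-6)


def test_corpus_with_no_walks_rejected():
    with pytest.raises(ValueError, match="empty corpus"):
        train_skipgram(WalkCorpus([], WalkParams()), SGParams())
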