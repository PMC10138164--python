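import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynalign import (
    EmbeddingState,
    SGParams,
    SimilarityMatrix,
    TemporalNetwork,
    align,
    align_networks,
    similarity_matrix,
)

from conftest import relabeled_copy


def _state(tokens, matrix):
    return EmbeddingState(tokens, np.asarray(matrix, dtype=np.float32))


def brute_force_sweep(sim: SimilarityMatrix) -> dict[str, str]:
    """Independent oracle: sort all pairs by (-score, v, u), sweep once."""
    pairs = sorted(
        (
            (-sim.scores[i, j], sim.rows[i], sim.cols[j])
            for i in range(len(sim.rows))
            for j in range(len(sim.cols))
        ),
    )
    mapping: dict[str, str] = {}
    used = set()
    for _, v, u in pairs:
        if v in mapping or u in used:
            continue
        mapping[v] = u
        used.add(u)
    return mapping


def test_cosine_matches_direct_formula():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(5, 8))
    B = rng.normal(size=(5, 8))
    sim = similarity_matrix(
        _state([f"g{i}" for i in range(5)], A),
        _state([f"h{i}" for i in range(5)], B),
    )
    # the state stores float32; the oracle reads those values back in
    # float64, matching the precision the similarity is computed at
    A64 = A.astype(np.float32).astype(np.float64)
    B64 = B.astype(np.float32).astype(np.float64)
    for i in range(5):
        for j in range(5):
            expected = np.dot(A64[i], B64[j]) / (
                np.linalg.norm(A64[i]) * np.linalg.norm(B64[j])
            )
            assert abs(sim.scores[i, j] - expected) < 1e-12


def test_cosine_identity_and_orthogonality():
    sim = similarity_matrix(
        _state(["g"], [[1.0, 0.0]]),
        _state(["h1", "h2", "h3"], [[2.0, 0.0], [0.0, 5.0], [-1.0, 0.0]]),
    )
    np.testing.assert_allclose(sim.scores[0], [1.0, 0.0, -1.0], atol=1e-7)


def test_zero_norm_vector_scores_zero_with_warning():
    with pytest.warns(UserWarning, match="zero-norm"):
        sim = similarity_matrix(
            _state(["g"], [[0.0, 0.0]]), _state(["h"], [[1.0, 1.0]])
        )
    assert sim.scores[0, 0] == 0.0


def test_ranked_matches_sorted_descending():
    sim = SimilarityMatrix(["v"], ["a", "b", "c"], [[0.2, 0.9, 0.5]])
    assert [u for u, _ in sim.ranked_matches("v")] == ["b", "c", "a"]


def test_greedy_resolves_collision_globally():
    # row-wise argmax would map both rows onto the first column
    sim = SimilarityMatrix(["v1", "v2"], ["u1", "u2"], [[0.9, 0.1], [0.8, 0.7]])
    aln = align(sim)
    assert aln.mapping == {"v1": "u1", "v2": "u2"}
    assert aln.scores["v1"] == pytest.approx(0.9)
    assert aln.scores["v2"] == pytest.approx(0.7)


def test_single_pair():
    aln = align(SimilarityMatrix(["v1"], ["u1"], [[0.3]]))
    assert aln.mapping == {"v1": "u1"}


def test_more_rows_than_columns_rejected():
    sim = SimilarityMatrix(["a", "b"], ["u"], [[0.1], [0.2]])
    with pytest.raises(ValueError, match="swap"):
        align(sim)


@given(
    st.integers(1, 5),
    st.integers(0, 1),
    st.randoms(use_true_random=False),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_greedy_equals_sweep_oracle(n, extra, rnd):
    m = n + extra
    values = rnd.sample(range(10_000), n * m)  # distinct entries
    scores = np.array(values, dtype=float).reshape(n, m) / 10_000
    sim = SimilarityMatrix(
        [f"v{i}" for i in range(n)], [f"u{j}" for j in range(m)], scores
    )
    assert align(sim).mapping == brute_force_sweep(sim)


def test_assigned_scores_non_increasing_and_injective():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n, m = rng.integers(2, 8), rng.integers(8, 12)
        sim = SimilarityMatrix(
            [f"v{i}" for i in range(n)],
            [f"u{j}" for j in range(m)],
            rng.uniform(-1, 1, size=(n, m)),
        )
        aln = align(sim)
        assert len(aln.mapping) == n
        assert len(set(aln.mapping.values())) == n
        ordered = sorted(aln.scores.values(), reverse=True)
        replay = [aln.scores[v] for v in brute_force_sweep(sim)]
        assert replay == sorted(replay, reverse=True)
        assert sorted(replay, reverse=True) == ordered


def test_optimal_total_at_least_greedy():
    rng = np.random.default_rng(7)
    for _ in range(20):
        sim = SimilarityMatrix(
            [f"v{i}" for i in range(5)],
            [f"u{j}" for j in range(6)],
            rng.uniform(-1, 1, size=(5, 6)),
        )
        assert align(sim, "optimal").total >= align(sim, "greedy").total - 1e-12


def test_align_networks_end_to_end(small_base, fast_walk_params, fast_sg_params):
    G, truth = relabeled_copy(small_base)
    aln = align_networks(G, small_base, fast_walk_params, fast_sg_params)
    assert len(aln.mapping) == G.n_nodes
    assert len(set(aln.mapping.values())) == G.n_nodes


def test_align_networks_rejects_oversized_source(small_base):
    tiny = TemporalNetwork("t", frozenset(), frozenset({("a", "b", 0)}))
    with pytest.raises(ValueError, match="swap"):
        align_networks(small_base, tiny)


def test_unknown_matcher_rejected():
    sim = SimilarityMatrix(["v"], ["u"], [[0.5]])
    with pytest.raises(ValueError, match="unknown method"):
        align(sim, "magic")
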