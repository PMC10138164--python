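"""Cross-network similarity and injective node mapping.

The similarity matrix holds the cosine similarity between every source
node's embedding and every target node's embedding.  The alignment is an
injective map f: V -> U built by iterative global score maximization:
repeatedly take the globally best unassigned (v, u) pair, so that no pair
assigned later scores at least as high as an earlier one.  An optimal
bipartite assignment (Hungarian) is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .embedding import EmbeddingState, SGParams, WalkParams, joint_temporal_embedding
from .netio import TemporalNetwork

__all__ = [
    "SimilarityMatrix",
    "Alignment",
    "similarity_matrix",
    "align",
    "align_networks",
]


@dataclass
class SimilarityMatrix:
    """|V| x |U| cosine scores between source rows and target columns."""

    rows: list[str]
    cols: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.rows), len(self.cols)):
            raise ValueError("score matrix shape does not match row/col labels")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("similarity scores must be finite")

    def ranked_matches(self, v: str) -> list[tuple[str, float]]:
        """Target nodes for source node v, sorted by descending similarity."""
        i = self.rows.index(v)
        order = np.argsort(-self.scores[i], kind="stable")
        return [(self.cols[j], float(self.scores[i, j])) for j in order]


@dataclass
class Alignment:
    """Injective node mapping with per-pair similarity scores."""

    mapping: dict[str, str]
    scores: dict[str, float]
    g_nodes: list[str]
    h_nodes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.mapping.values())) != len(self.mapping):
            raise ValueError("alignment must be injective")

    @property
    def total(self) -> float:
        return float(sum(self.scores.values()))

    def __len__(self) -> int:
        return len(self.mapping)

    def to_tsv(self, path) -> None:
        pairs = sorted(self.mapping.items(), key=lambda kv: -self.scores[kv[0]])
        with open(path, "w") as fh:
            fh.write("#g_node\th_node\tscore\n")
            for v, u in pairs:
                fh.write(f"{v}\t{u}\t{self.scores[v]:.6f}\n")


def similarity_matrix(
    embG: EmbeddingState, embH: EmbeddingState
) -> SimilarityMatrix:
    """Cosine similarity between every G vector and every H vector.

    Zero-norm vectors (untrained rows) get similarity 0 by convention.
    """
    if len(embG) == 0 or len(embH) == 0:
        raise ValueError("both embedding states must be non-empty")
    if embG.dim != embH.dim:
        raise ValueError("embedding dimensions differ")
    A = embG.matrix.astype(np.float64)
    B = embH.matrix.astype(np.float64)
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        warnings.warn("zero-norm embedding vector(s); their similarities are 0")
    na[na == 0] = np.inf
    nb[nb == 0] = np.inf
    scores = (A / na[:, None]) @ (B / nb[:, None]).T
    return SimilarityMatrix(list(embG.tokens), list(embH.tokens), scores)


def align(sim: SimilarityMatrix, method: str = "greedy") -> Alignment:
    """Injective mapping from rows to columns maximizing similarity.

    method="greedy" (default)
        iterative global maximization: sort all (v, u) pairs by
        descending score (ties broken lexicographically on (v, u)) and
        sweep, assigning a pair whenever both endpoints are free.  The
        assigned scores are non-increasing in assignment order.
    method="optimal"
        maximum-weight bipartite assignment (Hungarian algorithm); its
        total score is >= the greedy total.
    """
    n, m = len(sim.rows), len(sim.cols)
    if n > m:
        raise ValueError(
            "more source rows than target columns: swap the networks so that "
            "|V| <= |U|"
        )
    if method == "optimal":
        ri, cj = linear_sum_assignment(-sim.scores)
        mapping = {sim.rows[i]: sim.cols[j] for i, j in zip(ri, cj)}
    elif method == "greedy":
        order = sorted(
            ((i, j) for i in range(n) for j in range(m)),
            key=lambda ij: (-sim.scores[ij], sim.rows[ij[0]], sim.cols[ij[1]]),
        )
        mapping = {}
        used_cols: set[int] = set()
        used_rows: set[int] = set()
        for i, j in order:
            if i in used_rows or j in used_cols:
                continue
            mapping[sim.rows[i]] = sim.cols[j]
            used_rows.add(i)
            used_cols.add(j)
            if len(mapping) == n:
                break
    else:
        raise ValueError(f"unknown method {method!r}")
    scores = {
        v: float(sim.scores[sim.rows.index(v), sim.cols.index(u)])
        for v, u in mapping.items()
    }
    return Alignment(mapping, scores, list(sim.rows), list(sim.cols))


def align_networks(
    G: TemporalNetwork,
    H: TemporalNetwork,
    walk_params: WalkParams | None = None,
    sg_params: SGParams | None = None,
    method: str = "greedy",
) -> Alignment:
    """End-to-end pairwise alignment of two dynamic networks.

    Joint temporal embedding -> cosine similarity matrix -> injective
    mapping covering all of G's nodes (requires |V| <= |U|).
    """
    if G.n_nodes == 0:
        raise ValueError("source network has no nodes")
    if G.n_nodes > H.n_nodes:
        raise ValueError(
            "source network is larger than the target: swap G and H"
        )
    embG, embH = joint_temporal_embedding(G, H, walk_params, sg_params)
    sim = similarity_matrix(embG, embH)
    return align(sim, method=method)
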