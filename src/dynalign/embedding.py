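"""Temporal node embeddings via a skip-gram model with an initial state.

Each snapshot is turned into a corpus of node2vec-style random walks and
fed to a skip-gram model whose input-embedding rows are *initialized from
the previous time point's embeddings* (the intersection of the current
vocabulary with the previous state; nodes absent from the vocabulary are
dropped, fresh nodes get seeded initialization).  Iterating this over the
snapshot sequence yields one vector per node that reflects the whole
temporal evolution of its neighbourhood.

For aligning two networks the embeddings must live in one space: at every
time point a single joint model is trained on the concatenated,
prefix-disambiguated corpora of both networks, and fresh vectors are
seeded from temporal degree profiles through one shared random projection,
which anchors structurally equivalent nodes of the two networks at nearby
coordinates (see :func:`joint_temporal_embedding`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from ._sgns import train_sgns
from .netio import TemporalNetwork

__all__ = [
    "WalkParams",
    "SGParams",
    "WalkCorpus",
    "EmbeddingState",
    "sample_walks",
    "train_skipgram",
    "temporal_embedding",
    "joint_temporal_embedding",
]


@dataclass(frozen=True)
class WalkParams:
    """Random-walk sampling parameters (node2vec semantics)."""

    walks_per_node: int = 10
    walk_length: int = 80
    p: float = 1.0  # return bias: transition back to the previous node ∝ 1/p
    q: float = 1.0  # in-out bias: transition away from it ∝ 1/q

    def __post_init__(self) -> None:
        if self.walks_per_node < 1 or self.walk_length < 1:
            raise ValueError("walk parameters must be positive")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass(frozen=True)
class SGParams:
    """Skip-gram hyperparameters.

    ``dim`` is the hidden-layer size N (the embedding dimension); ``window``
    the rolling context window w; ``negative`` the number of negative
    samples standing in for the softmax normalization.  ``anchor`` is the
    elastic pull toward the initial (carried) state applied after each
    row update: it weights the maintenance of features from the previous
    time point against the current snapshot's evidence (0 disables it and
    recovers plain skip-gram).
    """

    dim: int = 128
    window: int = 5
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    anchor: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.window < 1:
            raise ValueError("dim and window must be >= 1")
        if self.epochs < 0 or self.negative < 0:
            raise ValueError("epochs and negative must be non-negative")
        if self.anchor < 0:
            raise ValueError("anchor must be non-negative")


@dataclass
class WalkCorpus:
    """A list of walks (node-id sequences) sampled from one snapshot."""

    walks: list[list[str]]
    params: WalkParams

    def __len__(self) -> int:
        return len(self.walks)


class EmbeddingState:
    """node id -> vector map of fixed dimension, with provenance metadata."""

    def __init__(self, tokens: list[str], matrix: np.ndarray, meta: dict | None = None):
        if len(tokens) != len(set(tokens)):
            raise ValueError("duplicate node ids in embedding state")
        if matrix.ndim != 2 or matrix.shape[0] != len(tokens):
            raise ValueError("matrix shape does not match token list")
        self.tokens = list(tokens)
        self.matrix = np.asarray(matrix, dtype=np.float32)
        self.meta = dict(meta or {})
        self._index = {tok: i for i, tok in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    @property
    def vectors(self) -> dict[str, np.ndarray]:
        return {tok: self.matrix[i] for tok, i in self._index.items()}

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __getitem__(self, token: str) -> np.ndarray:
        return self.matrix[self._index[token]]

    def subset(self, prefix: str, strip: bool = True) -> "EmbeddingState":
        """Slice out tokens starting with ``prefix`` (optionally stripped)."""
        keep = [t for t in self.tokens if t.startswith(prefix)]
        rows = np.array([self._index[t] for t in keep], dtype=int)
        names = [t[len(prefix):] if strip else t for t in keep]
        return EmbeddingState(names, self.matrix[rows].copy(), dict(self.meta))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#dim={self.dim} #t={self.meta.get('t', -1)}\n")
            for tok in self.tokens:
                vec = "\t".join(f"{x:.8g}" for x in self[tok])
                fh.write(f"{tok}\t{vec}\n")

    @classmethod
    def from_tsv(cls, path) -> "EmbeddingState":
        tokens: list[str] = []
        rows: list[list[float]] = []
        meta: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    for part in line[1:].split():
                        if "=" in part:
                            k, v = part.lstrip("#").split("=", 1)
                            meta[k] = int(v)
                    continue
                fields = line.split("\t")
                tokens.append(fields[0])
                rows.append([float(x) for x in fields[1:]])
        return cls(tokens, np.asarray(rows, dtype=np.float32), meta)


# ---------------------------------------------------------------------------
# random walks


def sample_walks(
    graph: nx.Graph,
    params: WalkParams | None = None,
    seed: int = 0,
) -> WalkCorpus:
    """Sample ``walks_per_node`` biased random walks from every node.

    Transitions follow node2vec's second-order scheme: from the current
    node, a neighbour x is chosen with unnormalized weight 1/p if x is the
    previous node, 1 if x neighbours the previous node, else 1/q.  With
    p = q = 1 this reduces to the uniform first-order walk.  Isolated
    nodes yield singleton walks so they stay in the vocabulary.
    """
    params = params or WalkParams()
    nodes = sorted(graph.nodes())
    if not nodes:
        warnings.warn("empty graph: returning an empty walk corpus")
        return WalkCorpus([], params)
    index = {n: i for i, n in enumerate(nodes)}
    neighbors = [np.array(sorted(index[m] for m in graph[n]), dtype=np.int64)
                 for n in nodes]
    neighbor_sets = [set(a.tolist()) for a in neighbors]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    uniform = params.p == 1.0 and params.q == 1.0
    walks: list[list[str]] = []
    for _ in range(params.walks_per_node):
        for start in range(len(nodes)):
            walk = [start]
            prev = -1
            cur = start
            for _ in range(params.walk_length - 1):
                nbrs = neighbors[cur]
                if nbrs.size == 0:
                    break
                if uniform or prev < 0:
                    nxt = int(nbrs[rng.integers(nbrs.size)])
                else:
                    w = np.empty(nbrs.size)
                    prev_nbrs = neighbor_sets[prev]
                    for k in range(nbrs.size):
                        x = int(nbrs[k])
                        if x == prev:
                            w[k] = 1.0 / params.p
                        elif x in prev_nbrs:
                            w[k] = 1.0
                        else:
                            w[k] = 1.0 / params.q
                    w /= w.sum()
                    nxt = int(nbrs[rng.choice(nbrs.size, p=w)])
                walk.append(nxt)
                prev, cur = cur, nxt
            walks.append([nodes[i] for i in walk])
    return WalkCorpus(walks, params)


# ---------------------------------------------------------------------------
# skip-gram training


def train_skipgram(
    corpus: WalkCorpus,
    params: SGParams | None = None,
    initial: EmbeddingState | None = None,
    init_fn=None,
) -> EmbeddingState:
    """Train skip-gram on a walk corpus, seeded from an initial state.

    The vocabulary is built from the corpus.  Input-embedding rows of
    nodes present in both the vocabulary and ``initial`` start from their
    initial vectors (the intersection; nodes only in ``initial`` are
    discarded).  Fresh nodes are initialized by ``init_fn(node)`` when
    given, else by seeded uniform noise.  With ``epochs=0`` and full
    initial coverage the output equals the initial state exactly.
    """
    params = params or SGParams()
    if not corpus.walks:
        raise ValueError("empty corpus: nothing to train on")
    vocab = sorted({tok for walk in corpus.walks for tok in walk})
    index = {tok: i for i, tok in enumerate(vocab)}
    V, dim = len(vocab), params.dim
    if initial is not None and len(initial) and initial.dim != dim:
        raise ValueError(
            f"initial state dimension {initial.dim} != params.dim {dim}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    W = ((rng.random((V, dim)) - 0.5) / dim).astype(np.float32)
    if init_fn is not None:
        for tok, i in index.items():
            vec = init_fn(tok)
            if vec is not None:
                W[i] = vec
    if initial is not None:
        for tok, i in index.items():
            if tok in initial:
                W[i] = initial[tok]
    if params.epochs > 0:
        counts = np.zeros(V, dtype=np.float64)
        flat: list[int] = []
        offsets = [0]
        for walk in corpus.walks:
            for tok in walk:
                ti = index[tok]
                flat.append(ti)
                counts[ti] += 1
            offsets.append(len(flat))
        tokens = np.asarray(flat, dtype=np.int32)
        off = np.asarray(offsets, dtype=np.int64)
        noise = counts ** 0.75
        neg_cdf = np.cumsum(noise / noise.sum())
        neg_cdf[-1] = 1.0
        C = np.zeros((V, dim), dtype=np.float32)
        W0 = W.copy() if params.anchor > 0 else np.zeros((1, dim), dtype=np.float32)
        train_sgns(
            tokens, off, W, C,
            params.window, params.negative, neg_cdf,
            params.alpha, params.min_alpha, params.epochs,
            np.uint64(params.seed % 2**63 + 1),
            W0, params.anchor,
        )
    return EmbeddingState(vocab, W, {"params": params})


# ---------------------------------------------------------------------------
# temporal chaining


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


def temporal_embedding(
    network: TemporalNetwork,
    walk_params: WalkParams | None = None,
    sg_params: SGParams | None = None,
) -> EmbeddingState:
    """Chain skip-gram training over the snapshot sequence.

    For t = 0..T-1 the corpus of snapshot t is trained with the state of
    t-1 as initial embeddings (empty for t = 0); the state after the last
    snapshot is returned.  Deterministic for a fixed seed.
    """
    walk_params = walk_params or WalkParams()
    sg_params = sg_params or SGParams()
    if network.n_events == 0:
        raise ValueError("no trainable content: every snapshot is empty")
    T = network.n_timepoints
    seeds = _child_seeds(sg_params.seed, 2 * T)
    state: EmbeddingState | None = None
    for t in range(T):
        corpus = sample_walks(network.snapshot(t), walk_params, seed=seeds[2 * t])
        sgp = replace(sg_params, seed=seeds[2 * t + 1])
        state = train_skipgram(corpus, sgp, initial=state)
        state.meta["t"] = t
    return state


def _temporal_degree_features(net: TemporalNetwork) -> tuple[list[str], np.ndarray]:
    """Per-node [log1p(deg_t), log1p(mean neighbour deg_t)] over all t."""
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    T = net.n_timepoints
    feats = np.zeros((len(nodes), 2 * T))
    for t in range(T):
        g = net.snapshot(t)
        deg = {n: g.degree(n) for n in nodes}
        for n in nodes:
            i = idx[n]
            feats[i, 2 * t] = np.log1p(deg[n])
            if deg[n] > 0:
                mnd = sum(deg[m] for m in g[n]) / deg[n]
                feats[i, 2 * t + 1] = np.log1p(mnd)
    return nodes, feats


def _structural_init(
    G: TemporalNetwork,
    H: TemporalNetwork,
    dim: int,
    seed: int,
    scale: float = 1.0,
) -> dict[str, np.ndarray]:
    """Shared deterministic initialization from temporal degree profiles.

    Features of both networks are z-scored jointly (one coordinate frame)
    and pushed through a single seeded random projection, so nodes with
    matching topological evolution start at nearby embeddings regardless
    of their identifiers.
    """
    nodes_g, fg = _temporal_degree_features(G)
    nodes_h, fh = _temporal_degree_features(H)
    stacked = np.vstack([fg, fh])
    mu = stacked.mean(axis=0)
    sd = stacked.std(axis=0)
    sd[sd == 0] = 1.0
    z = (stacked - mu) / sd
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    P = rng.normal(size=(z.shape[1], dim)) / np.sqrt(z.shape[1])
    proj = z @ P
    rms = np.sqrt((proj ** 2).sum(axis=1).mean())
    if rms > 0:
        proj *= scale / rms
    out: dict[str, np.ndarray] = {}
    for i, n in enumerate(nodes_g):
        out[f"G::{n}"] = proj[i].astype(np.float32)
    for j, n in enumerate(nodes_h):
        out[f"H::{n}"] = proj[len(nodes_g) + j].astype(np.float32)
    return out


def joint_temporal_embedding(
    G: TemporalNetwork,
    H: TemporalNetwork,
    walk_params: WalkParams | None = None,
    sg_params: SGParams | None = None,
) -> tuple[EmbeddingState, EmbeddingState]:
    """Embed two dynamic networks into one shared vector space.

    At every time point the walk corpora of G and H (tokens prefixed
    ``G::`` / ``H::`` to keep the vocabularies disjoint) are concatenated,
    shuffled and used to train a single skip-gram model initialized from
    the previous joint state; fresh rows come from the shared structural
    initialization.  The returned states are the per-network slices of the
    final joint state, so cosine similarities across networks are
    meaningful.
    """
    walk_params = walk_params or WalkParams()
    sg_params = sg_params or SGParams()
    if G.n_timepoints != H.n_timepoints:
        raise ValueError(
            f"unequal time points: G has {G.n_timepoints}, H has {H.n_timepoints}"
        )
    if G.n_events == 0 or H.n_events == 0:
        raise ValueError("no trainable content: a network has no events")
    T = G.n_timepoints
    init_vectors = _structural_init(G, H, sg_params.dim, sg_params.seed)
    seeds = _child_seeds(sg_params.seed, 4 * T)
    state: EmbeddingState | None = None
    for t in range(T):
        cg = sample_walks(G.snapshot(t), walk_params, seed=seeds[4 * t])
        ch = sample_walks(H.snapshot(t), walk_params, seed=seeds[4 * t + 1])
        walks = [["G::" + n for n in w] for w in cg.walks]
        walks += [["H::" + n for n in w] for w in ch.walks]
        shuffle_rng = np.random.default_rng(
            np.random.SeedSequence(seeds[4 * t + 2])
        )
        shuffle_rng.shuffle(walks)
        corpus = WalkCorpus(walks, walk_params)
        sgp = replace(sg_params, seed=seeds[4 * t + 3])
        state = train_skipgram(
            corpus, sgp, initial=state, init_fn=init_vectors.get
        )
        state.meta["t"] = t
    emb_g = state.subset("G::")
    emb_h = state.subset("H::")
    return emb_g, emb_h
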