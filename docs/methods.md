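# Methods

## Data model

A dynamic network is an ordered sequence of `T` undirected simple graphs
(snapshots) over one node universe; the elementary record is the event
`(u, v, t)`, an interaction active at integer time point `t ∈ [0, T−1]`.
Nodes may be silent (degree 0) in any snapshot without leaving the
universe — noise injection can silence a node without deleting it, and
every node must stay in the embedding vocabulary at every time point so
that its state can be carried forward. The on-disk format is a plain TSV
(`u<TAB>v<TAB>t`) with an optional `#T=<n>` header (preserves empty
snapshots) and `#node <id>` headers (preserves event-less nodes); reading
back a written file reproduces nodes, events and `T` exactly. Only
discrete snapshot indices are supported; interval-timestamped, directed or
weighted events are out of scope.

## Synthetic benchmark generator

The generator emulates temporal interactomes at desk scale (the default
configuration — 100 nodes, ≤2 edges attached per incoming node, 10 time
points — produces ≈200 edges per snapshot, the density regime of small
yeast PPI subnetworks).

* **Seed snapshot**: Barabási–Albert graph, so the degree distribution is
  scale-free and every node has at least one link.
* **Evolution**: snapshot `t` is snapshot `t−1` with a uniformly random
  `e_rate` fraction of edges rewired (`k = round(e_rate·|E|)` edges
  removed, `k` fresh pairs added, excluding self-loops, duplicates and the
  previous snapshot's edges). Edge count is conserved exactly, so `e_rate`
  cleanly parameterizes the conserved-edge fraction between consecutive
  snapshots: `1 − e_rate` up to rounding (94.9% at the default
  `e_rate = 0.05`, |E| = 196). Rewiring conserves edge count only, not the
  degree sequence.
* **Counterpart**: the source network G is the per-snapshot induced
  subnetwork of H on `keep_nodes` uniformly sampled nodes, then each
  snapshot is rewired by a `delta` fraction. G keeps H's node
  identifiers, so the ground-truth alignment is the namesake (identity)
  mapping. With all nodes kept, the per-snapshot edge overlap between G
  and H is `1 − delta` (89.8% at the default `delta = 0.10`).
* **Similarity metrics**: `conserved_edge_fraction` = |E₁∩E₂|/max(|E₁|,|E₂|)
  is the calibration metric (it equals the rewiring retention rate);
  the symmetric Jaccard |E₁∩E₂|/|E₁∪E₂| is also provided
  (`snapshot_similarity`) but charges each rewired edge twice, giving
  (1−e)/(1+e) under count-conserving rewiring.
* **Noise regimes** for robustness sweeps: `edges` removes a fraction of
  individual `(u,v,t)` triples (interactions persist, degraded at random
  time points); `events` removes a fraction of distinct interactions with
  all their occurrences (harsher). Removal counts are exact
  (`round(level · population)`); the node universe is unchanged.

All randomness descends from one integer seed through per-operation
`SeedSequence` streams, so every experiment is reproducible bit for bit.

What the generator does **not** emulate: real interactomes have assay
biases, correlated (not uniform) edge turnover, node birth/death, and
hub-biased noise. Passing the synthetic benchmarks therefore demonstrates
correctness of the machinery and robustness to uniform perturbation, not
performance on real interactome pairs.

## Temporal embedding

Per snapshot, a corpus of second-order (node2vec) random walks is sampled:
`walks_per_node` walks of `walk_length` steps from every non-isolated
node; return bias `1/p`, in-out bias `1/q`; isolated nodes contribute
singleton walks. With the default `p = q = 1` the walk is the uniform
first-order walk and sampling takes a fast path.

The skip-gram model (one hidden layer of size `dim`, no activation,
negative sampling as the tractable surrogate of the softmax output) is
trained on the corpus by a sequential, single-threaded numba kernel —
deterministic for a fixed seed, including its internal xorshift64* negative
-sampling stream. Training pairs are all (center, context) token pairs
within the rolling `window`; the learning rate decays linearly from
`alpha` to `min_alpha` over `epochs` passes.

**Temporal integration.** The model accepts an initial state: rows of the
input-embedding matrix whose token exists in the previous time point's
state start from that carried vector (nodes only in the old state are
discarded; genuinely new nodes are freshly initialized). Two properties
pin this design down: with `epochs = 0` and full coverage the output
equals the initial state exactly, and with an empty initial state the run
is a standard skip-gram training. On top of the carried initialization,
an **elastic anchor** pulls each updated row back toward its initial
vector (strength `anchor`, applied per update, scaled by the current
learning rate): each round is thereby a refinement of the carried state
rather than a rewrite, which is what makes the final state reflect the
maintenance of features across the whole snapshot sequence. `anchor = 0`
recovers plain skip-gram.

## Joint (cross-network) embedding

Two independently trained embedding spaces are incomparable (any rotation
of one leaves its training loss unchanged), so similarities across
networks require a common frame. Two mechanisms provide it:

1. **Joint training**: at each time point one model is trained on the
   concatenated corpora of both networks, tokens prefixed `G::`/`H::` so
   the vocabularies stay disjoint (no walk ever mixes prefixes).
2. **Shared structural initialization**: fresh rows are seeded from each
   node's temporal degree profile — `log1p` of its degree and of its mean
   neighbour degree in every snapshot (2T features), z-scored jointly
   over the nodes of both networks and projected through one shared
   seeded Gaussian matrix, scaled to unit root-mean-square row norm.
   Nodes whose topology evolves alike therefore *start* at nearby
   coordinates regardless of their identifiers, and the anchored training
   keeps the two halves of the space coupled while refining each network's
   internal geometry.

The anchor strength is what balances the two information sources: without
it, walk-sampling noise (independent between the networks) accumulates
and washes out the correspondence; with it very large, training adds
nothing beyond the degree profiles. The default `anchor = 3.0` was fixed
during design prototyping on relabeled-copy recovery at the benchmark
configuration and is deliberately on the conservative side.

After the last time point the per-network slices of the joint state are
returned; the mean of a node's projection weight vectors is the vector
itself, since one vector per node is kept (the final state).

## Similarity and matching

The similarity matrix holds the cosine of every (v, u) pair in float64;
zero-norm rows (possible only for never-trained, never-initialized
vectors) score 0 by convention, with a warning. Per-node descending
similarity lists are available (`ranked_matches`).

The mapping is built by **iterative global maximization**: all |V|·|U|
pairs are ordered by descending score (ties broken lexicographically on
(v, u) for determinism) and swept once, assigning a pair whenever both
endpoints are free. Assigned scores are non-increasing in assignment
order, every source node is matched (|V| ≤ |U| is required; callers are
told to swap otherwise), and the mapping is injective. A maximum-weight
bipartite assignment (`scipy` Hungarian) is offered behind
`method="optimal"`; it maximizes the total score, whereas the greedy sweep
maximizes each prefix of the assignment sequence — the greedy is the
default because it directly realizes the no-later-pair-scores-higher
condition.

Empirically the injective matching is load-bearing: embedding drift is
largely a shared, hub-directed shift, so the raw per-row argmax collides
many peripheral nodes onto hubs (top-1 recovery ≈ 50–70% on exact
relabeled copies at desk scale) while the global sweep resolves these
collisions almost completely (node correctness ≈ 0.95–1.0).

## Evaluation

Candidate pairs are the Cartesian product V × U. TP: aligned and true;
FP: aligned and false; FN: a true pair left unaligned; TN: the remainder
— the four counts always sum to |V|·|U|. NC = TP/|V|; when |V| = |U| and
the truth is total, NC = TPR. The noise sweep aligns a base network
against freshly perturbed copies of itself (per level and repeat),
averages NC/TPR/FPR over repeats, and summarizes the per-level
(FPR, TPR) points as a ROC curve: deduplicated, sorted, anchored at
(0,0)/(1,1), integrated by the trapezoidal rule. A simple moving average
is provided for trend analysis of NC series.

## Problem sizes and numerical choices

The shipped tests and sweeps run at desk scale, chosen as the smallest
sizes at which the benchmark's qualitative behavior is stable: 50-node /
5-time-point pairs for recovery checks, a 100-node / 8-time-point base
with 5 repeats per level for the 0–30% noise sweeps, and reduced training
settings (`dim = 64`, 5 walks × 20 steps, 3 epochs) that leave recovery
at zero noise ≥ 0.9 NC. The library defaults (`dim = 128`, 10 walks × 80
steps, 5 epochs, `window = 5`, 5 negatives) follow the established
word2vec/node2vec practice and suit larger networks. Logits in the kernel
are clamped to ±6 (classic sigmoid-table range); embeddings are float32,
similarities float64.

## Known limitations

* **Subset alignment is near its information floor.** When G is an
  induced subnetwork on a fraction of H's nodes, each kept node loses a
  random share of its neighbourhood, and the degree profiles that anchor
  the shared space decorrelate; for the mostly degree-2 periphery of
  scale-free benchmarks, topology alone then carries little identifying
  signal, and NC drops sharply (e.g. ≈0.1 at keep = 50%, delta = 0.10).
  The full mapping is still produced and scored honestly.
* Both networks must have the same number of time points (equal evolution
  rate is assumed); there is no time warping.
* The aligner is topology-only by design: no sequence homology or
  attribute similarity enters the score.
* Non-determinism enters only through seeds; training is single-threaded.
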