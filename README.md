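# dynalign

Pairwise **global alignment of dynamic networks** — graphs whose edge set
evolves over discrete time points, such as temporal protein–protein
interaction networks. Given a source network *G(V, E₁)* and a target
network *H(U, E₂)* (|V| ≤ |U|), each represented as an ordered sequence of
snapshots, `dynalign` produces an injective node mapping *f : V → U* that
matches nodes playing the same topological role *over time*. The typical
use case is transferring knowledge between species: aligning a
well-characterized interactome onto a larger, less annotated one.

## Method

1. **Temporal embedding.** Every snapshot is turned into a corpus of
   node2vec-style random walks and fed to a skip-gram model with hidden
   layer size *N*, rolling window *w* and negative sampling. The model is
   extended with an *initial state*: the input-embedding rows of nodes
   present in both the current vocabulary and the previous time point's
   embeddings start from (and are elastically anchored to) those carried
   vectors, so the final state after snapshot *T−1* reflects the whole
   temporal evolution. For the first time point the previous state is
   empty.
2. **Shared space.** The two networks are embedded jointly: at each time
   point one model is trained on the concatenated (prefix-disambiguated)
   corpora of both networks, with fresh vectors seeded from temporal
   degree profiles through a single shared random projection, so that
   cross-network cosine similarities are meaningful.
3. **Similarity matrix.** φ(v, u) = cosine similarity between the vectors
   of v ∈ V and u ∈ U, for all |V| × |U| pairs.
4. **Alignment.** Iterative global score maximization: repeatedly assign
   the globally best unassigned pair (v, u), so that no later assignment
   scores at least as high as an earlier one (collision handling by global
   maximization). An optimal bipartite assignment is available with
   `--matcher optimal`.

The package also ships the synthetic benchmark generator (Barabási–Albert
seed snapshot, per-step edge rewiring at the evolution rate *e-rate*,
counterpart divergence *delta*, namesake ground truth) and the evaluation
layer: node correctness (NC = TP/|V|), confusion counts over the Cartesian
product V × U, noise sweeps and ROC/AUC summaries.

## Worked example

```sh
$ dynalign generate --nodes 50 --timepoints 5 --seed 7
wrote G.tsv, H.tsv, truth.tsv

$ dynalign align G.tsv H.tsv --dim 64 --walks 5 --walk-length 20 --epochs 3 --seed 7
aligned 50 nodes, total score 25.522; wrote alignment.tsv

$ dynalign evaluate --alignment alignment.tsv --truth truth.tsv
TP=27 FP=23 TN=2427 FN=23
NC=0.5400 TPR=0.5400 FPR=0.0094
```

`generate` builds a 50-node, 5-time-point pair whose two networks diverge
by 10% per snapshot (`--delta 0.10`, the default) and writes the namesake
ground truth. `align` embeds both networks into one space and maps every
source node to a distinct target node; `alignment.tsv` lists the pairs
with their cosine scores, best first. `evaluate` scores the mapping
against the truth: 27 of 50 nodes were mapped to their true counterparts
(NC = 0.54) — at 10% topological divergence roughly half of the mostly
degree-2 periphery becomes structurally ambiguous, while the false
positive rate over the 2500 candidate pairs stays below 1%. With
`--delta 0` the same pipeline recovers essentially all nodes (NC ≈ 1).

The same pipeline is available as a library:

```python
from dynalign import (GeneratorConfig, generate_pair, align_networks,
                      node_correctness, WalkParams, SGParams)

pair = generate_pair(GeneratorConfig(n_nodes=50, n_timepoints=5, seed=7))
aln = align_networks(pair.G, pair.H,
                     WalkParams(walks_per_node=5, walk_length=20),
                     SGParams(dim=64, epochs=3, seed=7))
print(node_correctness(aln, pair.truth))
```

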