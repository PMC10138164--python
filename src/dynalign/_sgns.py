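"""Numba kernel for skip-gram training with negative sampling.

Single-threaded and fully deterministic given the seed: walk order, window
scanning and the internal xorshift64* stream are all sequential.  The
kernel updates the input-embedding matrix W and the output matrix C in
place; the input rows are the node embeddings.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_EXP = 6.0  # logits are clamped to +-6 as in the classic implementation


@njit(cache=True, inline="always")
def _next_u64(state):
    # xorshift64* PRNG; state must stay nonzero
    state ^= state >> 12
    state ^= (state << 25) & np.uint64(0xFFFFFFFFFFFFFFFF)
    state ^= state >> 27
    return (state * np.uint64(2685821657736338717)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    ), state


@njit(cache=True)
def train_sgns(
    tokens,  # int32[n_tokens] corpus as vocabulary indices
    offsets,  # int64[n_walks + 1] walk boundaries into tokens
    W,  # float32[V, dim] input embeddings (updated in place)
    C,  # float32[V, dim] output embeddings (updated in place)
    window,  # int
    negative,  # int
    neg_cdf,  # float64[V] cumulative unigram^0.75 distribution
    alpha0,  # float initial learning rate
    min_alpha,  # float final learning rate
    epochs,  # int
    seed,  # uint64
    W0,  # float32[V, dim] anchor state (ignored when anchor == 0)
    anchor,  # float >= 0: pull strength toward W0 per center update
):
    dim = W.shape[1]
    n_tokens = tokens.shape[0]
    total = max(1, epochs * n_tokens)
    processed = 0
    state = np.uint64(seed * 6364136223846793005 + 1442695040888963407)
    if state == np.uint64(0):
        state = np.uint64(88172645463325252)
    grad = np.empty(dim, dtype=np.float32)
    V = W.shape[0]
    for _ in range(epochs):
        for w in range(offsets.shape[0] - 1):
            start = offsets[w]
            end = offsets[w + 1]
            for i in range(start, end):
                alpha = alpha0 - (alpha0 - min_alpha) * (processed / total)
                processed += 1
                center = tokens[i]
                lo = i - window
                if lo < start:
                    lo = start
                hi = i + window + 1
                if hi > end:
                    hi = end
                for j in range(lo, hi):
                    if j == i:
                        continue
                    target = tokens[j]
                    # one positive pair + `negative` sampled negatives
                    for d in range(dim):
                        grad[d] = 0.0
                    for s in range(negative + 1):
                        if s == 0:
                            out = target
                            label = 1.0
                        else:
                            r, state = _next_u64(state)
                            u = (np.float64(r) + 1.0) / 18446744073709551616.0
                            # binary search the cumulative distribution
                            a = 0
                            b = V - 1
                            while a < b:
                                m = (a + b) // 2
                                if neg_cdf[m] < u:
                                    a = m + 1
                                else:
                                    b = m
                            out = a
                            if out == target:
                                continue
                            label = 0.0
                        dot = 0.0
                        for d in range(dim):
                            dot += W[center, d] * C[out, d]
                        if dot > _MAX_EXP:
                            f = 1.0
                        elif dot < -_MAX_EXP:
                            f = 0.0
                        else:
                            f = 1.0 / (1.0 + np.exp(-dot))
                        g = (label - f) * alpha
                        for d in range(dim):
                            grad[d] += g * C[out, d]
                            C[out, d] += g * W[center, d]
                    for d in range(dim):
                        W[center, d] += grad[d]
                    if anchor > 0.0:
                        # elastic pull toward the carried state: keeps the
                        # current round a refinement of, not a rewrite of,
                        # the temporal/structural anchor
                        ga = anchor * alpha
                        for d in range(dim):
                            W[center, d] += ga * (W0[center, d] - W[center, d])
    return W
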