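"""Numba inner loops for skip-gram training and collapsed Gibbs sampling.

Both kernels are strictly sequential and draw from numpy's legacy global
RNG seeded inside the jitted function, so a (seed, input) pair fully
determines the output on any machine.
"""

import numpy as np
from numba import njit

_MAX_EXP = 6.0


@njit(cache=False)
def _sigmoid(x):
    if x > _MAX_EXP:
        return 1.0
    if x < -_MAX_EXP:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=False)
def sgns_train(tokens, offsets, w_in, w_out, neg_table, window, negative,
               epochs, lr0, seed):
    """Train skip-gram with negative sampling in place.

    tokens: int32 token ids for the whole corpus, sentence-concatenated.
    offsets: int64 sentence boundaries, len = n_sentences + 1.
    w_in / w_out: (V, dim) float64 input and output matrices, updated in place.
    neg_table: int32 unigram^0.75 sampling table.
    """
    np.random.seed(seed)
    dim = w_in.shape[1]
    n_sent = offsets.shape[0] - 1
    total = np.float64(epochs * tokens.shape[0])
    processed = 0.0
    grad = np.empty(dim, np.float64)
    tbl = neg_table.shape[0]
    for _ in range(epochs):
        for s in range(n_sent):
            start = offsets[s]
            end = offsets[s + 1]
            for pos in range(start, end):
                lr = lr0 * (1.0 - processed / total)
                if lr < lr0 * 1e-4:
                    lr = lr0 * 1e-4
                processed += 1.0
                center = tokens[pos]
                b = 1 + np.random.randint(window)  # dynamic window in [1, window]
                for off in range(-b, b + 1):
                    ctx_pos = pos + off
                    if off == 0 or ctx_pos < start or ctx_pos >= end:
                        continue
                    ctx = tokens[ctx_pos]
                    for d in range(dim):
                        grad[d] = 0.0
                    for k in range(negative + 1):
                        if k == 0:
                            target = ctx
                            label = 1.0
                        else:
                            target = neg_table[np.random.randint(tbl)]
                            if target == ctx:
                                continue
                            label = 0.0
                        z = 0.0
                        for d in range(dim):
                            z += w_in[center, d] * w_out[target, d]
                        g = (label - _sigmoid(z)) * lr
                        for d in range(dim):
                            grad[d] += g * w_out[target, d]
                            w_out[target, d] += g * w_in[center, d]
                    for d in range(dim):
                        w_in[center, d] += grad[d]


@njit(cache=False)
def lda_gibbs(doc_ids, words, n_docs, n_vocab, n_topics, alpha, beta,
              iterations, seed):
    """Collapsed Gibbs sampler for LDA.

    doc_ids / words: int32 arrays, one entry per token occurrence.
    Returns (ndk, nkw, z) count matrices and final topic assignments.
    """
    np.random.seed(seed)
    n = words.shape[0]
    ndk = np.zeros((n_docs, n_topics), np.int64)
    nkw = np.zeros((n_topics, n_vocab), np.int64)
    nk = np.zeros(n_topics, np.int64)
    z = np.empty(n, np.int64)
    for i in range(n):
        k = np.random.randint(n_topics)
        z[i] = k
        ndk[doc_ids[i], k] += 1
        nkw[k, words[i]] += 1
        nk[k] += 1
    cum = np.empty(n_topics, np.float64)
    vb = n_vocab * beta
    for _ in range(iterations):
        for i in range(n):
            d = doc_ids[i]
            w = words[i]
            k = z[i]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            acc = 0.0
            for kk in range(n_topics):
                acc += (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + vb)
                cum[kk] = acc
            u = np.random.random() * acc
            k = 0
            while k < n_topics - 1 and cum[k] < u:
                k += 1
            z[i] = k
            ndk[d, k] += 1
            nkw[k, w] += 1
            nk[k] += 1
    return ndk, nkw, z
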