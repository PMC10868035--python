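"""Minimal single-threaded word2vec (SGNS / CBOW) on integer token lists.

Small-corpus implementation tailored to visit "documents" of medical codes:
a few hundred to a few thousand short sentences over a vocabulary of
hundreds to thousands of tokens. Deterministic for a fixed seed (one
worker, one RNG stream). Input vectors are returned as the embedding.

Negative sampling uses the standard unigram^0.75 noise distribution; the
learning rate decays linearly over the scheduled number of center-word
updates, with a floor at 1e-4 of the initial rate.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def train_word2vec(
    sentences: list[list[int]],
    vocab_size: int,
    dim: int,
    method: str = "sgns",
    epochs: int = 20,
    window: int | None = None,
    negatives: int = 5,
    lr: float = 0.05,
    shuffle_within_sentence: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Train embeddings; returns a (vocab_size, dim) array.

    ``window=None`` means full-sentence context (tokens carry no intra-visit
    order). Tokens never observed keep a zero vector.
    """
    if not sentences or all(len(s) == 0 for s in sentences):
        raise ValueError("empty corpus")
    rng = np.random.default_rng(seed)

    counts = np.zeros(vocab_size, dtype=float)
    for s in sentences:
        for tok in s:
            counts[tok] += 1
    observed = counts > 0
    noise = np.where(observed, counts, 0.0) ** 0.75
    noise /= noise.sum()

    syn0 = np.zeros((vocab_size, dim))
    syn0[observed] = rng.uniform(-0.5 / dim, 0.5 / dim, size=(int(observed.sum()), dim))
    syn1 = np.zeros((vocab_size, dim))

    total_centers = max(1, epochs * sum(len(s) for s in sentences))
    lr0 = lr
    done = 0
    for _epoch in range(epochs):
        for sent in sentences:
            if not sent:
                continue
            toks = np.array(sent, dtype=int)
            if shuffle_within_sentence and len(toks) > 1:
                toks = toks[rng.permutation(len(toks))]
            n = len(toks)
            for i in range(n):
                alpha = max(lr0 * (1 - done / total_centers), lr0 * 1e-4)
                done += 1
                if window is None:
                    lo, hi = 0, n
                else:
                    b = int(rng.integers(1, window + 1))  # dynamic window
                    lo, hi = max(0, i - b), min(n, i + b + 1)
                ctx = np.concatenate([toks[lo:i], toks[i + 1 : hi]])
                if ctx.size == 0:
                    continue
                center = int(toks[i])
                if method == "sgns":
                    # predict each context word from the center word
                    for c in ctx:
                        targets = np.empty(1 + negatives, dtype=int)
                        targets[0] = c
                        targets[1:] = rng.choice(vocab_size, size=negatives, p=noise)
                        labels = np.zeros(1 + negatives)
                        labels[0] = 1.0
                        h = syn0[center]
                        g = (labels - _sigmoid(syn1[targets] @ h)) * alpha
                        syn0[center] = h + g @ syn1[targets]
                        np.add.at(syn1, targets, np.outer(g, h))
                elif method == "cbow":
                    # predict the center word from the mean context vector
                    h = syn0[ctx].mean(axis=0)
                    targets = np.empty(1 + negatives, dtype=int)
                    targets[0] = center
                    targets[1:] = rng.choice(vocab_size, size=negatives, p=noise)
                    labels = np.zeros(1 + negatives)
                    labels[0] = 1.0
                    g = (labels - _sigmoid(syn1[targets] @ h)) * alpha
                    grad_h = g @ syn1[targets]
                    np.add.at(syn1, targets, np.outer(g, h))
                    np.add.at(syn0, ctx, np.broadcast_to(grad_h / len(ctx), (len(ctx), dim)))
                else:
                    raise ValueError(f"unknown method: {method!r}")
    return syn0
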