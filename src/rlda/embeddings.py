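"""Skip-gram word embeddings with negative sampling.

Trains one embedding space per (year-)corpus: a center word predicts each
context word within a window, optimized by stochastic gradient descent on the
negative-sampling objective

    log sigma(u_c . v_w)  +  sum_{j=1..neg} E_{c'~P_n} log sigma(-u_c' . v_w)

with the noise distribution P_n proportional to unigram frequency^0.75.
Training is single-threaded and fully deterministic given the seed.  All
topic-level analyses for a year must use that year's table so every topic
lives in one semantic space.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from numba import njit

from .preprocess import TokenizedCorpus

__all__ = ["EmbeddingTable", "train_skipgram", "OOV"]

#: Sentinel returned by lookups of out-of-vocabulary words.
OOV = None


class EmbeddingTable:
    """word -> dense vector map with an explicit out-of-vocabulary policy."""

    def __init__(self, words: list[str], vectors: np.ndarray):
        if vectors.ndim != 2 or len(words) != vectors.shape[0]:
            raise ValueError("vectors must be (n_words, dim)")
        norms = np.linalg.norm(vectors, axis=1)
        if len(words) and (norms == 0).any():
            raise ValueError("zero-norm vector for in-vocabulary word")
        self.words = list(words)
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self._index = {w: i for i, w in enumerate(words)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def lookup(self, word: str):
        """Return the word's vector, or the OOV marker (None) — never a
        silent zero vector."""
        i = self._index.get(word)
        return None if i is None else self.vectors[i]

    def coverage(self, words: list[str]) -> float:
        """Fraction of ``words`` present in the table (vocabulary audit)."""
        if not words:
            return 1.0
        return sum(w in self._index for w in words) / len(words)

    def save(self, path: str | Path) -> None:
        """Write word2vec text format: header 'count dim', then word + floats."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.words)} {self.dim}\n")
            for w, vec in zip(self.words, self.vectors):
                fh.write(w + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingTable":
        with Path(path).open(encoding="utf-8") as fh:
            n, dim = map(int, fh.readline().split())
            words, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                words.append(parts[0])
                rows.append([float(x) for x in parts[1 : dim + 1]])
        if len(words) != n:
            raise ValueError("embedding file truncated")
        return cls(words, np.asarray(rows))


@njit(cache=True)
def _sgns_epoch(tokens, starts, vin, vout, window, n_neg, lr0, lr1, epoch_frac0,
                epoch_frac1, neg_table, win_draws, neg_draws):  # pragma: no cover
    dim = vin.shape[1]
    n_tok = tokens.shape[0]
    n_pairs = 0
    pos = 0
    for s in range(starts.shape[0] - 1):
        lo, hi = starts[s], starts[s + 1]
        for i in range(lo, hi):
            w = tokens[i]
            # word2vec-style dynamic window: uniform in [1, window]
            b = 1 + int(win_draws[pos] * window)
            if b > window:
                b = window
            # linear decay from lr0 to lr1 across all epochs
            frac = epoch_frac0 + (epoch_frac1 - epoch_frac0) * pos / n_tok
            lr = lr0 + (lr1 - lr0) * frac
            jlo = i - b if i - b > lo else lo
            jhi = i + b + 1 if i + b + 1 < hi else hi
            for j in range(jlo, jhi):
                if j == i:
                    continue
                c = tokens[j]
                # positive update on (center=w, context=c) plus negatives
                grad_in = np.zeros(dim)
                vw = vin[w]
                for neg in range(n_neg + 1):
                    if neg == 0:
                        target = c
                        label = 1.0
                    else:
                        target = neg_table[
                            int(neg_draws[(pos * (n_neg + 1) + neg) % neg_draws.shape[0]]
                                * neg_table.shape[0])
                        ]
                        if target == c:
                            continue
                        label = 0.0
                    dot = 0.0
                    for d in range(dim):
                        dot += vw[d] * vout[target, d]
                    if dot > 8.0:
                        sig = 1.0
                    elif dot < -8.0:
                        sig = 0.0
                    else:
                        sig = 1.0 / (1.0 + np.exp(-dot))
                    g = (label - sig) * lr
                    for d in range(dim):
                        grad_in[d] += g * vout[target, d]
                        vout[target, d] += g * vw[d]
                for d in range(dim):
                    vin[w, d] += grad_in[d]
                n_pairs += 1
            pos += 1
    return n_pairs


def train_skipgram(
    corpus: TokenizedCorpus,
    dim: int = 100,
    window: int = 5,
    negative_samples: int = 5,
    epochs: int = 5,
    min_count: int = 1,
    seed: int = 0,
    learning_rate: float = 0.025,
) -> EmbeddingTable:
    """Train skip-gram embeddings on a tokenized corpus.

    Words below ``min_count`` are removed before training (and absent from
    the returned table).  The learning rate decays linearly from
    ``learning_rate`` to 1e-4 of it across all epochs.
    """
    if corpus.M == 0 or sum(corpus.N) == 0:
        raise ValueError("corpus is empty")
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if window < 1:
        raise ValueError("window must be >= 1")

    counts = np.zeros(corpus.V, dtype=np.int64)
    for seq in corpus.docs:
        np.add.at(counts, np.asarray(seq, dtype=np.int64), 1)
    keep = np.flatnonzero(counts >= min_count)
    if keep.size == 0:
        raise ValueError("no word reaches min_count")
    remap = -np.ones(corpus.V, dtype=np.int64)
    remap[keep] = np.arange(keep.size)
    words = [corpus.vocabulary[i] for i in keep]

    seqs = []
    for seq in corpus.docs:
        arr = remap[np.asarray(seq, dtype=np.int64)]
        arr = arr[arr >= 0]
        if arr.size:
            seqs.append(arr)
    if not seqs:
        raise ValueError("corpus empty after min_count filtering")
    tokens = np.concatenate(seqs)
    starts = np.zeros(len(seqs) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in seqs], out=starts[1:])

    # unigram^0.75 negative-sampling table
    freq = counts[keep].astype(np.float64) ** 0.75
    probs = freq / freq.sum()
    table_size = 100_000
    neg_table = np.searchsorted(np.cumsum(probs), np.arange(table_size) / table_size,
                                side="right").astype(np.int64)
    neg_table = np.minimum(neg_table, keep.size - 1)

    rng = np.random.default_rng(seed)
    n_words = keep.size
    vin = (rng.random((n_words, dim)) - 0.5) / dim
    vout = np.zeros((n_words, dim))

    n_tok = tokens.shape[0]
    for epoch in range(epochs):
        win_draws = rng.random(n_tok)
        neg_draws = rng.random(n_tok * (negative_samples + 1))
        f0 = epoch / epochs
        f1 = (epoch + 1) / epochs
        _sgns_epoch(tokens, starts, vin, vout, window, negative_samples,
                    learning_rate, learning_rate * 1e-4, f0, f1,
                    neg_table, win_draws, neg_draws)

    # guard against pathological all-zero rows (never updated words)
    norms = np.linalg.norm(vin, axis=1)
    vin[norms == 0] += 1e-8
    return EmbeddingTable(words, vin)
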