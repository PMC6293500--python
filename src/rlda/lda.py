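"""Latent Dirichlet allocation estimated by collapsed Gibbs sampling.

The model: each topic k is a distribution phi_k over the vocabulary drawn
from a symmetric Dirichlet(beta) prior; each document m mixes topics with
weights theta_m drawn from Dirichlet(alpha); each token first draws a topic
assignment z from theta_m and then a word from phi_z.  With theta and phi
integrated out, the collapsed Gibbs sampler resamples each token's topic from

    p(z = k | rest)  ∝  (n_doc_topic[m,k] + alpha)
                       * (n_topic_word[k,w] + beta) / (n_topic[k] + V*beta)

where the counts exclude the token being resampled.  Point estimates are
taken from the final sweep:

    phi[k,w]   = (n_topic_word[k,w] + beta) / (n_topic[k] + V*beta)
    theta[m,k] = (n_doc_topic[m,k] + alpha) / (N_m + K*alpha)

Usage follows the model/results convention::

    model = LatentDirichletAllocation(corpus, n_topics=100)
    res = model.fit(iterations=500, seed=0)
    res.top_words(20)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .preprocess import TokenizedCorpus

__all__ = ["LDAConfig", "LatentDirichletAllocation", "LDAResults", "TopicWordTable"]


@dataclass(frozen=True)
class LDAConfig:
    """Sampler settings.

    ``alpha`` defaults to 5/K (the usual convention); ``beta`` to 0.01.
    ``top_w`` is the number of words kept per topic in the topic-word table.
    """

    n_topics: int = 100
    alpha: float | None = None
    beta: float = 0.01
    iterations: int = 500
    top_w: int = 20

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.top_w < 1:
            raise ValueError("top_w must be >= 1")

    @property
    def effective_alpha(self) -> float:
        return 5.0 / self.n_topics if self.alpha is None else self.alpha


@njit(cache=True)
def _gibbs_sweeps(doc_ids, word_ids, z, n_doc_topic, n_topic_word, n_topic,
                  alpha, beta, n_sweeps, uniforms):  # pragma: no cover - numba
    n_tokens = word_ids.shape[0]
    K = n_topic.shape[0]
    V = n_topic_word.shape[1]
    Vbeta = V * beta
    probs = np.empty(K)
    for sweep in range(n_sweeps):
        for t in range(n_tokens):
            m = doc_ids[t]
            w = word_ids[t]
            k_old = z[t]
            n_doc_topic[m, k_old] -= 1
            n_topic_word[k_old, w] -= 1
            n_topic[k_old] -= 1
            total = 0.0
            for k in range(K):
                p = (n_doc_topic[m, k] + alpha) * (n_topic_word[k, w] + beta) / (
                    n_topic[k] + Vbeta
                )
                total += p
                probs[k] = total
            u = uniforms[sweep, t] * total
            k_new = 0
            while probs[k_new] < u:
                k_new += 1
            z[t] = k_new
            n_doc_topic[m, k_new] += 1
            n_topic_word[k_new, w] += 1
            n_topic[k_new] += 1


class LatentDirichletAllocation:
    """LDA model over a tokenized corpus.

    Parameters
    ----------
    corpus : TokenizedCorpus
        Token-id sequences over an ordered vocabulary.
    n_topics, alpha, beta, iterations, top_w :
        See :class:`LDAConfig`; ``alpha=None`` means 5/n_topics.
    """

    def __init__(self, corpus: TokenizedCorpus, n_topics: int = 100,
                 alpha: float | None = None, beta: float = 0.01,
                 iterations: int = 500, top_w: int = 20):
        if corpus.M == 0 or corpus.V == 0 or sum(corpus.N) == 0:
            raise ValueError("corpus is empty")
        self.corpus = corpus
        self.config = LDAConfig(n_topics=n_topics, alpha=alpha, beta=beta,
                                iterations=iterations, top_w=top_w)

    def fit(self, seed: int = 0) -> "LDAResults":
        """Run the collapsed Gibbs sampler and return final-sweep estimates."""
        cfg = self.config
        K = cfg.n_topics
        alpha = cfg.effective_alpha
        corpus = self.corpus
        V = corpus.V

        doc_ids = np.concatenate(
            [np.full(len(seq), m, dtype=np.int64) for m, seq in enumerate(corpus.docs)]
        )
        word_ids = np.concatenate(
            [np.asarray(seq, dtype=np.int64) for seq in corpus.docs]
        )
        n_tokens = word_ids.shape[0]

        rng = np.random.default_rng(seed)
        z = rng.integers(0, K, size=n_tokens).astype(np.int64)

        n_doc_topic = np.zeros((corpus.M, K), dtype=np.int64)
        n_topic_word = np.zeros((K, V), dtype=np.int64)
        n_topic = np.zeros(K, dtype=np.int64)
        np.add.at(n_doc_topic, (doc_ids, z), 1)
        np.add.at(n_topic_word, (z, word_ids), 1)
        np.add.at(n_topic, z, 1)

        # Uniform draws are pre-generated outside the kernel so determinism
        # depends only on numpy's seeded Generator.  Sweeps run in blocks to
        # bound the random buffer at ~8 MB.
        block = max(1, min(cfg.iterations, int(1e6) // max(1, n_tokens) + 1))
        done = 0
        while done < cfg.iterations:
            n_sweeps = min(block, cfg.iterations - done)
            uniforms = rng.random((n_sweeps, n_tokens))
            _gibbs_sweeps(doc_ids, word_ids, z, n_doc_topic, n_topic_word,
                          n_topic, alpha, cfg.beta, n_sweeps, uniforms)
            done += n_sweeps

        return LDAResults(model=self, z=z, doc_ids=doc_ids, word_ids=word_ids,
                          n_doc_topic=n_doc_topic, n_topic_word=n_topic_word,
                          n_topic=n_topic, seed=seed)


@dataclass
class TopicWordTable:
    """Per-topic top-W (word, probability) rows, probabilities descending."""

    rows: list[list[tuple[str, float]]]

    @property
    def n_topics(self) -> int:
        return len(self.rows)

    def __getitem__(self, k: int) -> list[tuple[str, float]]:
        return self.rows[k]

    def __iter__(self):
        return iter(self.rows)

    def to_dataframe(self):
        import pandas as pd

        recs = [
            {"topic": k, "rank": r + 1, "word": w, "probability": p}
            for k, row in enumerate(self.rows)
            for r, (w, p) in enumerate(row)
        ]
        return pd.DataFrame(recs, columns=["topic", "rank", "word", "probability"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TopicWordTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        rows: list[list[tuple[str, float]]] = []
        for k, grp in df.sort_values(["topic", "rank"]).groupby("topic"):
            while len(rows) < k:
                rows.append([])
            rows.append([(str(w), float(p)) for w, p in zip(grp["word"], grp["probability"])])
        return cls(rows)


@dataclass
class LDAResults:
    """Fitted sampler state and the derived phi/theta point estimates."""

    model: LatentDirichletAllocation
    z: np.ndarray
    doc_ids: np.ndarray
    word_ids: np.ndarray
    n_doc_topic: np.ndarray
    n_topic_word: np.ndarray
    n_topic: np.ndarray
    seed: int
    _phi: np.ndarray | None = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)

    @property
    def config(self) -> LDAConfig:
        return self.model.config

    @property
    def phi(self) -> np.ndarray:
        """Topic-word probabilities, K x V; rows sum to 1."""
        if self._phi is None:
            beta = self.config.beta
            V = self.n_topic_word.shape[1]
            self._phi = (self.n_topic_word + beta) / (
                self.n_topic[:, None] + V * beta
            )
        return self._phi

    @property
    def theta(self) -> np.ndarray:
        """Document-topic probabilities, M x K; rows sum to 1."""
        if self._theta is None:
            alpha = self.config.effective_alpha
            K = self.n_doc_topic.shape[1]
            N_m = self.n_doc_topic.sum(axis=1)
            self._theta = (self.n_doc_topic + alpha) / (
                N_m[:, None] + K * alpha
            )
        return self._theta

    def check_counts(self) -> None:
        """Raise if the count tables are inconsistent with the assignments."""
        if (self.n_doc_topic < 0).any() or (self.n_topic_word < 0).any():
            raise AssertionError("negative counts")
        if self.n_doc_topic.sum() != self.z.shape[0]:
            raise AssertionError("doc-topic counts do not sum to token count")
        if self.n_topic_word.sum() != self.z.shape[0]:
            raise AssertionError("topic-word counts do not sum to token count")
        if not np.array_equal(self.n_topic_word.sum(axis=1), self.n_topic):
            raise AssertionError("topic totals inconsistent")

    def top_words(self, top_w: int | None = None) -> TopicWordTable:
        """Per-topic top words by phi, descending; ties broken by vocab order.

        If ``top_w`` exceeds the vocabulary size, rows are truncated to V.
        """
        import warnings

        if top_w is None:
            top_w = self.config.top_w
        vocab = self.model.corpus.vocabulary
        V = len(vocab)
        if top_w > V:
            warnings.warn(
                f"top_w={top_w} exceeds vocabulary size {V}; rows truncated",
                stacklevel=2,
            )
            top_w = V
        phi = self.phi
        rows = []
        for k in range(phi.shape[0]):
            # stable sort on -phi keeps vocabulary order among ties
            order = np.argsort(-phi[k], kind="stable")[:top_w]
            rows.append([(vocab[w], float(phi[k, w])) for w in order])
        return TopicWordTable(rows)

    def summary(self) -> str:
        cfg = self.config
        corpus = self.model.corpus
        lines = [
            "Latent Dirichlet Allocation (collapsed Gibbs)",
            "=" * 45,
            f"Documents:            {corpus.M}",
            f"Vocabulary size:      {corpus.V}",
            f"Tokens:               {int(self.n_topic.sum())}",
            f"Topics (K):           {cfg.n_topics}",
            f"alpha:                {cfg.effective_alpha:g}",
            f"beta:                 {cfg.beta:g}",
            f"Gibbs sweeps:         {cfg.iterations}",
            f"Seed:                 {self.seed}",
            "",
            "Top words of the 5 largest topics:",
        ]
        table = self.top_words(min(8, corpus.V))
        sizes = np.argsort(-self.n_topic)[:5]
        for k in sizes:
            words = ", ".join(w for w, _ in table[int(k)])
            lines.append(f"  topic {int(k):3d} (n={int(self.n_topic[k])}): {words}")
        return "\n".join(lines)
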