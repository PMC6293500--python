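"""Ground-truth corpus generator following the LDA generative process.

Documents are sampled exactly as the topic model assumes: per topic a word
distribution phi_k ~ Dirichlet(beta_true), per document a topic mixture
theta_m ~ Dirichlet(alpha_true), then for every token a topic
z ~ Categorical(theta_m) and a word w ~ Categorical(phi_z).  Document lengths
are Poisson.  The vocabulary consists of pronounceable pseudo-words
(consonant-vowel syllables) so the text also exercises the pre-processing
pipeline, where pseudo-words tag as plain nouns.

"Planted" disease topics support end-to-end tests of relation discovery and
hotspot counting: a planted topic concentrates a chosen probability mass on
a given real-word list (e.g. depression vocabulary) and dominates a fraction
of the documents in chosen years, so the pipeline must rediscover it as an
exemplar topic in exactly those years.

Years are metadata: apart from planted topics, the generator does not model
temporal drift.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .corpus_io import Document, DocumentCollection
from .preprocess import TokenizedCorpus

__all__ = [
    "PlantedTopic",
    "GeneratorConfig",
    "GroundTruth",
    "generate",
    "pseudo_vocabulary",
    "recovery_score",
]


def pseudo_vocabulary(n: int) -> list[str]:
    """Deterministic list of n distinct pronounceable pseudo-words."""
    consonants = "bdfgklmnprstvz"
    vowels = "aeiou"
    syllables = [c + v for c, v in itertools.product(consonants, vowels)]
    words = []
    for combo in itertools.product(syllables, repeat=3):
        words.append("".join(combo))
        if len(words) == n:
            return words
    raise ValueError(f"cannot generate {n} pseudo-words")


@dataclass(frozen=True)
class PlantedTopic:
    """A topic concentrated on a fixed word list, active in given years.

    ``boost`` is the probability mass placed (uniformly) on the word list;
    ``doc_fraction`` the fraction of each active year's documents dominated
    by this topic; ``doc_weight`` the topic's mixture weight in those
    documents.
    """

    years: frozenset[int]
    words: tuple[str, ...]
    boost: float = 0.9
    doc_fraction: float = 0.3
    doc_weight: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.boost <= 1):
            raise ValueError("boost must be in (0,1]")
        if not (0 < self.doc_fraction <= 1):
            raise ValueError("doc_fraction must be in (0,1]")
        if not (0 < self.doc_weight < 1):
            raise ValueError("doc_weight must be in (0,1)")
        if not self.words:
            raise ValueError("planted word list is empty")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults give a small, clearly structured corpus: 10 topics over a
    500-word vocabulary, 200 documents averaging 60 content words (roughly an
    abstract's noun/adjective yield), sparse topics (beta_true = 0.01) and
    mildly mixed documents (alpha_true = 0.1).
    """

    K_true: int = 10
    vocab_size: int = 500
    M: int = 200
    doc_length_mean: float = 60.0
    alpha_true: float = 0.1
    beta_true: float = 0.01
    seed: int = 0
    years: dict[int, int] | None = None  # year -> number of documents
    planted_topics: tuple[PlantedTopic, ...] = ()

    def __post_init__(self) -> None:
        if min(self.K_true, self.vocab_size, self.M) < 1:
            raise ValueError("K_true, vocab_size and M must be positive")
        if self.doc_length_mean <= 0 or self.alpha_true <= 0 or self.beta_true <= 0:
            raise ValueError("doc_length_mean, alpha_true, beta_true must be positive")
        if self.years is not None and sum(self.years.values()) != self.M:
            raise ValueError("per-year document counts must sum to M")


@dataclass
class GroundTruth:
    """True parameters and assignments behind a generated corpus."""

    phi: np.ndarray          # (K_total, V) topic-word distributions
    theta: np.ndarray        # (M, K_total) document-topic mixtures
    z: list[np.ndarray]      # per-document token topic assignments
    vocabulary: list[str]
    doc_years: list[int]
    token_ids: list[np.ndarray] = field(default_factory=list)
    planted_topic_ids: list[int] = field(default_factory=list)

    @property
    def K_total(self) -> int:
        return self.phi.shape[0]

    def docs_token_ids(self) -> list[list[int]]:
        return [list(map(int, doc)) for doc in self.token_ids]

    def tokenized_corpus(self) -> TokenizedCorpus:
        """The corpus as token-id sequences (pre-processing bypass)."""
        return TokenizedCorpus(self.docs_token_ids(), list(self.vocabulary))


def generate(config: GeneratorConfig) -> tuple[DocumentCollection, GroundTruth]:
    """Sample a corpus from the generative process; deterministic per seed."""
    rng = np.random.default_rng(config.seed)

    planted_words = [w for pt in config.planted_topics for w in pt.words]
    base_vocab = pseudo_vocabulary(config.vocab_size)
    vocabulary = base_vocab + [w for w in dict.fromkeys(planted_words)
                               if w not in set(base_vocab)]
    V = len(vocabulary)
    word_index = {w: i for i, w in enumerate(vocabulary)}

    K_base = config.K_true
    K_total = K_base + len(config.planted_topics)

    # base topics: Dirichlet(beta_true) over the pseudo-word vocabulary only
    phi = np.zeros((K_total, V))
    phi[:K_base, : config.vocab_size] = rng.dirichlet(
        np.full(config.vocab_size, config.beta_true), size=K_base
    )

    planted_ids = []
    for p, pt in enumerate(config.planted_topics):
        k = K_base + p
        planted_ids.append(k)
        row = rng.dirichlet(np.full(config.vocab_size, config.beta_true))
        phi[k, : config.vocab_size] = (1.0 - pt.boost) * row
        ids = [word_index[w] for w in pt.words]
        phi[k, ids] += pt.boost / len(ids)
        phi[k] /= phi[k].sum()

    years_plan: list[int]
    if config.years is not None:
        years_plan = [y for y, n in sorted(config.years.items()) for _ in range(n)]
    else:
        years_plan = [0] * config.M

    theta = np.zeros((config.M, K_total))
    z_list: list[np.ndarray] = []
    token_ids: list[np.ndarray] = []
    docs: list[Document] = []

    # which documents in each active year carry each planted topic
    planted_doc: dict[int, set[int]] = {k: set() for k in planted_ids}
    for p, pt in enumerate(config.planted_topics):
        k = planted_ids[p]
        for year in sorted(pt.years):
            idx = [m for m, y in enumerate(years_plan) if y == year]
            n_pick = max(1, int(round(pt.doc_fraction * len(idx)))) if idx else 0
            picked = rng.choice(idx, size=n_pick, replace=False) if n_pick else []
            planted_doc[k].update(int(m) for m in picked)

    for m in range(config.M):
        base_theta = rng.dirichlet(np.full(K_base, config.alpha_true))
        th = np.zeros(K_total)
        th[:K_base] = base_theta
        for p, pt in enumerate(config.planted_topics):
            k = planted_ids[p]
            if m in planted_doc[k]:
                th[:K_base] *= 1.0 - pt.doc_weight
                th[k] = pt.doc_weight
        th /= th.sum()
        theta[m] = th

        n_m = max(1, rng.poisson(config.doc_length_mean))
        z = rng.choice(K_total, size=n_m, p=th)
        words = np.array([rng.choice(V, p=phi[k]) for k in z], dtype=np.int64)
        z_list.append(z.astype(np.int64))
        token_ids.append(words)
        docs.append(
            Document(
                id=f"syn-{m:05d}",
                year=years_plan[m],
                title="",
                abstract=" ".join(vocabulary[w] for w in words),
            )
        )

    truth = GroundTruth(
        phi=phi,
        theta=theta,
        z=z_list,
        vocabulary=vocabulary,
        doc_years=list(years_plan),
        token_ids=token_ids,
        planted_topic_ids=planted_ids,
    )
    return DocumentCollection(docs), truth


def recovery_score(phi_true: np.ndarray, phi_est: np.ndarray) -> float:
    """1 minus the mean total-variation distance of greedily matched topics.

    Topics are matched one-to-one, best pair first, by TV distance
    ``0.5 * sum |phi_true - phi_est|``; the mean runs over the
    ``min(K_true, K_est)`` matched pairs.  1.0 means perfect recovery up to
    topic permutation; the score is in [0, 1].
    """
    phi_true = np.asarray(phi_true, dtype=float)
    phi_est = np.asarray(phi_est, dtype=float)
    if phi_true.ndim != 2 or phi_est.ndim != 2 or phi_true.shape[1] != phi_est.shape[1]:
        raise ValueError("phi matrices must share the vocabulary axis")
    tv = 0.5 * np.abs(phi_true[:, None, :] - phi_est[None, :, :]).sum(axis=2)
    n_pairs = min(tv.shape)
    used_t: set[int] = set()
    used_e: set[int] = set()
    dists = []
    flat = [(tv[i, j], i, j) for i in range(tv.shape[0]) for j in range(tv.shape[1])]
    flat.sort()
    for d, i, j in flat:
        if i in used_t or j in used_e:
            continue
        used_t.add(i)
        used_e.add(j)
        dists.append(d)
        if len(dists) == n_pairs:
            break
    return float(1.0 - np.mean(dists))
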