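"""Embedding-valued topic representations and the topic-similarity metric.

Each LDA topic's top-W words are replaced by their embedding vectors, giving
a W x l matrix per topic; the probability-weighted average of its rows is the
topic centroid.  Pairwise topic similarity is the negative reciprocal of the
cosine between centroids,

    s(i,j) = -1 / cos(theta)          (cos(theta) > x_floor)
    s(i,j) = -1 / x_floor             (cos(theta) <= x_floor)

so identical directions give -1 (the maximum), smaller positive cosines give
more-negative values, and (near-)orthogonal or opposed centroids are floored
at -1/x_floor.  The floor generalizes the "add a minimal value x at
cos(theta)=0" rule: without clamping, a negative cosine would flip the sign
of s and invert the similarity ranking that affinity propagation relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import EmbeddingTable

__all__ = [
    "TopicMatrix",
    "TopicCentroid",
    "SimilarityMatrix",
    "DegenerateTopicError",
    "build_topic_matrix",
    "centroid",
    "cosine",
    "topic_similarity",
    "similarity_matrix",
]


class DegenerateTopicError(ValueError):
    """Raised when every top word of a topic is out of vocabulary."""


@dataclass
class TopicMatrix:
    """Top-W words of one topic with embeddings as rows.

    ``weights`` are the topic's LDA probabilities renormalized to sum to 1
    over the surviving (in-vocabulary) words.
    """

    topic_id: int
    words: list[str]
    weights: np.ndarray
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if not (len(self.words) == self.weights.shape[0] == self.rows.shape[0]):
            raise ValueError("words/weights/rows length mismatch")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")

    @property
    def l(self) -> int:
        """Embedding dimension."""
        return self.rows.shape[1]


@dataclass
class TopicCentroid:
    topic_id: int
    vector: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.isfinite(self.vector).all():
            raise ValueError("centroid has non-finite entries")


@dataclass
class SimilarityMatrix:
    """Pairwise topic similarities; diagonal is filled by preference-setting."""

    S: np.ndarray
    x_floor: float

    @property
    def n(self) -> int:
        return self.S.shape[0]


def build_topic_matrix(
    topic_id: int,
    topic_row: list[tuple[str, float]],
    table: EmbeddingTable,
) -> TopicMatrix:
    """Replace a topic's top words by their embeddings.

    Out-of-vocabulary words are dropped and the remaining probabilities
    renormalized to sum to 1 (proportions preserved).  A topic whose words
    are all OOV cannot be represented and raises DegenerateTopicError.
    """
    words, weights, rows = [], [], []
    for word, prob in topic_row:
        vec = table.lookup(word)
        if vec is None:
            continue
        words.append(word)
        weights.append(prob)
        rows.append(vec)
    if not words:
        raise DegenerateTopicError(
            f"topic {topic_id}: all {len(topic_row)} top words out of vocabulary"
        )
    weights = np.asarray(weights, dtype=np.float64)
    weights = weights / weights.sum()
    return TopicMatrix(topic_id=topic_id, words=words, weights=weights,
                       rows=np.vstack(rows))


def centroid(matrix: TopicMatrix) -> TopicCentroid:
    """Probability-weighted average of the topic matrix rows."""
    return TopicCentroid(matrix.topic_id, matrix.weights @ matrix.rows)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors; errors on zero norm."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError("vectors have different lengths")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine undefined for zero-norm vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def topic_similarity(ci: TopicCentroid, cj: TopicCentroid,
                     x_floor: float = 1e-6) -> float:
    """Negative reciprocal cosine similarity between two topic centroids.

    Strictly increasing in cos(theta) on (x_floor, 1]; cosines at or below
    x_floor (orthogonal or opposed centroids) are clamped to x_floor, giving
    the floor value -1/x_floor.
    """
    if x_floor <= 0:
        raise ValueError("x_floor must be > 0")
    c = cosine(ci.vector, cj.vector)
    if c <= x_floor:
        c = x_floor
    return -1.0 / c


def similarity_matrix(centroids: list[TopicCentroid],
                      x_floor: float = 1e-6) -> SimilarityMatrix:
    """All-pairs topic similarity; diagonal left at 0 for preference-setting."""
    n = len(centroids)
    if n < 2:
        raise ValueError("need at least 2 centroids")
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = topic_similarity(centroids[i], centroids[j], x_floor)
            S[i, j] = S[j, i] = s
    return SimilarityMatrix(S=S, x_floor=x_floor)
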