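"""Affinity propagation clustering by responsibility/availability message
passing.

Given a similarity matrix S (here: negative-reciprocal-cosine topic
similarities) with the diagonal set to the preference, the algorithm
iterates, for all (i, k) simultaneously,

    r(i,k) <- s(i,k) - max_{k' != k} { a(i,k') + s(i,k') }
    a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))   (i != k)
    a(k,k) <- sum_{i' != k} max(0, r(i',k))

each update damped with factor lambda in (0,1):

    r_t <- (1 - lambda) r_t + lambda r_{t-1}     (same for a_t)

Points k with r(k,k) + a(k,k) > 0 are exemplars; every other point is
assigned to its most similar exemplar.  The preference (self-similarity)
controls how many exemplars emerge; the median of the off-diagonal
similarities is the conventional default.

Usage::

    S = set_preference(sim, strategy="median")
    res = AffinityPropagation(damping=0.5).fit(S)
    res.exemplars, res.assignment
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topic_repr import SimilarityMatrix

__all__ = ["APConfig", "AffinityPropagation", "APResults", "set_preference",
           "net_similarity", "exemplar_topics"]


@dataclass(frozen=True)
class APConfig:
    """Affinity-propagation settings.

    damping : lambda in the open interval (0,1); higher is more inertia.
    conv_window : sweeps of unchanged exemplar set to declare convergence.
    """

    damping: float = 0.5
    max_iter: int = 500
    conv_window: int = 50
    jitter: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.damping < 1.0):
            raise ValueError(f"damping must be in (0,1), got {self.damping}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.conv_window < 1:
            raise ValueError("conv_window must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


def set_preference(sim: SimilarityMatrix | np.ndarray,
                   strategy: str | float = "median") -> np.ndarray:
    """Return a copy of S with the diagonal set to the preference.

    ``strategy`` is either "median" (median of the off-diagonal entries,
    the classical default) or a fixed numeric value.
    """
    S = sim.S if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=float)
    S = S.copy()
    n = S.shape[0]
    if isinstance(strategy, str):
        if strategy != "median":
            raise ValueError(f"unknown preference strategy {strategy!r}")
        off = S[~np.eye(n, dtype=bool)]
        pref = float(np.median(off))
    else:
        pref = float(strategy)
    np.fill_diagonal(S, pref)
    return S


class AffinityPropagation:
    """Exemplar-based clustering model; ``fit`` takes the prepared S."""

    def __init__(self, damping: float = 0.5, max_iter: int = 500,
                 conv_window: int = 50, jitter: float = 1e-6):
        self.config = APConfig(damping=damping, max_iter=max_iter,
                               conv_window=conv_window, jitter=jitter)

    def fit(self, S: np.ndarray) -> "APResults":
        S = np.asarray(S, dtype=np.float64)
        n = S.shape[0]
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if n < 2:
            raise ValueError("need at least 2 samples")

        lam = self.config.damping
        S_orig = S
        # Degenerate ties (exactly interchangeable points) leave the messages
        # perfectly symmetric and no exemplar ever emerges; break them with a
        # deterministic, vanishingly small jitter used only for the messages.
        if self.config.jitter > 0:
            rng = np.random.default_rng(0)
            span = float(S.max() - S.min()) or 1.0
            S = S + rng.standard_normal((n, n)) * self.config.jitter * span
        R = np.zeros((n, n))
        A = np.zeros((n, n))
        idx = np.arange(n)

        last_exemplars: np.ndarray | None = None
        stable = 0
        converged = False
        n_iter = 0
        for t in range(self.config.max_iter):
            n_iter = t + 1
            # responsibilities
            AS = A + S
            max1 = AS.max(axis=1)
            argmax1 = AS.argmax(axis=1)
            tmp = AS.copy()
            tmp[idx, argmax1] = -np.inf
            max2 = tmp.max(axis=1)
            R_new = S - max1[:, None]
            R_new[idx, argmax1] = S[idx, argmax1] - max2
            R = (1 - lam) * R_new + lam * R

            # availabilities
            Rp = np.maximum(R, 0.0)
            np.fill_diagonal(Rp, R.diagonal())
            col = Rp.sum(axis=0)
            A_new = np.minimum(0.0, col[None, :] - Rp)
            # diagonal: sum over i' != k of max(0, r(i',k))
            diag = np.maximum(R, 0.0).sum(axis=0) - np.maximum(R.diagonal(), 0.0)
            np.fill_diagonal(A_new, diag)
            A = (1 - lam) * A_new + lam * A

            exemplars = np.flatnonzero(R.diagonal() + A.diagonal() > 0)
            if last_exemplars is not None and np.array_equal(exemplars, last_exemplars) \
                    and exemplars.size > 0:
                stable += 1
                if stable >= self.config.conv_window:
                    converged = True
                    break
            else:
                stable = 0
            last_exemplars = exemplars

        exemplars = np.flatnonzero(R.diagonal() + A.diagonal() > 0)
        if exemplars.size == 0:
            # degenerate run: fall back to the single best candidate
            exemplars = np.array([int(np.argmax(R.diagonal() + A.diagonal()))])

        assignment = {}
        ex_set = set(exemplars.tolist())
        for i in range(n):
            if i in ex_set:
                assignment[i] = i
            else:
                # argmax over exemplars of s(i,k); ties -> lowest index
                k_best = exemplars[int(np.argmax(S_orig[i, exemplars]))]
                assignment[i] = int(k_best)

        return APResults(config=self.config, S=S_orig, R=R, A=A,
                         exemplars=[int(k) for k in exemplars],
                         assignment=assignment, n_iter=n_iter,
                         converged=converged)


@dataclass
class APResults:
    """Clustering result: exemplars, assignments and final message matrices."""

    config: APConfig
    S: np.ndarray = field(repr=False)
    R: np.ndarray = field(repr=False)
    A: np.ndarray = field(repr=False)
    exemplars: list[int]
    assignment: dict[int, int]
    n_iter: int
    converged: bool

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, k: int) -> list[int]:
        """Samples assigned to exemplar k (including k itself)."""
        return [i for i, e in self.assignment.items() if e == k]

    def net_similarity(self) -> float:
        """Sum of s(i, exemplar(i)) over all points (preferences included
        for exemplars) — the quantity affinity propagation maximizes."""
        return float(sum(self.S[i, k] for i, k in self.assignment.items()))

    def summary(self) -> str:
        lines = [
            "Affinity Propagation",
            "=" * 30,
            f"Samples:        {self.S.shape[0]}",
            f"Clusters:       {self.n_clusters}",
            f"Exemplars:      {self.exemplars}",
            f"Iterations:     {self.n_iter} ({'converged' if self.converged else 'max_iter reached'})",
            f"Damping:        {self.config.damping}",
            f"Net similarity: {self.net_similarity():.4f}",
        ]
        for k in self.exemplars:
            lines.append(f"  exemplar {k}: members {self.members(k)}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "exemplars": self.exemplars,
            "assignment": {str(i): k for i, k in self.assignment.items()},
            "n_clusters": self.n_clusters,
        }


def net_similarity(S: np.ndarray, exemplars: list[int]) -> float:
    """Net similarity of the best assignment to a fixed exemplar set."""
    S = np.asarray(S, dtype=float)
    ex = np.asarray(sorted(exemplars), dtype=int)
    total = float(S.diagonal()[ex].sum())
    for i in range(S.shape[0]):
        if i not in set(ex.tolist()):
            total += float(S[i, ex].max())
    return total


def optimal_exemplars(S: np.ndarray) -> tuple[list[int], float]:
    """Exhaustive search over all non-empty exemplar subsets (test oracle;
    exponential in n, use only for small matrices)."""
    from itertools import combinations

    n = np.asarray(S).shape[0]
    best: tuple[list[int], float] | None = None
    for r in range(1, n + 1):
        for subset in combinations(range(n), r):
            val = net_similarity(S, list(subset))
            if best is None or val > best[1]:
                best = (list(subset), val)
    assert best is not None
    return best


def exemplar_topics(result: APResults, topics) -> list[dict]:
    """Topic-word rows of the exemplar topics, annotated with cluster members.

    ``topics`` is a TopicWordTable indexed by topic id = sample index.
    """
    n_topics = topics.n_topics if hasattr(topics, "n_topics") else len(topics)
    if max(result.exemplars) >= n_topics:
        raise ValueError("exemplar index outside topic table")
    out = []
    for k in result.exemplars:
        out.append({
            "topic_id": k,
            "words": list(topics[k]),
            "members": result.members(k),
        })
    return out
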