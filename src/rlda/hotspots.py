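"""Cross-year hotspot aggregation and disease-relation extraction.

For each year, affinity propagation reduces the LDA topics to exemplar
("central") topics.  The exemplar topic's rank-1 word is that cluster's
central word; merging all exemplar rows of a year yields the year's
"super word cloud" data (word, weight) with weight = the word's topic
probability.  Counting in how many years a central word (or a user-supplied
synonym group) appears gives the trend record, tiered as
once / twice / thrice / more-than-thrice.

Relation extraction scans the exemplar topics of a seed-disease corpus
(diabetes or obesity) for terms of a disease lexicon: an edge
(seed disease, lexicon disease) is emitted when any synonym appears among an
exemplar topic's top words with probability above a threshold, in any year.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from .corpus_io import SynonymLexicon

__all__ = [
    "YearHotspots",
    "HotspotRecord",
    "central_word",
    "merge_year",
    "count_across_years",
    "export_wordcloud_data",
    "read_wordcloud_data",
    "relation_edges",
    "export_relation_edges",
    "tier_for_count",
    "TIER_MORE_THAN_THRICE",
    "TIER_THRICE",
    "TIER_TWICE",
    "TIER_ONCE",
]

TIER_MORE_THAN_THRICE = "more-than-thrice"
TIER_THRICE = "thrice"
TIER_TWICE = "twice"
TIER_ONCE = "once"


def tier_for_count(count: int) -> str:
    if count > 3:
        return TIER_MORE_THAN_THRICE
    if count == 3:
        return TIER_THRICE
    if count == 2:
        return TIER_TWICE
    if count == 1:
        return TIER_ONCE
    raise ValueError("count must be >= 1")


@dataclass
class YearHotspots:
    """One year's merged central-topic words with their weights."""

    year: int
    central_words: list[tuple[str, float]]

    def words(self) -> set[str]:
        return {w for w, _ in self.central_words}


@dataclass
class HotspotRecord:
    """Cross-year appearance record for a (grouped) central word."""

    word: str
    appearance_years: list[int]
    count: int
    tier: str


def central_word(exemplar_row: list[tuple[str, float]]) -> str:
    """The rank-1 (highest-probability) word of an exemplar topic.

    The row is probability-sorted with ties already broken by vocabulary
    order, so the first entry is the central word.
    """
    if not exemplar_row:
        raise ValueError("empty exemplar topic row")
    return exemplar_row[0][0]


def merge_year(year: int, exemplar_rows: list[list[tuple[str, float]]]) -> YearHotspots:
    """Union of all exemplar rows' (word, probability) pairs for one year.

    A word appearing in several exemplar topics keeps its maximum weight;
    output is sorted by weight descending (ties alphabetical).
    """
    if not exemplar_rows:
        raise ValueError("need at least one exemplar row")
    best: dict[str, float] = {}
    for row in exemplar_rows:
        for word, prob in row:
            if word not in best or prob > best[word]:
                best[word] = prob
    merged = sorted(best.items(), key=lambda wp: (-wp[1], wp[0]))
    return YearHotspots(year=year, central_words=merged)


def count_across_years(
    yearly: list[YearHotspots],
    word_groups: dict[str, list[str]] | None = None,
    central_only: bool = True,
) -> list[HotspotRecord]:
    """Count cross-year appearances of central words.

    ``word_groups`` maps a group label to its member words (e.g. grouping
    cataract/retina/retinopathy); a group counts a year when any member
    appears.  With ``central_only`` each year contributes only its per-topic
    central words, i.e. the rank-1 entries are expected in ``central_words``.
    Records are sorted by count descending, then alphabetically.
    """
    years = [yh.year for yh in yearly]
    if len(set(years)) != len(years):
        raise ValueError("duplicate years in input")

    year_words: dict[int, set[str]] = {yh.year: yh.words() for yh in yearly}

    groups: dict[str, list[str]] = {}
    grouped_members: set[str] = set()
    if word_groups:
        for label, members in word_groups.items():
            groups[label] = list(members)
            grouped_members.update(members)
    for words in year_words.values():
        for w in words:
            if w not in grouped_members and w not in groups:
                groups[w] = [w]

    records = []
    for label, members in groups.items():
        appearance = sorted(
            y for y, words in year_words.items() if any(m in words for m in members)
        )
        if appearance:
            records.append(
                HotspotRecord(
                    word=label,
                    appearance_years=appearance,
                    count=len(appearance),
                    tier=tier_for_count(len(appearance)),
                )
            )
    records.sort(key=lambda r: (-r.count, r.word))
    return records


def export_wordcloud_data(yh: YearHotspots, path: str | Path) -> None:
    """Write word<TAB>weight rows, weight descending, 6-decimal precision."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write("word\tweight\n")
        for word, weight in yh.central_words:
            fh.write(f"{word}\t{weight:.6f}\n")


def read_wordcloud_data(year: int, path: str | Path) -> YearHotspots:
    with Path(path).open(encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != ["word", "weight"]:
            raise ValueError(f"unexpected word-cloud header {header!r}")
        rows = [(w, float(x)) for w, x in reader]
    return YearHotspots(year=year, central_words=rows)


def relation_edges(
    exemplars_by_seed: dict[str, list[list[tuple[str, float]]]],
    disease_lexicon: SynonymLexicon,
    min_weight: float = 0.0,
) -> list[tuple[str, str, float]]:
    """Disease co-occurrence edges for chord-diagram input.

    ``exemplars_by_seed`` maps each seed disease (the disease whose corpus
    was modelled, e.g. "diabetes"/"obesity") to the exemplar topic rows
    pooled across years.  An edge (seed, disease) is emitted when any synonym
    of a lexicon disease appears in any exemplar row with probability >=
    ``min_weight``; its weight is the maximum such probability.  Edges are
    deduplicated; self-edges (seed disease found in its own topics) are
    skipped.  Output is sorted by (seed, disease).
    """
    if len(disease_lexicon) == 0:
        raise ValueError("disease lexicon is empty")
    edges: dict[tuple[str, str], float] = {}
    for seed, rows in exemplars_by_seed.items():
        for disease in disease_lexicon.diseases():
            if disease == seed:
                continue
            synonyms = {s.lower() for s in disease_lexicon.terms(disease)}
            for row in rows:
                for word, prob in row:
                    if word.lower() in synonyms and prob >= min_weight:
                        key = (seed, disease)
                        if key not in edges or prob > edges[key]:
                            edges[key] = prob
    return sorted((s, d, w) for (s, d), w in edges.items())


def export_relation_edges(edges: list[tuple[str, str, float]], path: str | Path) -> None:
    """Write the chord-diagram edge list as CSV: source,target,weight."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for s, d, w in edges:
            writer.writerow([s, d, f"{w:.6f}"])
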