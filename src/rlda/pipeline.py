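"""End-to-end driver: corpus -> per-year topics -> embeddings -> topic
clustering -> hotspot and relation outputs.

Stages are run per publication year, and each stage writes its artifact
before the next starts, so a pipeline directory is a reproducible record:
tokenized corpus, topic-word table, embedding table, similarity matrix,
cluster result and word-cloud data per year, plus global trend records and a
manifest of every parameter and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .ap import AffinityPropagation, exemplar_topics, set_preference
from .corpus_io import (DocumentCollection, SynonymLexicon, default_lexicon,
                        default_stopwords, read_jsonl, read_lexicon,
                        read_medline, stratify_by_year)
from .embeddings import train_skipgram
from .hotspots import (YearHotspots, count_across_years, export_wordcloud_data,
                       merge_year, relation_edges)
from .lda import LatentDirichletAllocation, TopicWordTable
from .preprocess import tokenize_collection
from .topic_repr import (DegenerateTopicError, build_topic_matrix, centroid,
                         similarity_matrix)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "relations_from_runs"]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    corpus: str
    output_dir: str
    corpus_format: str = "jsonl"          # jsonl | medline
    lexicon: str | None = None            # None -> packaged diabetes/obesity lexicon
    stoplist: str | None = None           # None -> packaged stop-word list
    seed_disease: str | None = None       # label for relation extraction
    # LDA
    n_topics: int = 100
    alpha: float | None = None            # None -> 5/n_topics
    beta: float = 0.01
    iterations: int = 500
    top_w: int = 20
    # embeddings
    dim: int = 100
    window: int = 5
    negative_samples: int = 5
    epochs: int = 5
    min_count: int = 1
    # topic similarity / clustering
    x_floor: float = 1e-6
    damping: float = 0.5
    max_iter: int = 500
    conv_window: int = 50
    preference: str | float = "median"
    # relations
    min_weight: float = 0.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory summary of a run: per-year exemplar rows and hotspots."""

    config: RunConfig
    years: list[int]
    exemplar_rows_by_year: dict[int, list[list[tuple[str, float]]]]
    yearly_hotspots: list[YearHotspots]
    trend_records: list
    output_dir: Path

    def pooled_exemplar_rows(self) -> list[list[tuple[str, float]]]:
        return [row for rows in self.exemplar_rows_by_year.values() for row in rows]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and year."""


def _stage(name: str, year, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError(f"stage {name!r} (year={year}) failed: {exc}") from exc


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage for every year and write all artifacts.

    Raises StageError naming the failing stage; configuration problems
    (missing input paths) are reported before any compute starts.
    """
    corpus_path = Path(config.corpus)
    if not corpus_path.exists():
        raise FileNotFoundError(f"corpus not found: {corpus_path}")
    if config.lexicon is not None and not Path(config.lexicon).exists():
        raise FileNotFoundError(f"lexicon not found: {config.lexicon}")
    if config.stoplist is not None and not Path(config.stoplist).exists():
        raise FileNotFoundError(f"stoplist not found: {config.stoplist}")

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.corpus_format == "medline":
        collection = read_medline(corpus_path)
    elif config.corpus_format == "jsonl":
        collection = read_jsonl(corpus_path)
    else:
        raise ValueError(f"unknown corpus format {config.corpus_format!r}")

    stoplist = (default_stopwords() if config.stoplist is None
                else [w.strip() for w in Path(config.stoplist).read_text().splitlines() if w.strip()])

    by_year = stratify_by_year(collection)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(config).items()},
        "M_total": collection.M,
        "years": {},
    }

    exemplar_rows_by_year: dict[int, list[list[tuple[str, float]]]] = {}
    yearly_hotspots: list[YearHotspots] = []

    for year, part in by_year.items():
        year_info: dict = {"M": part.M}

        tokenized = _stage("preprocess", year, tokenize_collection, part, stoplist)
        _write_tokenized(tokenized, outdir / f"tokens_{year}.jsonl",
                         outdir / f"vocabulary_{year}.txt")
        year_info["V"] = tokenized.V
        year_info["tokens"] = int(sum(tokenized.N))

        model = LatentDirichletAllocation(
            tokenized, n_topics=config.n_topics, alpha=config.alpha,
            beta=config.beta, iterations=config.iterations, top_w=config.top_w)
        res = _stage("lda", year, model.fit, seed=config.seed)
        table = res.top_words(config.top_w)
        table.to_tsv(outdir / f"topics_{year}.tsv")

        emb = _stage("embeddings", year, train_skipgram, tokenized,
                     dim=config.dim, window=config.window,
                     negative_samples=config.negative_samples,
                     epochs=config.epochs, min_count=config.min_count,
                     seed=config.seed)
        emb.save(outdir / f"embeddings_{year}.txt")
        top_words_flat = [w for row in table for w, _ in row]
        year_info["embedding_coverage_of_top_words"] = emb.coverage(top_words_flat)

        centroids = []
        for k, row in enumerate(table):
            try:
                centroids.append(centroid(build_topic_matrix(k, row, emb)))
            except DegenerateTopicError:
                year_info.setdefault("degenerate_topics", []).append(k)

        if len(centroids) >= 2:
            sim = _stage("similarity", year, similarity_matrix, centroids,
                         config.x_floor)
            np.savetxt(outdir / f"similarity_{year}.tsv", sim.S, delimiter="\t")
            S = set_preference(sim, config.preference)
            ap = AffinityPropagation(damping=config.damping,
                                     max_iter=config.max_iter,
                                     conv_window=config.conv_window)
            result = _stage("cluster", year, ap.fit, S)
            # map centroid positions back to topic ids
            topic_of = [c.topic_id for c in centroids]
            ex_rows = [table[topic_of[k]] for k in result.exemplars]
            cluster_json = {
                "exemplars": [topic_of[k] for k in result.exemplars],
                "assignment": {str(topic_of[i]): topic_of[k]
                               for i, k in result.assignment.items()},
                "n_clusters": result.n_clusters,
                "converged": result.converged,
                "n_iter": result.n_iter,
            }
            year_info["n_clusters"] = result.n_clusters
        else:
            ex_rows = [table[c.topic_id] for c in centroids]
            cluster_json = {
                "exemplars": [c.topic_id for c in centroids],
                "assignment": {str(c.topic_id): c.topic_id for c in centroids},
                "n_clusters": len(centroids), "converged": True, "n_iter": 0,
            }
            year_info["n_clusters"] = len(centroids)
        (outdir / f"clusters_{year}.json").write_text(json.dumps(cluster_json, indent=1))

        yh = _stage("hotspots", year, merge_year, year, ex_rows)
        export_wordcloud_data(yh, outdir / f"hotspots_{year}.tsv")
        exemplar_rows_by_year[year] = ex_rows
        yearly_hotspots.append(yh)
        manifest["years"][str(year)] = year_info

    # trend records over central words only (rank-1 word of each exemplar)
    central_yearly = [
        merge_year(yh.year, [[row[0]] for row in exemplar_rows_by_year[yh.year] if row])
        for yh in yearly_hotspots
    ]
    trend = count_across_years(central_yearly)
    (outdir / "trend_records.json").write_text(json.dumps(
        [asdict(r) for r in trend], indent=1))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return PipelineResult(
        config=config,
        years=list(by_year),
        exemplar_rows_by_year=exemplar_rows_by_year,
        yearly_hotspots=yearly_hotspots,
        trend_records=trend,
        output_dir=outdir,
    )


def relations_from_runs(
    runs: dict[str, PipelineResult],
    lexicon: SynonymLexicon | None = None,
    min_weight: float = 0.0,
) -> list[tuple[str, str, float]]:
    """Pool exemplar topics of several seed-disease runs into relation edges."""
    if lexicon is None:
        lexicon = default_lexicon()
    pooled = {seed: res.pooled_exemplar_rows() for seed, res in runs.items()}
    return relation_edges(pooled, lexicon, min_weight=min_weight)


def _write_tokenized(corpus, tokens_path: Path, vocab_path: Path) -> None:
    with tokens_path.open("w", encoding="utf-8") as fh:
        for seq in corpus.docs:
            fh.write(json.dumps(list(map(int, seq))) + "\n")
    vocab_path.write_text("\n".join(corpus.vocabulary) + "\n", encoding="utf-8")
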