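"""End-to-end pipeline: ontology -> score -> filter -> (evaluate) -> topics.

One config drives all four phases; a single global seed fans out to
deterministic per-stage seeds, and every artifact (evaluation matrix,
retained/excluded corpora, topic model, topic table, TF-IDF table) is written
to the output directory along with a JSON run report recording record counts
in and out of every stage. Re-running with the same config reproduces every
output byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import ontology as onto
from . import relevance, topics
from .preprocess import clean_text, read_corpus, tokenize_lemmatize, write_corpus

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("infoveil")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    ontology_path: str = ""
    corpus_path: str = ""
    corpus_format: str = "jsonl"
    truth_path: Optional[str] = None
    outdir: str = "infoveil_out"
    lo: int = 2
    hi: int = 10
    k: Optional[int] = None
    k_grid: Optional[list[int]] = None
    alpha: Optional[float] = None
    beta: float = 0.01
    iterations: int = 100
    holdout_fraction: float = 0.2
    epsilon: float = 0.01
    n_top_words: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage_seeds(seed: int) -> dict[str, int]:
    """Fan one global seed out into independent per-stage seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    names = ["select_k", "fit"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all phases and return the run report (also written to report.json)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: getattr(config, k) for k in config.__dataclass_fields__}, "stages": {}}
    seeds = _stage_seeds(config.seed)
    report["seeds"] = seeds

    # --- phase I: ontology / topic expansion
    try:
        root = onto.load_ontology(config.ontology_path)
        term_set = onto.flatten_terms(root)
        query = onto.build_query(onto.QuerySpec(term_set=term_set, language="en",
                                               exclude_retweets=True, exclude_urls=True))
        (outdir / "terms.txt").write_text("\n".join(term_set.terms) + "\n", encoding="utf-8")
        (outdir / "query.txt").write_text(query + "\n", encoding="utf-8")
    except Exception as exc:
        raise PipelineError("ontology", str(exc)) from exc
    log.info("ontology: %d terms", len(term_set))
    report["stages"]["ontology"] = {"n_terms": len(term_set)}

    # --- phase II stand-in: load the already-collected corpus
    try:
        corpus = read_corpus(config.corpus_path, format=config.corpus_format)
    except Exception as exc:
        raise PipelineError("load_corpus", str(exc)) from exc
    log.info("corpus: %d posts", len(corpus))
    report["stages"]["load_corpus"] = {"n_posts": len(corpus)}

    # --- phase III: evaluation matrix, quality filter
    try:
        matrix = relevance.build_matrix(corpus, term_set, lo=config.lo, hi=config.hi)
        relevance.write_matrix_csv(matrix, outdir / "matrix.csv")
        retained, excluded = relevance.filter_relevant(matrix, corpus)
        write_corpus(retained, outdir / "relevant.jsonl")
        write_corpus(excluded, outdir / "excluded.jsonl")
    except Exception as exc:
        raise PipelineError("score_filter", str(exc)) from exc
    log.info("filter: %d retained, %d excluded", len(retained), len(excluded))
    report["stages"]["score_filter"] = {
        "n_in": len(corpus), "n_retained": len(retained), "n_excluded": len(excluded),
        "lo": config.lo, "hi": config.hi,
    }

    # --- optional evaluation against ground truth
    if config.truth_path:
        try:
            truth_map = relevance.read_labels_csv(config.truth_path)
            truth = [truth_map[pid] for pid in matrix.post_ids]
            conf = relevance.confusion(matrix.labels.tolist(), truth)
            mets = relevance.metrics(conf)
            block = {
                "confusion": {"tp": conf.tp, "fp": conf.fp, "fn": conf.fn, "tn": conf.tn},
                "metrics": mets.rounded(3),
            }
            (outdir / "metrics.json").write_text(json.dumps(block, indent=2) + "\n", encoding="utf-8")
        except Exception as exc:
            raise PipelineError("evaluate", str(exc)) from exc
        log.info("evaluate: %s", block["metrics"])
        report["stages"]["evaluate"] = block

    # --- phase IV: topic modeling on the retained posts
    try:
        docs = [
            tokenize_lemmatize(clean_text(p.text, "modeling"), post_id=p.id) for p in retained
        ]
        if config.k is not None:
            chosen_k = config.k
        else:
            grid = config.k_grid or [2, 3, 4, 5, 6, 7, 8, 9, 10]
            sel = topics.select_k(
                docs, grid, holdout_fraction=config.holdout_fraction, epsilon=config.epsilon,
                alpha=config.alpha, beta=config.beta, iterations=config.iterations,
                seed=seeds["select_k"],
            )
            chosen_k = sel.chosen_k
            report["stages"]["select_k"] = {
                "k_grid": sel.k_grid,
                "heldout_perplexity": {str(k): v for k, v in sel.heldout_perplexity.items()},
                "chosen_k": sel.chosen_k,
            }
            log.info("select_k: chose k=%d", chosen_k)
        model = topics.fit_lda(
            docs, k=chosen_k, alpha=config.alpha, beta=config.beta,
            iterations=config.iterations, seed=seeds["fit"],
        )
        topics.save_model(model, outdir / "model")
        assignments = topics.assign_topics(model)
        summaries = topics.topic_weights(assignments, model=model, n_words=config.n_top_words)
        with open(outdir / "topics.csv", "w", encoding="utf-8") as fh:
            fh.write("topic_id,top_words,count,pct\n")
            for s in summaries:
                fh.write(f"{s.topic_id},{' '.join(s.top_words)},{s.weight_count},{s.weight_pct:.2f}\n")
        table = topics.tfidf_scores(docs, groups=assignments, top_n=config.n_top_words)
        table.to_csv(outdir / "tfidf.csv", index=False)
    except Exception as exc:
        raise PipelineError("topics", str(exc)) from exc
    n_assigned = int((assignments != topics.UNASSIGNED).sum())
    log.info("topics: k=%d, %d docs assigned", chosen_k, n_assigned)
    report["stages"]["topics"] = {"k": int(chosen_k), "n_docs": len(docs), "n_assigned": n_assigned}

    report["elapsed_s"] = round(time.time() - t0, 3)
    report["outputs"] = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file() and p.name != "report.json"
    )
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return report
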