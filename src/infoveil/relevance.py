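"""Quality-score relevance filtering and classifier evaluation.

The evaluation matrix is a posts x ontology-terms binary presence matrix: a
cell is 1 iff the term occurs in the post (as a contiguous token sequence on
scoring-cleaned text), regardless of how often it repeats. The per-post
quality score is the row sum — the number of *distinct* ontology terms
present — and a post is labeled relevant iff its score lies in the inclusive
band [lo, hi] (defaults [2, 10]). The rationale: at least two domain terms
make a post plausibly on-topic, while more than ten scatter its context
beyond usefulness.

Also here: confusion counts, precision/recall/F-measure/accuracy, and
Cohen's kappa for interrater agreement.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ontology import TermSet
from .preprocess import Corpus, clean_text, tokenize

__all__ = [
    "EvaluationMatrix",
    "ConfusionCounts",
    "Metrics",
    "build_matrix",
    "filter_relevant",
    "confusion",
    "metrics",
    "cohen_kappa",
    "write_matrix_csv",
    "read_labels_csv",
]


def _match_posts(corpus: Corpus, terms: Sequence[str]) -> np.ndarray:
    """Binary (n_posts, n_terms) presence matrix by contiguous token-sequence match.

    Each term is tokenized the same way as the scoring-cleaned post text, so a
    single-word term matches only whole tokens ("oxy" never fires inside an
    "oxycodone" token) and a multiword term matches the exact n-gram.
    """
    term_tokens = [tuple(tokenize(clean_text(t, "scoring"))) for t in terms]
    lengths = sorted({len(tt) for tt in term_tokens if tt})
    out = np.zeros((len(corpus), len(terms)), dtype=bool)
    for i, post in enumerate(corpus):
        toks = tokenize(clean_text(post.text, "scoring"))
        grams: dict[int, set[tuple[str, ...]]] = {}
        for n in lengths:
            grams[n] = {tuple(toks[j : j + n]) for j in range(len(toks) - n + 1)}
        for j, tt in enumerate(term_tokens):
            if tt and tt in grams.get(len(tt), ()):
                out[i, j] = True
    return out


@dataclass
class EvaluationMatrix:
    """Posts x terms binary matrix with quality scores and relevance labels.

    Invariants (enforced at construction): cells are 0/1; ``scores`` equals
    the row sums exactly; ``labels[i] == 1`` iff ``lo <= scores[i] <= hi``.
    """

    post_ids: list[str]
    terms: TermSet
    cells: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    lo: int
    hi: int

    def __post_init__(self) -> None:
        c = np.asarray(self.cells)
        if c.size and not np.isin(c, (0, 1)).all():
            raise ValueError("matrix cells must be binary")
        if not np.array_equal(self.scores, c.sum(axis=1)):
            raise ValueError("scores must equal row sums")
        expected = ((self.scores >= self.lo) & (self.scores <= self.hi)).astype(int)
        if not np.array_equal(self.labels, expected):
            raise ValueError("labels must be 1 exactly when lo <= score <= hi")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class Metrics:
    """Precision, recall, F-measure, accuracy; ``None`` marks an undefined value."""

    precision: Optional[float]
    recall: Optional[float]
    f_measure: Optional[float]
    accuracy: Optional[float]

    def rounded(self, ndigits: int = 3) -> dict[str, Optional[float]]:
        """Display form: round-half-even to ``ndigits`` decimals."""
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in (
                ("precision", self.precision),
                ("recall", self.recall),
                ("f_measure", self.f_measure),
                ("accuracy", self.accuracy),
            )
        }


def build_matrix(corpus: Corpus, terms: TermSet, lo: int = 2, hi: int = 10) -> EvaluationMatrix:
    """Populate the evaluation matrix for a corpus against an ontology term set.

    Presence is binary per term (repetition does not raise the score); the
    quality score is the number of distinct terms present; the relevance label
    applies the inclusive [lo, hi] band. An empty corpus yields an empty
    matrix; an empty term set is an error.
    """
    if len(terms) == 0:
        raise ValueError("term set is empty")
    if not (0 <= lo <= hi):
        raise ValueError(f"invalid thresholds lo={lo}, hi={hi}")
    cells = _match_posts(corpus, terms.terms).astype(int)
    scores = cells.sum(axis=1)
    labels = ((scores >= lo) & (scores <= hi)).astype(int)
    return EvaluationMatrix(
        post_ids=corpus.ids(), terms=terms, cells=cells, scores=scores, labels=labels, lo=lo, hi=hi
    )


def filter_relevant(matrix: EvaluationMatrix, corpus: Corpus) -> tuple[Corpus, Corpus]:
    """Partition a corpus into (relevant, excluded) by the matrix labels.

    Exact and exhaustive: every post lands in exactly one half. Raises if the
    matrix rows do not align with the corpus ids.
    """
    if matrix.post_ids != corpus.ids():
        raise ValueError("matrix rows do not align with corpus ids")
    rel = [p for p, lab in zip(corpus, matrix.labels) if lab == 1]
    exc = [p for p, lab in zip(corpus, matrix.labels) if lab == 0]
    return Corpus(rel), Corpus(exc)


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """2x2 confusion counts for aligned binary prediction/truth vectors."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(truth)} truths")
    p = np.asarray(pred, dtype=int)
    t = np.asarray(truth, dtype=int)
    return ConfusionCounts(
        tp=int(((p == 1) & (t == 1)).sum()),
        fp=int(((p == 1) & (t == 0)).sum()),
        fn=int(((p == 0) & (t == 1)).sum()),
        tn=int(((p == 0) & (t == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Precision, recall, F-measure and accuracy from confusion counts.

    precision = tp/(tp+fp), recall = tp/(tp+fn), F = 2PR/(P+R),
    accuracy = (tp+tn)/total. A zero denominator yields an explicit ``None``
    ("undefined"), never a silent 0.
    """
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f = None
    else:
        f = 2 * precision * recall / (precision + recall)
    accuracy = (c.tp + c.tn) / c.total if c.total > 0 else None
    return Metrics(precision=precision, recall=recall, f_measure=f, accuracy=accuracy)


def cohen_kappa(rater_a: Sequence, rater_b: Sequence) -> float:
    """Cohen's kappa: chance-corrected agreement between two raters.

    kappa = (p_o - p_e) / (1 - p_e), where p_o is observed agreement and p_e
    the expected agreement from the raters' marginal label frequencies.
    Returns 1.0 when both p_o and p_e equal 1 (degenerate perfect agreement).
    """
    if len(rater_a) != len(rater_b):
        raise ValueError(f"length mismatch: {len(rater_a)} vs {len(rater_b)}")
    n = len(rater_a)
    if n == 0:
        raise ValueError("need at least one rated item")
    labels = sorted(set(rater_a) | set(rater_b), key=str)
    p_o = sum(a == b for a, b in zip(rater_a, rater_b)) / n
    p_e = 0.0
    for lab in labels:
        p_e += (sum(a == lab for a in rater_a) / n) * (sum(b == lab for b in rater_b) / n)
    if math.isclose(p_e, 1.0):
        return 1.0 if math.isclose(p_o, 1.0) else 0.0
    return (p_o - p_e) / (1 - p_e)


# --- I/O helpers (Fig-8-style matrix CSV, ground-truth labels) ----------


def write_matrix_csv(matrix: EvaluationMatrix, path) -> None:
    """CSV layout: ``id,<term1>,...,<termN>,score,label`` — one row per post."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", *matrix.terms.terms, "score", "label"])
        for i, pid in enumerate(matrix.post_ids):
            w.writerow([pid, *matrix.cells[i].tolist(), int(matrix.scores[i]), int(matrix.labels[i])])


def read_labels_csv(path) -> dict[str, int]:
    """Read ``id,label`` ground-truth CSV into an id -> 0/1 map."""
    out: dict[str, int] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames or "label" not in reader.fieldnames:
            raise ValueError(f"{path}: CSV header must contain 'id' and 'label'")
        for row in reader:
            out[row["id"]] = int(row["label"])
    return out
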