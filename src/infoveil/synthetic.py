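"""Synthetic tweet-like corpora with planted relevance and topic structure.

Every post is assembled in three steps: (1) draw a planted relevance label,
(2) embed that label's number of *distinct* ontology terms (relevant posts
carry a count inside the relevance band, irrelevant posts a count outside
it), and (3) pad to a tweet-scale length with background words drawn from a
k-topic LDA generative process (Dirichlet document-topic mixture, per-topic
categorical word draws). The background vocabulary is disjoint from the
ontology terms, so term matches downstream are unambiguous and a noiseless
pipeline recovers the planted relevance labels exactly.

``label_noise`` flips the *recorded* ground-truth label with the given
probability while leaving the embedded term counts alone — emulating
imperfect human annotation, and producing controlled false positives and
negatives when the score filter is benchmarked against the truth table.

What this emulates: the score regimes and topic mixtures of short public
drug-discussion posts. What it does not: grammar, slang morphology, named
entities, or any linguistic structure beyond bag-of-words.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ontology import OntologyNode, flatten_terms
from .preprocess import Corpus, Post

__all__ = [
    "SyntheticSpec",
    "generate_toy_ontology",
    "generate_lda_corpus",
    "generate_corpus",
]

_CONSONANTS = list("bcdfghjklmnpqrstvwz")
_VOWELS = list("aeiou")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic corpus generator.

    Relevant posts embed a distinct-term count drawn uniformly from
    ``relevant_range`` (inclusive); irrelevant posts draw from
    ``irrelevant_low`` or from (relevant_range[1], max available] — both
    sides of the relevance band. ``doc_len_mean``/``doc_len_dispersion``
    parametrize a negative-binomial token count truncated to [5, 50]
    (tweet scale).
    """

    n_posts: int = 1000
    ontology: Optional[OntologyNode] = None
    relevant_fraction: float = 0.5
    relevant_range: tuple[int, int] = (2, 10)
    irrelevant_low: tuple[int, ...] = (0, 1)
    k_true: int = 5
    alpha: float = 0.3
    beta: float = 0.01
    vocab_size: int = 500
    doc_len_mean: float = 18.0
    doc_len_dispersion: float = 5.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.relevant_fraction <= 1.0):
            raise ValueError("relevant_fraction must be in [0, 1]")
        if not (0.0 <= self.label_noise <= 1.0):
            raise ValueError("label_noise must be in [0, 1]")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        lo, hi = self.relevant_range
        if not (0 <= lo <= hi):
            raise ValueError(f"invalid relevant_range {self.relevant_range}")


def _word(rng: np.random.Generator, syllables: int = 3) -> str:
    return "".join(rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(syllables))


def generate_toy_ontology(
    n_classes: int = 3, terms_per_class: int = 4, seed: int = 0
) -> OntologyNode:
    """A deterministic synthetic ontology: one theme, n_classes classes, each
    with ``terms_per_class`` unique single-token pronounceable terms."""
    if n_classes < 1 or terms_per_class < 1:
        raise ValueError("n_classes and terms_per_class must be positive")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()

    def fresh() -> str:
        while True:
            w = _word(rng)
            if w not in seen:
                seen.add(w)
                return w

    children = [
        OntologyNode(
            name=f"class {i + 1}",
            kind="class",
            terms=[fresh() for _ in range(terms_per_class)],
        )
        for i in range(n_classes)
    ]
    return OntologyNode(name="synthetic abuse", kind="theme", terms=[], children=children)


def _doc_lengths(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    # negative binomial with mean `mean` and shape `dispersion`, truncated to [5, 50]
    p = dispersion / (dispersion + mean)
    lengths = rng.negative_binomial(dispersion, p, size=n)
    return np.clip(lengths, 5, 50)


def generate_lda_corpus(
    n_docs: int,
    k: int,
    vocab_size: int,
    alpha: float = 0.3,
    beta: float = 0.01,
    doc_len_mean: float = 18.0,
    doc_len_dispersion: float = 5.0,
    seed: int = 0,
    vocab_prefix: str = "w",
):
    """Draw a pure LDA corpus with known parameters.

    Returns ``(docs, theta, phi, dominant)``: token lists, the planted D x k
    document-topic matrix, the planted k x V topic-word matrix, and each
    document's dominant planted topic (argmax of its theta row).
    """
    rng = np.random.default_rng(seed)
    vocab = [f"{vocab_prefix}{j:04d}" for j in range(vocab_size)]
    phi = rng.dirichlet(np.full(vocab_size, beta), size=k)
    theta = rng.dirichlet(np.full(k, alpha), size=n_docs)
    lengths = _doc_lengths(rng, n_docs, doc_len_mean, doc_len_dispersion)
    docs = []
    for d in range(n_docs):
        z = rng.choice(k, size=lengths[d], p=theta[d])
        words = [vocab[rng.choice(vocab_size, p=phi[t])] for t in z]
        docs.append(words)
    dominant = theta.argmax(axis=1)
    return docs, theta, phi, dominant


def generate_corpus(spec: SyntheticSpec) -> tuple[Corpus, pd.DataFrame]:
    """Generate a corpus plus a truth table, fully reproducible per seed.

    The truth table has one row per post: ``id``, ``relevant`` (the recorded
    ground-truth label, flipped with probability ``label_noise``),
    ``planted_relevant`` (the construction label driving the embedded term
    count), ``embedded_terms`` (distinct ontology terms placed in the post),
    and ``dominant_topic`` (the argmax of the post's planted topic mixture).
    """
    rng = np.random.default_rng(spec.seed)
    ontology = spec.ontology if spec.ontology is not None else generate_toy_ontology(
        n_classes=4, terms_per_class=5, seed=spec.seed
    )
    terms = flatten_terms(ontology).terms
    n_terms = len(terms)
    lo, hi = spec.relevant_range
    if lo > n_terms:
        raise ValueError(
            f"relevant_range lower bound {lo} exceeds the {n_terms} available ontology terms"
        )
    rel_counts = list(range(lo, min(hi, n_terms) + 1))
    irr_counts = [c for c in spec.irrelevant_low if c <= n_terms]
    irr_counts += list(range(hi + 1, min(n_terms, hi + 4) + 1))
    if not irr_counts:
        raise ValueError("no feasible irrelevant term count for this ontology size")

    bg_docs, theta, phi, dominant = generate_lda_corpus(
        n_docs=spec.n_posts,
        k=spec.k_true,
        vocab_size=spec.vocab_size,
        alpha=spec.alpha,
        beta=spec.beta,
        doc_len_mean=spec.doc_len_mean,
        doc_len_dispersion=spec.doc_len_dispersion,
        seed=int(rng.integers(2**31 - 1)),
    )

    posts: list[Post] = []
    rows = []
    width = len(str(max(spec.n_posts - 1, 1)))
    for i in range(spec.n_posts):
        planted = bool(rng.random() < spec.relevant_fraction)
        count = int(rng.choice(rel_counts)) if planted else int(rng.choice(irr_counts))
        chosen = list(rng.choice(n_terms, size=count, replace=False)) if count else []
        tokens = list(bg_docs[i])
        for t_idx in chosen:
            pos = int(rng.integers(len(tokens) + 1))
            tokens[pos:pos] = terms[t_idx].split()
        recorded = planted
        if spec.label_noise and rng.random() < spec.label_noise:
            recorded = not recorded
        pid = f"p{i:0{width}d}"
        posts.append(Post(id=pid, text=" ".join(tokens)))
        rows.append(
            {
                "id": pid,
                "relevant": int(recorded),
                "planted_relevant": int(planted),
                "embedded_terms": count,
                "dominant_topic": int(dominant[i]),
            }
        )
    truth = pd.DataFrame(rows)
    return Corpus(posts), truth
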