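"""LDA topic discovery: fitting, held-out perplexity, k selection, weights, TF-IDF.

The topic model is standard latent Dirichlet allocation: each document draws a
topic mixture theta ~ Dirichlet(alpha), each topic is a word distribution
phi ~ Dirichlet(beta), and every token is generated by picking a topic from
theta and a word from that topic's phi. Estimation runs through scikit-learn's
variational-Bayes implementation; the fitted model is exposed here as plain
stochastic matrices (phi: k x V, theta: D x k) so that everything downstream
— perplexity, dominant-topic assignment, topic weights — is computed by this
module from first principles and is independent of the estimation backend.

Held-out perplexity is exp(-L/N), evaluated by document completion: each
held-out document's theta is inferred by fold-in EM (phi frozen) from half of
its tokens, and L accumulates over the other half, N of them in vocabulary —
scoring the same tokens used to fit theta would let extra topics always
appear to help. The number of topics is chosen by
fitting a grid of k, watching held-out perplexity fall, and stopping at the
first k whose relative improvement over the previous grid point drops below
``epsilon`` — the "decrease then flatten" rule.

TF-IDF here is pinned to one variant: tf = raw term count in the (sub)corpus,
idf = ln(D / df) over documents, no smoothing. Terms present in every
document therefore score exactly 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import LatentDirichletAllocation

from .preprocess import TokenizedDoc

__all__ = [
    "TopicModel",
    "TopicSummary",
    "ModelSelection",
    "UNASSIGNED",
    "fit_lda",
    "infer_doc_topics",
    "perplexity",
    "select_k",
    "assign_topics",
    "topic_weights",
    "top_words",
    "tfidf_scores",
    "save_model",
    "load_model",
]

UNASSIGNED = -1  # sentinel for documents with no in-vocabulary tokens

_ROW_SUM_TOL = 1e-8


def _as_token_lists(docs) -> list[list[str]]:
    out = []
    for d in docs:
        if isinstance(d, TokenizedDoc):
            out.append(list(d.tokens))
        else:
            out.append(list(d))
    return out


def _build_vocab(token_docs: Sequence[Sequence[str]]) -> list[str]:
    # first-occurrence document order: deterministic for a fixed corpus
    vocab: dict[str, None] = {}
    for doc in token_docs:
        for tok in doc:
            vocab.setdefault(tok)
    return list(vocab)


def _count_matrix(token_docs: Sequence[Sequence[str]], vocab: Sequence[str]) -> sparse.csr_matrix:
    index = {w: j for j, w in enumerate(vocab)}
    rows, cols, vals = [], [], []
    for i, doc in enumerate(token_docs):
        counts: dict[int, int] = {}
        for tok in doc:
            j = index.get(tok)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(c)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(token_docs), len(vocab)), dtype=np.float64
    )


@dataclass
class TopicModel:
    """A fitted k-topic model as plain stochastic matrices.

    ``topic_word`` (phi) is k x V, ``doc_topic`` (theta) is D x k; every row
    of each sums to 1 within 1e-8 (enforced at construction).
    """

    k: int
    alpha: float
    beta: float
    topic_word: np.ndarray
    doc_topic: np.ndarray
    vocab: list[str]
    seed: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        phi = np.asarray(self.topic_word, dtype=np.float64)
        theta = np.asarray(self.doc_topic, dtype=np.float64)
        if phi.shape != (self.k, len(self.vocab)):
            raise ValueError(f"topic_word shape {phi.shape} != (k={self.k}, V={len(self.vocab)})")
        if theta.ndim != 2 or theta.shape[1] != self.k:
            raise ValueError("doc_topic must be D x k")
        for name, m in (("topic_word", phi), ("doc_topic", theta)):
            if m.size and not np.allclose(m.sum(axis=1), 1.0, atol=_ROW_SUM_TOL):
                raise ValueError(f"{name} rows must sum to 1")
        self.topic_word = phi
        self.doc_topic = theta


@dataclass
class TopicSummary:
    topic_id: int
    top_words: list[str]
    weight_count: int
    weight_pct: float


@dataclass
class ModelSelection:
    k_grid: list[int]
    heldout_perplexity: dict[int, float]
    chosen_k: int
    holdout_fraction: float
    seed: int = 0


def fit_lda(
    docs,
    k: int,
    alpha: Optional[float] = None,
    beta: float = 0.01,
    iterations: int = 100,
    seed: int = 0,
) -> TopicModel:
    """Fit a k-topic LDA model on modeling-stage tokenized documents.

    ``alpha`` defaults to 1/k (symmetric document-topic prior), ``beta`` to
    0.01 (topic-word prior). Fitting is deterministic for a fixed seed and
    configuration. Requires at least k documents and a non-empty vocabulary.
    """
    token_docs = _as_token_lists(docs)
    if not token_docs:
        raise ValueError("empty corpus")
    if len(token_docs) < k:
        raise ValueError(f"need at least k={k} documents, got {len(token_docs)}")
    vocab = _build_vocab(token_docs)
    if not vocab:
        raise ValueError("empty vocabulary")
    if alpha is None:
        alpha = 1.0 / k
    X = _count_matrix(token_docs, vocab)
    lda = LatentDirichletAllocation(
        n_components=k,
        doc_topic_prior=alpha,
        topic_word_prior=beta,
        max_iter=iterations,
        learning_method="batch",
        evaluate_every=10,
        random_state=seed,
    )
    lda.fit(X)
    phi = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    theta = lda.transform(X)  # already normalized rows
    return TopicModel(
        k=k, alpha=alpha, beta=beta, topic_word=phi, doc_topic=theta, vocab=list(vocab), seed=seed
    )


def infer_doc_topics(model: TopicModel, docs, n_iter: int = 100) -> np.ndarray:
    """Infer theta rows for new documents by fold-in EM with phi frozen.

    Starts from a uniform mixture and iterates the standard E/M updates; the
    M-step uses the Dirichlet posterior-mean estimate
    theta_dk = (E[n_dk] + alpha) / (n_d + k * alpha), i.e. the model's alpha
    acts as additive smoothing exactly as in collapsed-Gibbs fold-in.
    Deterministic. Documents with no in-vocabulary tokens get a uniform row.
    """
    token_docs = _as_token_lists(docs)
    X = _count_matrix(token_docs, model.vocab).toarray()
    D, k = len(token_docs), model.k
    phi = model.topic_word
    theta = np.full((D, k), 1.0 / k)
    alpha = model.alpha
    for _ in range(n_iter):
        # responsibilities: p(z=k | w, d) proportional to theta_dk * phi_kw
        mix = theta @ phi  # D x V
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(mix > 0, X / mix, 0.0)
        new = theta * (ratio @ phi.T) + alpha
        theta = new / new.sum(axis=1, keepdims=True)
    empty = X.sum(axis=1) == 0
    theta[empty] = 1.0 / k
    return theta


def perplexity(model: TopicModel, docs, n_iter: int = 100) -> float:
    """Held-out perplexity exp(-L/N) by document completion.

    A held-out document's topic mixture theta is unknown, and estimating it
    from the very tokens being scored would let extra topics always help.
    Instead each document is split deterministically into alternating halves:
    theta is inferred by fold-in from the even-position tokens and the log
    likelihood L is accumulated over the N odd-position tokens under
    p(w | d) = sum_k theta_dk phi_kw. Single-token documents contribute to
    inference only. Words outside the model vocabulary are dropped; if no
    evaluable in-vocabulary token remains this raises, since the likelihood
    would be vacuous.
    """
    token_docs = _as_token_lists(docs)
    if not token_docs:
        raise ValueError("held-out set is empty")
    infer_half = [d[0::2] for d in token_docs]
    eval_half = [d[1::2] for d in token_docs]
    X = _count_matrix(eval_half, model.vocab)
    n_tokens = X.sum()
    if n_tokens == 0:
        raise ValueError("all held-out tokens are out of vocabulary or inference-only")
    theta = infer_doc_topics(model, infer_half, n_iter=n_iter)
    mix = theta @ model.topic_word  # D x V
    Xc = X.tocoo()
    loglik = float(np.sum(Xc.data * np.log(mix[Xc.row, Xc.col])))
    return float(np.exp(-loglik / n_tokens))


def select_k(
    docs,
    k_grid: Sequence[int],
    holdout_fraction: float = 0.2,
    epsilon: float = 0.01,
    alpha: Optional[float] = None,
    beta: float = 0.01,
    iterations: int = 100,
    seed: int = 0,
) -> ModelSelection:
    """Choose the topic count where held-out perplexity stops improving.

    Splits documents 80/20 (by default) uniformly at random, fits one model
    per k on the training side, and evaluates perplexity on the held-out side.
    The chosen k is the first grid point whose relative perplexity improvement
    over the previous point falls below ``epsilon``; if the curve keeps
    improving through the whole grid, the last grid point is returned.
    """
    k_grid = list(k_grid)
    if len(k_grid) < 2:
        raise ValueError("k_grid must have at least 2 entries")
    if sorted(k_grid) != k_grid:
        raise ValueError("k_grid must be sorted ascending")
    if not (0.0 < holdout_fraction < 1.0):
        raise ValueError("holdout_fraction must be in (0, 1)")
    token_docs = _as_token_lists(docs)
    n = len(token_docs)
    n_test = int(round(n * holdout_fraction))
    if n_test == 0 or n_test == n:
        raise ValueError(f"degenerate split: {n} docs at holdout_fraction={holdout_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = set(perm[:n_test].tolist())
    train = [token_docs[i] for i in range(n) if i not in test_idx]
    test = [token_docs[i] for i in range(n) if i in test_idx]

    perps: dict[int, float] = {}
    chosen: Optional[int] = None
    for i, k in enumerate(k_grid):
        model = fit_lda(train, k=k, alpha=alpha, beta=beta, iterations=iterations, seed=seed)
        perps[k] = perplexity(model, test)
        if chosen is None and i > 0:
            prev = perps[k_grid[i - 1]]
            improvement = (prev - perps[k]) / prev
            if improvement < epsilon:
                chosen = k
    if chosen is None:
        chosen = k_grid[-1]
    return ModelSelection(
        k_grid=k_grid,
        heldout_perplexity=perps,
        chosen_k=chosen,
        holdout_fraction=holdout_fraction,
        seed=seed,
    )


def assign_topics(model: TopicModel, docs=None) -> np.ndarray:
    """Dominant topic per document: argmax of theta, ties to the lowest id.

    With ``docs=None`` the model's own training documents are used; otherwise
    theta is inferred by fold-in. Documents with no in-vocabulary tokens get
    the ``UNASSIGNED`` (-1) sentinel and are excluded from topic weights.
    """
    if docs is None:
        theta = model.doc_topic
        empty = np.zeros(len(theta), dtype=bool)
    else:
        token_docs = _as_token_lists(docs)
        theta = infer_doc_topics(model, token_docs)
        X = _count_matrix(token_docs, model.vocab)
        empty = np.asarray(X.sum(axis=1)).ravel() == 0
    out = theta.argmax(axis=1)  # np.argmax takes the first maximum: lowest id on ties
    out = out.astype(int)
    out[empty] = UNASSIGNED
    return out


def top_words(model: TopicModel, topic_id: int, n: int = 10) -> list[str]:
    """The n highest-probability words of a topic (ties by vocabulary order)."""
    row = model.topic_word[topic_id]
    order = np.argsort(-row, kind="stable")
    return [model.vocab[j] for j in order[:n]]


def topic_weights(
    assignments: Sequence[int],
    model: Optional[TopicModel] = None,
    n_words: int = 10,
) -> list[TopicSummary]:
    """Topic weights: how many documents have each topic as their dominant one.

    Unassigned documents are excluded; percentages are over assigned documents
    and sum to 100 up to rounding. Sorted by descending count (ties by topic
    id). When a model is supplied, each summary carries the topic's top words.
    """
    arr = np.asarray(list(assignments), dtype=int)
    if arr.size == 0:
        raise ValueError("no assignments")
    assigned = arr[arr != UNASSIGNED]
    n_assigned = len(assigned)
    topics, counts = np.unique(assigned, return_counts=True)
    order = np.lexsort((topics, -counts))
    out = []
    for idx in order:
        t = int(topics[idx])
        c = int(counts[idx])
        words = top_words(model, t, n_words) if model is not None else []
        pct = 100.0 * c / n_assigned if n_assigned else 0.0
        out.append(TopicSummary(topic_id=t, top_words=words, weight_count=c, weight_pct=pct))
    return out


def tfidf_scores(
    docs,
    groups: Optional[Sequence[int]] = None,
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Unigram TF-IDF per term within each group of documents.

    tf is the raw count of the term in the group's pooled subcorpus; idf is
    ln(D/df) with D the total number of documents and df the number of
    documents (anywhere, not just the group) containing the term. With
    ``groups=None`` each document is its own group. Returns a DataFrame with
    columns group, term, tf, idf, score, sorted by (group, -score, term);
    ``top_n`` keeps the highest-scoring terms per group.
    """
    token_docs = _as_token_lists(docs)
    if not token_docs:
        raise ValueError("empty document collection")
    D = len(token_docs)
    if groups is None:
        groups = list(range(D))
    groups = list(groups)
    if len(groups) != D:
        raise ValueError("groups must align with docs")
    df_count: dict[str, int] = {}
    for doc in token_docs:
        for tok in set(doc):
            df_count[tok] = df_count.get(tok, 0) + 1
    rows = []
    group_ids = sorted({g for g in groups if g != UNASSIGNED})
    for g in group_ids:
        tf: dict[str, int] = {}
        for doc, gg in zip(token_docs, groups):
            if gg != g:
                continue
            for tok in doc:
                tf[tok] = tf.get(tok, 0) + 1
        for term, c in tf.items():
            idf = math.log(D / df_count[term])
            rows.append((g, term, c, idf, c * idf))
    out = pd.DataFrame(rows, columns=["group", "term", "tf", "idf", "score"])
    out = out.sort_values(["group", "score", "term"], ascending=[True, False, True], kind="stable")
    if top_n is not None:
        out = out.groupby("group", group_keys=False).head(top_n)
    return out.reset_index(drop=True)


# --- model persistence (text-only artifact directory) -------------------


def save_model(model: TopicModel, outdir) -> None:
    """Write vocab, phi, theta (CSV) and JSON metadata to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "vocab.txt").write_text("\n".join(model.vocab) + "\n", encoding="utf-8")
    np.savetxt(out / "topic_word.csv", model.topic_word, delimiter=",")
    np.savetxt(out / "doc_topic.csv", model.doc_topic, delimiter=",")
    meta = {"k": model.k, "alpha": model.alpha, "beta": model.beta, "seed": model.seed}
    (out / "meta.json").write_text(json.dumps(meta, indent=2) + "\n", encoding="utf-8")


def load_model(indir) -> TopicModel:
    """Load a model written by :func:`save_model`."""
    d = Path(indir)
    meta = json.loads((d / "meta.json").read_text(encoding="utf-8"))
    vocab = (d / "vocab.txt").read_text(encoding="utf-8").splitlines()
    phi = np.loadtxt(d / "topic_word.csv", delimiter=",", ndmin=2)
    theta = np.loadtxt(d / "doc_topic.csv", delimiter=",", ndmin=2)
    # re-normalize to absorb round-trip rounding
    phi = phi / phi.sum(axis=1, keepdims=True)
    theta = theta / theta.sum(axis=1, keepdims=True)
    return TopicModel(
        k=int(meta["k"]),
        alpha=float(meta["alpha"]),
        beta=float(meta["beta"]),
        topic_word=phi,
        doc_topic=theta,
        vocab=vocab,
        seed=int(meta["seed"]),
    )
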