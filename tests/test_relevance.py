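"""Evaluation matrix, quality-score filter, classifier metrics, Cohen's kappa."""

import numpy as np
import pytest

from infoveil.ontology import TermSet
from infoveil.preprocess import Corpus, Post, clean_text
from infoveil.relevance import (
    ConfusionCounts,
    build_matrix,
    cohen_kappa,
    confusion,
    filter_relevant,
    metrics,
    read_labels_csv,
    write_matrix_csv,
)


def brute_force_match(post_text: str, term: str) -> bool:
    """Independent contiguous token-sequence matcher (plain loop)."""
    toks = clean_text(post_text, "scoring").split()
    tt = clean_text(term, "scoring").split()
    if not tt:
        return False
    for i in range(len(toks) - len(tt) + 1):
        if toks[i : i + len(tt)] == tt:
            return True
    return False


def random_corpus_and_terms(rng):
    terms = [f"kw{j}" for j in range(15)] + ["two word", "long slang phrase"]
    posts = []
    for i in range(int(rng.integers(3, 30))):
        n = int(rng.integers(0, 14))
        words = list(rng.choice(terms[:15], size=n, replace=False)) if n else []
        words += ["filler"] * int(rng.integers(0, 5))
        rng.shuffle(words)
        posts.append(Post(f"p{i}", " ".join(words)))
    return Corpus(posts), TermSet(list(terms))


class TestBuildMatrix:
    def test_row_score_label_example(self):
        c = Corpus([Post("1", "need oxy and percocet now")])
        m = build_matrix(c, TermSet(["oxy", "percocet", "heroin"]))
        assert m.cells[0].tolist() == [1, 1, 0]
        assert m.scores[0] == 2
        assert m.labels[0] == 1

    def test_zero_and_overloaded_posts_not_relevant(self):
        terms = TermSet([f"kw{j}" for j in range(12)])
        c = Corpus([
            Post("none", "no matching words at all"),
            Post("eleven", " ".join(f"kw{j}" for j in range(11))),
        ])
        m = build_matrix(c, terms)
        assert m.scores.tolist() == [0, 11]
        assert m.labels.tolist() == [0, 0]

    def test_presence_is_binary_under_repetition(self):
        c = Corpus([Post("r", "oxy oxy oxy oxy oxy")])
        m = build_matrix(c, TermSet(["oxy"]))
        assert m.cells[0, 0] == 1 and m.scores[0] == 1

    def test_single_word_term_never_fires_inside_longer_token(self):
        c = Corpus([Post("x", "prescribed oxycodone yesterday")])
        m = build_matrix(c, TermSet(["oxy", "oxycodone"]))
        assert m.cells[0].tolist() == [0, 1]

    def test_multiword_term_matches_exact_ngram(self):
        c = Corpus([Post("x", "he was on the nod all night"), Post("y", "on a nod")])
        m = build_matrix(c, TermSet(["on the nod"]))
        assert m.cells[:, 0].tolist() == [1, 0]

    def test_empty_term_set_rejected_empty_corpus_ok(self):
        with pytest.raises(ValueError, match="empty"):
            build_matrix(Corpus([Post("a", "x")]), TermSet([]))
        m = build_matrix(Corpus([]), TermSet(["oxy"]))
        assert m.cells.shape == (0, 1)

    def test_agrees_with_brute_force_matcher(self):
        """Cell-for-cell agreement with an independent n-gram matcher, 1000+ pairs."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            corpus, terms = random_corpus_and_terms(rng)
            m = build_matrix(corpus, terms)
            for i, post in enumerate(corpus):
                for j, term in enumerate(terms.terms):
                    assert bool(m.cells[i, j]) == brute_force_match(post.text, term)
                    checked += 1

    def test_matrix_invariants_on_random_corpora(self):
        """Binarity, score=row sum, label<=>band, widening monotonicity; 100 corpora."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            corpus, terms = random_corpus_and_terms(rng)
            lo = int(rng.integers(0, 4))
            hi = int(rng.integers(lo, 14))
            m = build_matrix(corpus, terms, lo=lo, hi=hi)
            assert np.isin(m.cells, (0, 1)).all()
            assert (m.scores == m.cells.sum(axis=1)).all()
            assert (m.labels == ((m.scores >= lo) & (m.scores <= hi))).all()
            wide = build_matrix(corpus, terms, lo=max(lo - 1, 0), hi=hi + 1)
            assert wide.labels.sum() >= m.labels.sum()


class TestFilter:
    def _corpus_with_scores(self, scores):
        terms = TermSet([f"kw{j}" for j in range(max(scores) + 1)] if max(scores) else ["kw0"])
        posts = [
            Post(f"p{i}", " ".join(f"kw{j}" for j in range(s)) or "nothing")
            for i, s in enumerate(scores)
        ]
        return Corpus(posts), terms

    @pytest.mark.parametrize(
        "scores, n_retained",
        [
            ((0, 2, 10, 11, 3), 3),
            ((0, 0, 0), 0),
            ((2, 2, 2), 3),  # boundary inclusive
        ],
    )
    def test_threshold_partition(self, scores, n_retained):
        corpus, terms = self._corpus_with_scores(scores)
        m = build_matrix(corpus, terms)
        rel, exc = filter_relevant(m, corpus)
        assert len(rel) == n_retained
        assert len(rel) + len(exc) == len(corpus)

    def test_misaligned_corpus_rejected(self):
        corpus, terms = self._corpus_with_scores((2, 3))
        m = build_matrix(corpus, terms)
        other = Corpus([Post("z1", "a"), Post("z2", "b")])
        with pytest.raises(ValueError, match="align"):
            filter_relevant(m, other)


class TestConfusionMetrics:
    def test_all_predicted_relevant_regime(self):
        pred = [1] * 1000
        truth = [1] * 764 + [0] * 236
        c = confusion(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (764, 236, 0, 0)

    def test_perfect_prediction(self):
        truth = [0, 1, 1, 0, 1]
        c = confusion(truth, truth)
        assert c.fp == 0 and c.fn == 0
        m = metrics(c)
        assert m.precision == m.recall == m.f_measure == m.accuracy == 1.0

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(5)
        pred = rng.integers(0, 2, size=20)
        truth = rng.integers(0, 2, size=20)
        c = confusion(pred, truth)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for p, t in zip(pred, truth):
            tally[{(1, 1): "tp", (1, 0): "fp", (0, 1): "fn", (0, 0): "tn"}[(p, t)]] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tally["tp"], tally["fp"], tally["fn"], tally["tn"])
        assert c.total == 20

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])

    @pytest.mark.parametrize(
        "counts, expected",
        [
            # search query alone: every post predicted relevant
            ((764, 236, 0, 0), {"precision": 0.764, "recall": 1.000, "f_measure": 0.866, "accuracy": 0.764}),
            # with the evaluation-matrix filter applied
            ((738, 46, 26, 190), {"precision": 0.941, "recall": 0.966, "f_measure": 0.953, "accuracy": 0.928}),
        ],
    )
    def test_published_benchmark_metrics(self, counts, expected):
        m = metrics(ConfusionCounts(*counts)).rounded(3)
        assert m == expected

    def test_undefined_metrics_are_explicit(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert m.precision is None
        assert m.accuracy == 1.0
        assert m.rounded()["precision"] is None


class TestKappa:
    def test_perfect_agreement_is_one(self):
        labels = [0, 1, 1, 0, 1, 0]
        assert cohen_kappa(labels, labels) == 1.0

    def test_hand_computed_table(self):
        # agreement table (40, 10, 10, 40): p_o = 0.8, p_e = 0.5 -> kappa 0.6
        a = [0] * 50 + [1] * 50
        b = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        assert cohen_kappa(a, b) == pytest.approx(0.6)

    def test_chance_level_agreement_near_zero(self):
        # constructed so observed agreement equals the marginal product exactly
        a = [0, 0, 1, 1]
        b = [0, 1, 0, 1]
        assert cohen_kappa(a, b) == pytest.approx(0.0)

    def test_permutation_oracle(self):
        """kappa recomputed from the full 2x2 table definition on random vectors."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            a = rng.integers(0, 2, size=n).tolist()
            b = rng.integers(0, 2, size=n).tolist()
            p_o = sum(x == y for x, y in zip(a, b)) / n
            p_e = sum(
                (a.count(v) / n) * (b.count(v) / n) for v in (0, 1)
            )
            if p_e == 1.0:
                continue
            assert cohen_kappa(a, b) == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa([1], [1, 0])
        with pytest.raises(ValueError):
            cohen_kappa([], [])


class TestMatrixIO:
    def test_csv_layout_round_trips_labels(self, tmp_path):
        c = Corpus([Post("1", "oxy percocet"), Post("2", "nothing")])
        m = build_matrix(c, TermSet(["oxy", "percocet"]))
        path = tmp_path / "matrix.csv"
        write_matrix_csv(m, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "id,oxy,percocet,score,label"
        assert lines[1] == "1,1,1,2,1"
        assert lines[2] == "2,0,0,0,0"

    def test_labels_csv_reader(self, tmp_path):
        p = tmp_path / "truth.csv"
        p.write_text("id,label\na,1\nb,0\n")
        assert read_labels_csv(p) == {"a": 1, "b": 0}
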