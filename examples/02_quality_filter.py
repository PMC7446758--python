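"""Quality scoring: the posts x terms evaluation matrix and the [2,10] filter.

Each post's quality score is the number of distinct ontology terms it
contains; posts scoring 2-10 are kept as relevant (a single keyword is too
weak a signal, more than ten means the post's context is too scattered).
"""

from infoveil import (
    Corpus,
    Post,
    build_matrix,
    confusion,
    filter_relevant,
    flatten_terms,
    load_toy_ontology,
    metrics,
)

corpus = Corpus([
    Post("a", "my doctor put me on oxycodone after surgery and now the withdrawal is brutal"),
    Post("b", "great weather in boston today"),
    Post("c", "naloxone saves lives during an overdose, carry narcan"),
    Post("d", "opioid opioids opiate opiates heroin fentanyl oxy percs smack dope lean rehab"),
])

terms = flatten_terms(load_toy_ontology())
matrix = build_matrix(corpus, terms, lo=2, hi=10)
for pid, score, label in zip(matrix.post_ids, matrix.scores, matrix.labels):
    print(f"post {pid}: score {score:2d} -> {'relevant' if label else 'not relevant'}")

retained, excluded = filter_relevant(matrix, corpus)
print(f"\nretained {len(retained)} of {len(corpus)} posts")
# 'a' and 'c' carry 2-10 distinct domain terms; 'b' has none; 'd' crams in
# 12 distinct terms, which the upper threshold rejects as keyword noise.

truth = [1, 0, 1, 0]  # what a human rater would say
c = confusion(matrix.labels.tolist(), truth)
m = metrics(c).rounded(3)
print(f"vs ground truth: tp={c.tp} fp={c.fp} fn={c.fn} tn={c.tn}; {m}")
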