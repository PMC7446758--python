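"""Topic discovery: select k by held-out perplexity, fit LDA, weigh topics.

On a synthetic corpus with five planted topics the held-out perplexity falls
steeply until the true topic count and then flattens; the selection rule
stops at the first grid point whose relative improvement drops below 1%.
"""

from infoveil import fit_lda, select_k, tfidf_scores, topic_weights
from infoveil.synthetic import generate_lda_corpus
from infoveil.topics import assign_topics

docs, theta, phi, dominant = generate_lda_corpus(
    n_docs=800, k=5, vocab_size=200, seed=42
)

sel = select_k(docs, k_grid=[2, 3, 4, 5, 6, 7, 8], holdout_fraction=0.2, seed=42)
print("held-out perplexity by k:")
for k in sel.k_grid:
    marker = "  <- chosen" if k == sel.chosen_k else ""
    print(f"  k={k}: {sel.heldout_perplexity[k]:7.2f}{marker}")

model = fit_lda(docs, k=sel.chosen_k, seed=42)
assignments = assign_topics(model)
print("\ntopic weights (share of documents whose dominant topic this is):")
for s in topic_weights(assignments, model=model, n_words=5):
    print(f"  topic {s.topic_id}: {s.weight_count:4d} docs ({s.weight_pct:5.2f}%)  "
          f"top words: {', '.join(s.top_words)}")

table = tfidf_scores(docs, groups=assignments, top_n=3)
print("\ntop TF-IDF terms per topic (word-cloud sizing scores):")
print(table.to_string(index=False))
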