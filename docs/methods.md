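# Methods

This note documents the models, procedures and numerical choices behind
`infoveil`, in the order the pipeline runs them.

## Ontology and term matching

The ontology is a strict tree of named nodes (`theme` / `class` /
`subclass`), each carrying zero or more surface terms; every leaf must carry
at least one term. Terms are case-folded once at load time and all matching
downstream is case-insensitive — social-media capitalization carries no
signal. Flattening traverses depth-first in document order and deduplicates,
keeping the first node that introduced each term as its provenance; this
fixed order makes query strings and matrix columns reproducible.

A term matches a post only as a **contiguous whole-token sequence** on
scoring-cleaned text: single-word terms match whole tokens (so `oxy` never
fires inside an `oxycodone` token, and `heroin` never inside `heroine`),
multiword terms match exact token n-grams. Substring matching was rejected
because drug slang is riddled with embeddings of one term in another.
Coverage counts per ontology node use this same matcher, so the coverage
tree and the evaluation matrix can never disagree about what "contains a
term" means.

## Preprocessing

Cleaning runs in two stages because its two consumers need different views:

* **scoring** — remove URLs, @-handles, emoji (by Unicode pictograph
  blocks), and punctuation; case-fold; **keep stopwords**. Quality scoring
  must see multiword ontology phrases intact, and some ("on the nod")
  consist mostly of stopwords.
* **modeling** — scoring plus stopword removal, for the topic-model
  bag-of-words.

Both stages are idempotent. The stopword list is packaged and fixed
(a standard ~170-word English list) rather than taken from a library default,
so results cannot drift with a dependency upgrade; it can be overridden per
call. Lemmatization is a deliberately small rule-based English lemmatizer
(regular plurals, -ing/-ed forms with undoubling and silent-e restoration,
a short irregular table biased toward health/drug vocabulary). It is not a
dictionary lemmatizer and will leave rare forms untouched; the exact outputs
of the packaged configuration are pinned by golden-file tests, and any
callable can be substituted via `tokenize_lemmatize(lemmatizer=...)`.

## Quality scoring and the relevance filter

The evaluation matrix is binary by definition: presence, not frequency. The
quality score is therefore the count of **distinct** ontology terms in the
post, and the relevance label applies the inclusive band [lo, hi], default
[2, 10]. The rationale for the defaults: two independent domain terms make
topical relevance plausible, while more than ten distinct terms in a
tweet-length post indicates scattered, low-quality keyword noise. The
thresholds are parameters everywhere they appear; no optimality claim is
attached to the defaults.

Metrics are computed at full precision and displayed rounded half-even to 3
decimals. A metric with a zero denominator (e.g. precision with no positive
predictions) is reported as an explicit *undefined* (`None`), never silently
as 0. Cohen's κ uses the standard marginal-product chance correction and is
defined over arbitrary label alphabets; the degenerate case p_e = 1 returns
1 for perfect agreement.

## Topic model

Standard LDA: θ_d ~ Dirichlet(α), φ_k ~ Dirichlet(β), token topics
z ~ Cat(θ_d), words w ~ Cat(φ_z). Estimation is variational Bayes
(scikit-learn's batch implementation) behind a stable interface; the fitted
model is exported as plain stochastic matrices φ (k × V) and θ (D × k), and
every downstream quantity is computed from those matrices by this package,
independent of the estimation backend. Fits are bit-reproducible for a fixed
seed and configuration.

Defaults: α = 1/k, β = 0.01, `iterations` = 100. One hundred batch EM sweeps
with a perplexity-based early stop (checked every 10 sweeps) is ample for
variational convergence at the corpus sizes this package targets; the value
is configurable for users who want longer runs.

### Held-out perplexity and choosing k

Perplexity is exp(−L/N) over held-out tokens with L evaluated under point
estimates: p(w | d) = Σ_k θ̂_dk φ̂_kw. Because a held-out document's θ is
unknown, it must be inferred — and inferring it from the same tokens being
scored lets extra topics always appear to help, which destroys the
"decrease then flatten" signal the selection rule needs. We therefore use
**document completion**: each held-out document is split deterministically
into alternating halves; θ̂ is estimated by fold-in EM (φ frozen,
Dirichlet posterior-mean smoothing with the model's α, uniform
initialization, 100 iterations — fully deterministic) on the even-position
tokens, and L accumulates over the odd-position tokens. Words outside the
training vocabulary are dropped; single-token documents contribute to
inference only. The closed forms survive exactly: a uniform single-topic
model over V words has perplexity V for any held-out corpus, and a one-topic
model with φ(a) = 0.5 scores perplexity 2 on the document "a a".

`select_k` splits documents uniformly at random (default 20% held out,
seeded), fits one model per grid point, and chooses the smallest k whose
relative held-out-perplexity improvement over the previous grid point falls
below ε (default 0.01). A strictly flat curve therefore yields the second
grid point; a curve that keeps improving yields the last. On planted
corpora (k_true = 5, 2000 documents, vocabulary 500 — the scale used
throughout the tests because it is large enough for reliable recovery and
small enough to iterate on) the rule lands in {4, 5, 6} in most seeds;
because it stops at the first *flat* point, it lands one above the truth
about as often as exactly on it. The choice is an elbow heuristic, not an
estimator with guarantees.

### Assignments, weights, TF-IDF

The dominant topic of a document is the argmax of its θ row, ties broken
toward the lowest topic id; documents with no in-vocabulary tokens get a
sentinel and are excluded from weights. Topic weights are dominant-topic
counts and percentages over assigned documents, sorted descending — the
shape of the final "what does the public discuss" table.

TF-IDF is pinned to one unambiguous variant: tf = raw count of the term in
the (sub)corpus, idf = ln(D/df) over all documents, no smoothing, so a term
in every document scores exactly 0. When grouped by dominant topic, the
per-topic top-n tables are the intended input for word-cloud rendering
(which this package does not do).

## Synthetic corpora

The generator emulates the statistical skeleton of short drug-discussion
posts: each post draws a planted relevance label (default fraction 0.5),
embeds the corresponding number of distinct ontology terms (relevant:
uniform on [2, 10]; irrelevant: {0, 1} or 11–14), and pads to a
negative-binomial length truncated to 5–50 tokens (mean 18 — tweet scale)
with background words from a k_true-topic LDA process (defaults k_true = 5,
α = 0.3 for the concentrated mixtures short posts exhibit, β = 0.01 for
well-separated topics, vocabulary 500). The background vocabulary is
disjoint from the ontology terms by construction, and generated ontologies
use unique single-token terms, so a noiseless run recovers the planted
relevant set *exactly* — the end-to-end tests rely on this identity.
`label_noise` flips the recorded ground-truth label (not the construction),
producing calibrated false positives/negatives whose expected metric values
are checked analytically in the tests.

What passing on synthetic data does **not** show: robustness to real
linguistic variation (misspellings, morphology of slang, sarcasm), to
ontology terms that overlap one another textually, or to the heavy-tailed
document-length and topic-imbalance structure of a live platform stream.

## Pipeline and determinism

One YAML config drives all phases; a single global seed is fanned out into
independent per-stage seeds via `numpy.random.SeedSequence.spawn`, so adding
a stage never perturbs another stage's stream. Re-running a config
reproduces the evaluation matrix, topic table and TF-IDF table byte for
byte. Every stage logs record counts in/out, and the run report lists every
artifact written.

## Known limitations

* The packaged opioid ontology is a 50-term toy standing in for a full
  research vocabulary (>250 terms); coverage numbers on it are
  illustrative only.
* The rule lemmatizer under-normalizes rare or irregular forms.
* The query dialect is generic boolean, not any specific platform's syntax.
* κ is implemented and tested as a formula; real interrater agreement
  requires per-rater labels that only a human study can provide.
* Variational LDA can land in local optima on small corpora; the seed is
  part of the result and is recorded in every model artifact.
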