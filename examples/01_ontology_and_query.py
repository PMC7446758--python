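"""Topic expansion: load the toy opioid ontology, flatten it, build a query.

The ontology organizes the domain vocabulary (formal drug names, symptoms,
slang, recovery terms) into a tree; flattening a subtree yields the keyword
list that drives both search-query generation and relevance scoring.
"""

from infoveil import QuerySpec, build_query, flatten_terms, load_toy_ontology

root = load_toy_ontology()
terms = flatten_terms(root)
print(f"ontology '{root.name}': {len(terms)} distinct terms")
print("first ten:", ", ".join(terms.terms[:10]))

opioid = flatten_terms(root, "drug abuse/opioid drug")
print(f"\n'opioid drug' subtree: {len(opioid)} terms")

spec = QuerySpec(
    term_set=opioid,
    language="en",
    location="United States",
    exclude_retweets=True,
    exclude_urls=True,
    date_range=("2018-06-29", "2019-04-11"),
)
query = build_query(spec)
print("\nsearch query (generic boolean dialect):")
print(query[:200] + ("..." if len(query) > 200 else ""))
# Every ontology term appears OR-ed (multiword terms quoted); the trailing
# clauses restrict language, place, date window, and drop retweets/URL posts.
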