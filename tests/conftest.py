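import numpy as np
import pytest

from infoveil.ontology import OntologyNode, TermSet, load_toy_ontology
from infoveil.preprocess import Corpus, Post


@pytest.fixture(scope="session")
def toy_ontology() -> OntologyNode:
    return load_toy_ontology()


@pytest.fixture()
def small_tree() -> OntologyNode:
    """3 nodes x 2 distinct terms each (disjoint)."""
    return OntologyNode(
        name="root",
        kind="theme",
        terms=["r1", "r2"],
        children=[
            OntologyNode(name="a", terms=["a1", "a2"]),
            OntologyNode(name="b", terms=["b1", "b2"]),
        ],
    )


@pytest.fixture()
def tiny_corpus() -> Corpus:
    return Corpus(
        [
            Post("t1", "need oxy and percocet now"),
            Post("t2", "nothing to see here"),
            Post("t3", "heroin heroin heroin"),
        ]
    )


def random_tree(rng: np.random.Generator, depth: int = 0, counter=None) -> OntologyNode:
    """Small random ontology tree for property tests; terms may repeat across nodes."""
    if counter is None:
        counter = [0]
    counter[0] += 1
    pool = [f"term{j}" for j in range(12)]
    n_terms = int(rng.integers(0, 4))
    terms = list(rng.choice(pool, size=n_terms, replace=False)) if n_terms else []
    children = []
    if depth < 2:
        for i in range(int(rng.integers(0, 3))):
            children.append(random_tree(rng, depth + 1, counter))
    if not terms and not children:
        terms = [str(rng.choice(pool))]
    # unique child names within the parent
    for i, c in enumerate(children):
        c.name = f"n{counter[0]}_{i}"
    return OntologyNode(name=f"n{counter[0]}", terms=terms, children=children)
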