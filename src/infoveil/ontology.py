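"""Hierarchical drug-abuse ontology: loading, flattening, query generation, coverage.

The ontology is a strict tree of themes, classes and subclasses; each node may
carry surface *terms* (instances, possibly multiword, e.g. ``"on the nod"``).
Flattening a subtree yields the ordered, case-folded, deduplicated term list
that drives both boolean search-query generation and the relevance evaluation
matrix. Terms are case-folded once at load time and matched case-insensitively
everywhere downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Optional, Sequence

__all__ = [
    "OntologyNode",
    "TermSet",
    "QuerySpec",
    "OntologyError",
    "load_ontology",
    "load_toy_ontology",
    "flatten_terms",
    "build_query",
    "parse_query_terms",
    "coverage_tree",
]

_KINDS = ("theme", "class", "subclass")


class OntologyError(ValueError):
    """Raised for schema violations, broken invariants, or bad lookups."""


@dataclass
class OntologyNode:
    """One node of the ontology tree.

    ``kind`` is one of ``theme`` / ``class`` / ``subclass``; ``terms`` are the
    surface strings attached directly to this node (already case-folded after
    :func:`load_ontology`); ``children`` are sub-nodes.
    """

    name: str
    kind: str = "class"
    terms: list[str] = field(default_factory=list)
    children: list["OntologyNode"] = field(default_factory=list)

    def walk(self, prefix: tuple[str, ...] = ()) -> Iterator[tuple[tuple[str, ...], "OntologyNode"]]:
        """Depth-first, document-order traversal yielding (path, node)."""
        path = prefix + (self.name,)
        yield path, self
        for child in self.children:
            yield from child.walk(path)

    def find(self, path: Sequence[str] | str) -> "OntologyNode":
        """Return the node at *path* ("a/b/c" or sequence of names)."""
        parts = path.split("/") if isinstance(path, str) else list(path)
        if not parts or parts[0] != self.name:
            raise OntologyError(f"path {parts!r} does not start at root {self.name!r}")
        node = self
        for name in parts[1:]:
            for child in node.children:
                if child.name == name:
                    node = child
                    break
            else:
                raise OntologyError(f"no node named {name!r} under {node.name!r}")
        return node


@dataclass
class TermSet:
    """Ordered, deduplicated, case-folded term list with node-path provenance.

    ``origin`` maps each term to the path of the first node (in depth-first
    document order) that carries it.
    """

    terms: list[str]
    origin: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)

    def __contains__(self, term: str) -> bool:
        return term.casefold() in set(self.terms)


@dataclass
class QuerySpec:
    """Restrictions wrapped around a term set to form a boolean search query."""

    term_set: TermSet
    language: Optional[str] = None
    location: Optional[str] = None
    exclude_retweets: bool = False
    exclude_urls: bool = False
    date_range: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.date_range is not None:
            start, end = self.date_range
            if start > end:
                raise OntologyError(f"date_range start {start!r} after end {end!r}")


def _validate_node(obj: dict, path: tuple[str, ...]) -> OntologyNode:
    if not isinstance(obj, dict):
        raise OntologyError(f"node at {'/'.join(path) or '<root>'} is not an object")
    name = obj.get("name")
    if not isinstance(name, str) or not name.strip():
        raise OntologyError(f"node under {'/'.join(path) or '<root>'} has no valid 'name'")
    kind = obj.get("kind", "class")
    if kind not in _KINDS:
        raise OntologyError(f"node {name!r}: kind {kind!r} not in {_KINDS}")
    raw_terms = obj.get("terms", [])
    if not isinstance(raw_terms, list) or any(not isinstance(t, str) or not t.strip() for t in raw_terms):
        raise OntologyError(f"node {name!r}: 'terms' must be a list of non-empty strings")
    terms = [t.strip().casefold() for t in raw_terms]
    raw_children = obj.get("children", [])
    if not isinstance(raw_children, list):
        raise OntologyError(f"node {name!r}: 'children' must be a list")
    here = path + (name,)
    children = [_validate_node(c, here) for c in raw_children]
    seen: set[str] = set()
    for child in children:
        if child.name in seen:
            raise OntologyError(f"node {name!r}: duplicate child name {child.name!r}")
        seen.add(child.name)
    if not terms and not children:
        raise OntologyError(f"leaf node {name!r} has neither terms nor children")
    return OntologyNode(name=name, kind=kind, terms=terms, children=children)


def load_ontology(path) -> OntologyNode:
    """Load and validate an ontology JSON tree.

    Schema: ``{"name": str, "kind": "theme"|"class"|"subclass",
    "terms": [str, ...], "children": [<node>, ...]}``; every leaf must carry at
    least one term. Terms are case-folded on load. Raises :class:`OntologyError`
    naming the offending node on any schema violation.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise OntologyError(f"{path}: not valid JSON: {exc}") from exc
    return _validate_node(obj, ())


def load_toy_ontology() -> OntologyNode:
    """Load the packaged toy opioid ontology (a small stand-in vocabulary)."""
    ref = resources.files("infoveil").joinpath("data/toy_opioid_ontology.json")
    with resources.as_file(ref) as p:
        return load_ontology(p)


def flatten_terms(root: OntologyNode, subtree: Sequence[str] | str | None = None) -> TermSet:
    """Collect all terms of a subtree into an ordered, deduplicated TermSet.

    Order is depth-first document order; a term carried by several nodes keeps
    the provenance of the first node that introduced it.
    """
    node = root if subtree is None else root.find(subtree)
    prefix: tuple[str, ...] = ()
    if subtree is not None:
        parts = subtree.split("/") if isinstance(subtree, str) else list(subtree)
        prefix = tuple(parts[:-1])
    terms: list[str] = []
    origin: dict[str, tuple[str, ...]] = {}
    for path, n in node.walk(prefix):
        for term in n.terms:
            if term not in origin:
                origin[term] = path
                terms.append(term)
    return TermSet(terms=terms, origin=origin)


def _quote(term: str) -> str:
    return f'"{term}"' if " " in term else term


def build_query(spec: QuerySpec) -> str:
    """Render a QuerySpec as a generic boolean query string.

    All terms are OR-ed (multiword terms quoted); restrictions are appended as
    AND clauses (``lang:``, ``location:``, ``since:``/``until:``, and negated
    ``-is:retweet`` / ``-has:url``). Deterministic for a given spec.
    """
    if not spec.term_set.terms:
        raise OntologyError("cannot build a query from an empty term set")
    clause = "(" + " OR ".join(_quote(t) for t in spec.term_set.terms) + ")"
    parts = [clause]
    if spec.language:
        parts.append(f"lang:{spec.language}")
    if spec.location:
        parts.append(f'location:"{spec.location}"')
    if spec.date_range:
        parts.append(f"since:{spec.date_range[0]}")
        parts.append(f"until:{spec.date_range[1]}")
    if spec.exclude_retweets:
        parts.append("-is:retweet")
    if spec.exclude_urls:
        parts.append("-has:url")
    return " AND ".join(parts)


def parse_query_terms(query: str) -> list[str]:
    """Recover the term list from a query built by :func:`build_query`."""
    if not query.startswith("("):
        raise OntologyError("query does not start with a term clause")
    depth_end = query.index(")")
    inner = query[1:depth_end]
    terms = []
    for raw in inner.split(" OR "):
        raw = raw.strip()
        if raw.startswith('"') and raw.endswith('"'):
            raw = raw[1:-1]
        if raw:
            terms.append(raw)
    return terms


def coverage_tree(root: OntologyNode, corpus) -> dict[tuple[str, ...], int]:
    """Count, for every node, the posts matching >= 1 term of its subtree.

    A post matching terms under two sibling subtrees is counted once in each
    sibling and once (not twice) at their parent. Matching uses the same
    token-sequence matcher as the relevance evaluation matrix, so coverage
    numbers and quality scores are consistent with each other.
    """
    from .relevance import _match_posts  # shared matcher, avoids an import cycle

    all_terms = flatten_terms(root)
    post_term = _match_posts(corpus, all_terms.terms)  # n_posts x n_terms bool
    col = {t: j for j, t in enumerate(all_terms.terms)}
    counts: dict[tuple[str, ...], int] = {}
    for path, node in root.walk():
        sub = flatten_terms(root, path)
        idx = [col[t] for t in sub.terms]
        counts[path] = int(post_term[:, idx].any(axis=1).sum()) if idx else 0
    return counts
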