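"""Post cleaning, tokenization, lemmatization, and corpus I/O.

Cleaning runs in two stages matched to the two consumers downstream:

* ``scoring`` — strip URLs, user handles, emoji and punctuation, case-fold,
  but **keep stopwords**: quality scoring must still see multiword ontology
  phrases intact (some, like "on the nod", contain stopwords).
* ``modeling`` — everything in ``scoring`` plus stopword removal, for the
  topic-model bag-of-words.

Lemmatization is a lightweight rule-based English lemmatizer (plural nouns
and common verb inflections, a small irregular table); its exact outputs are
pinned by golden-file tests. Swap in your own by passing ``lemmatizer=`` to
:func:`tokenize_lemmatize`.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterator, Optional

__all__ = [
    "Post",
    "Corpus",
    "TokenizedDoc",
    "CorpusError",
    "clean_text",
    "tokenize",
    "lemmatize",
    "tokenize_lemmatize",
    "default_stopwords",
    "read_corpus",
    "write_corpus",
]


class CorpusError(ValueError):
    """Raised for malformed corpus files or duplicate post ids."""


@dataclass
class Post:
    id: str
    text: str
    meta: dict = field(default_factory=dict)


@dataclass
class Corpus:
    """Ordered collection of posts with unique ids."""

    posts: list[Post]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.posts:
            if p.id in seen:
                raise CorpusError(f"duplicate post id {p.id!r}")
            seen.add(p.id)

    def __len__(self) -> int:
        return len(self.posts)

    def __iter__(self) -> Iterator[Post]:
        return iter(self.posts)

    def ids(self) -> list[str]:
        return [p.id for p in self.posts]

    def texts(self) -> list[str]:
        return [p.text for p in self.posts]


@dataclass
class TokenizedDoc:
    post_id: str
    tokens: list[str]
    raw_token_count: int


# --- cleaning -----------------------------------------------------------

_URL_RE = re.compile(r"""(?:https?://|www\.)\S+""", re.IGNORECASE)
_HANDLE_RE = re.compile(r"@\w+")
# Unicode emoji / pictograph blocks plus variation selectors and ZWJ.
_EMOJI_RE = re.compile(
    "["
    "\U0001F000-\U0001FAFF"  # mahjong..symbols-extended (covers emoticons, transport, supplemental)
    "\U00002600-\U000027BF"  # misc symbols, dingbats
    "\U0001F1E6-\U0001F1FF"  # regional indicators (flags)
    "\U00002B00-\U00002BFF"  # misc symbols and arrows (stars)
    "\U0000FE0E\U0000FE0F\U0000200D"
    "]+"
)
_KEEP_RE = re.compile(r"[^\w\s'-]", re.UNICODE)
_WS_RE = re.compile(r"\s+")

_STOPWORDS: Optional[frozenset[str]] = None


def default_stopwords() -> frozenset[str]:
    """The packaged English stopword list (fixed for reproducibility)."""
    global _STOPWORDS
    if _STOPWORDS is None:
        text = resources.files("infoveil").joinpath("data/stopwords.txt").read_text("utf-8")
        _STOPWORDS = frozenset(w.strip() for w in text.splitlines() if w.strip())
    return _STOPWORDS


def clean_text(text: str, stage: str = "scoring", stopwords: Optional[frozenset[str]] = None) -> str:
    """Normalize a raw post for ``scoring`` or ``modeling``.

    Both stages remove URLs, @-handles, emoji and punctuation (apostrophes and
    intra-word hyphens survive) and case-fold; ``modeling`` additionally drops
    stopwords. Idempotent per stage; empty output is allowed.
    """
    if stage not in ("scoring", "modeling"):
        raise ValueError(f"unknown cleaning stage {stage!r}")
    s = unicodedata.normalize("NFC", text)
    s = _URL_RE.sub(" ", s)
    s = _HANDLE_RE.sub(" ", s)
    s = _EMOJI_RE.sub(" ", s)
    s = s.casefold()
    s = _KEEP_RE.sub(" ", s)
    words = [w.strip("'-") for w in _WS_RE.split(s)]
    words = [w for w in words if w]
    if stage == "modeling":
        stop = default_stopwords() if stopwords is None else stopwords
        words = [w for w in words if w not in stop]
    return " ".join(words)


# --- tokenization / lemmatization ---------------------------------------

_VOWELS = set("aeiou")

# Irregulars that matter for short health/drug posts; deliberately small.
_IRREGULAR = {
    "men": "man", "women": "woman", "people": "people", "children": "child",
    "feet": "foot", "teeth": "tooth", "lives": "life", "died": "die",
    "dying": "die", "dies": "die", "took": "take", "taken": "take",
    "felt": "feel", "got": "get", "gave": "give", "went": "go",
    "was": "be", "were": "be", "been": "be", "made": "make",
    "said": "say", "found": "find", "told": "tell", "kept": "keep",
    "left": "leave", "lost": "lose", "sold": "sell", "bought": "buy",
    "this": "this", "his": "his", "is": "is", "does": "do", "has": "have",
}


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization of cleaned text."""
    return text.split()


def lemmatize(token: str) -> str:
    """Rule-based lemma for one lowercase token.

    Handles regular plurals (-s, -es, -ies), -ing and -ed verb forms with
    doubled-consonant undoubling and silent-e restoration heuristics. Words
    of length <= 3 and anything unrecognized pass through unchanged.
    """
    if token in _IRREGULAR:
        return _IRREGULAR[token]
    n = len(token)
    if n <= 3 or not token.isalpha():
        return token
    # plural nouns / 3rd person verbs
    if token.endswith("ies") and n > 4:
        return token[:-3] + "y"
    if token.endswith(("xes", "zes", "ches", "shes")):
        return token[:-2]
    if token.endswith("ss"):
        return token
    if token.endswith("s") and not token.endswith("us") and not token.endswith("is"):
        return token[:-1]
    if token.endswith("ing") and n > 5:
        stem = token[:-3]
        return _fix_stem(stem)
    if token.endswith("ed") and n > 4:
        stem = token[:-2]
        if token.endswith("ied"):
            return token[:-3] + "y"
        return _fix_stem(stem)
    return token


def _fix_stem(stem: str) -> str:
    # running -> run; taking -> take; killed/killing keep their double l
    if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in "lsz" and stem[-1] not in _VOWELS:
        return stem[:-1]
    if (
        len(stem) >= 3
        and stem[-1] not in _VOWELS
        and stem[-1] not in "wxy"
        and stem[-2] in _VOWELS
        and stem[-3] not in _VOWELS
    ):
        return stem + "e"
    return stem


def tokenize_lemmatize(
    text: str,
    post_id: str = "",
    lemmatizer: Callable[[str], str] = lemmatize,
) -> TokenizedDoc:
    """Tokenize already-cleaned text and lemmatize each token.

    Order and multiplicity are preserved (no deduplication); determinism is
    guaranteed for a fixed ``lemmatizer``.
    """
    raw = tokenize(text)
    return TokenizedDoc(post_id=post_id, tokens=[lemmatizer(t) for t in raw], raw_token_count=len(raw))


# --- corpus I/O ---------------------------------------------------------


def read_corpus(path, format: str = "jsonl") -> Corpus:
    """Read a corpus from JSONL (one ``{"id","text","meta"?}`` per line) or CSV
    (header ``id,text``). Malformed records raise :class:`CorpusError` naming
    the offending line; duplicate ids are rejected.
    """
    posts: list[Post] = []
    if format == "jsonl":
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
                if not isinstance(obj, dict) or "id" not in obj or "text" not in obj:
                    raise CorpusError(f"{path}:{lineno}: record must have 'id' and 'text'")
                posts.append(Post(id=str(obj["id"]), text=str(obj["text"]), meta=obj.get("meta") or {}))
    elif format == "csv":
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "id" not in reader.fieldnames or "text" not in reader.fieldnames:
                raise CorpusError(f"{path}: CSV header must contain 'id' and 'text'")
            for lineno, row in enumerate(reader, start=2):
                if row.get("id") is None or row.get("text") is None:
                    raise CorpusError(f"{path}:{lineno}: missing id or text")
                meta = {k: v for k, v in row.items() if k not in ("id", "text") and v}
                posts.append(Post(id=row["id"], text=row["text"], meta=meta))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return Corpus(posts)


def write_corpus(corpus: Corpus, path, format: str = "jsonl") -> None:
    """Write a corpus; ``read_corpus(write_corpus(c)) == c`` on valid corpora."""
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for p in corpus:
                rec = {"id": p.id, "text": p.text}
                if p.meta:
                    rec["meta"] = p.meta
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "text"])
            for p in corpus:
                writer.writerow([p.id, p.text])
    else:
        raise ValueError(f"unknown corpus format {format!r}")
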