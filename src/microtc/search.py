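"""A small full-text inverted index over genes, T/Cs and experiments.

Documents carry typed text fields (gene identifier, symbol, annotation;
T/C name, description; experiment title, description).  Tokenization is
deliberately permissive: lowercase, split on non-alphanumerics, and for
compound words like ``PR-1`` the joined form ``pr1`` is added so queries
using either spelling hit.  Queries use OR semantics over terms — any
matching word retrieves the document — ranked by summed tf·idf with
``idf = ln((N+1)/(df+1)) + 1``.  No stemming, no stop words: recall of
exact tokens is the contract.  A slow substring mode is available for
partial-word ("letters") matching.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

from .errors import MicrotcError

DOC_TYPES = ("gene", "tc", "experiment")
_ALNUM_RUN = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class SearchDoc:
    doc_id: str
    doc_type: str
    fields: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.doc_type not in DOC_TYPES:
            raise MicrotcError(f"doc_type must be one of {DOC_TYPES}, got {self.doc_type!r}")


def tokenize(text: str) -> list[str]:
    """Lowercase alphanumeric tokens; compounds also yield their joined form."""
    tokens: list[str] = []
    for word in text.split():
        runs = _ALNUM_RUN.findall(word.lower())
        tokens.extend(runs)
        if len(runs) > 1:
            tokens.append("".join(runs))
    return tokens


class InvertedIndex:
    """token → postings (doc_id, field, term frequency), with tf·idf scoring."""

    def __init__(self):
        self.postings: dict[str, list[tuple[str, str, int]]] = {}
        self.doc_types: dict[str, str] = {}
        self.doc_lengths: dict[str, int] = {}

    @property
    def n_docs(self) -> int:
        return len(self.doc_types)

    @classmethod
    def build(cls, docs: list[SearchDoc]) -> "InvertedIndex":
        """Index a document list deterministically; duplicate doc_ids error."""
        idx = cls()
        seen = set()
        for doc in docs:
            if doc.doc_id in seen:
                raise MicrotcError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            idx.doc_types[doc.doc_id] = doc.doc_type
            length = 0
            counts: dict[tuple[str, str], int] = {}
            for fname in sorted(doc.fields):
                for tok in tokenize(str(doc.fields[fname])):
                    counts[(tok, fname)] = counts.get((tok, fname), 0) + 1
                    length += 1
            self_postings = idx.postings
            for (tok, fname), tf in sorted(counts.items()):
                self_postings.setdefault(tok, []).append((doc.doc_id, fname, tf))
            idx.doc_lengths[doc.doc_id] = length
        for plist in idx.postings.values():
            plist.sort()
        return idx

    def _idf(self, token: str) -> float:
        df = len({d for d, _, _ in self.postings.get(token, [])})
        return math.log((self.n_docs + 1) / (df + 1)) + 1.0

    def _matching_tokens(self, term: str, substring: bool) -> list[str]:
        if not substring:
            return [term] if term in self.postings else []
        return sorted(t for t in self.postings if term in t)

    def query(
        self, q: str, doc_type: str | None = None, substring: bool = False
    ) -> list[tuple[str, float]]:
        """OR-match the query terms; return (doc_id, score) by descending score.

        Ties are broken by doc_id so results are stable across runs.
        """
        scores: dict[str, float] = {}
        for term in set(tokenize(q)):
            for token in self._matching_tokens(term, substring):
                idf = self._idf(token)
                tf_per_doc: dict[str, int] = {}
                for doc_id, _fname, tf in self.postings[token]:
                    tf_per_doc[doc_id] = tf_per_doc.get(doc_id, 0) + tf
                for doc_id, tf in tf_per_doc.items():
                    if doc_type is not None and self.doc_types[doc_id] != doc_type:
                        continue
                    scores[doc_id] = scores.get(doc_id, 0.0) + tf * idf
        return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "doc_types": self.doc_types,
            "doc_lengths": self.doc_lengths,
            "postings": {t: [list(p) for p in plist] for t, plist in self.postings.items()},
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "InvertedIndex":
        payload = json.loads(text)
        idx = cls()
        idx.doc_types = dict(payload["doc_types"])
        idx.doc_lengths = {k: int(v) for k, v in payload["doc_lengths"].items()}
        idx.postings = {
            t: [(d, f, int(tf)) for d, f, tf in plist] for t, plist in payload["postings"].items()
        }
        return idx

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "InvertedIndex":
        with open(path) as fh:
            return cls.from_json(fh.read())


def build_index(docs: list[SearchDoc]) -> InvertedIndex:
    """Convenience wrapper over :meth:`InvertedIndex.build`."""
    return InvertedIndex.build(docs)
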