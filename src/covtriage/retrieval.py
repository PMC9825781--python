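"""In-house inverted index with Okapi BM25 and concept-id query expansion.

The index holds two posting namespaces side by side: normalized token
variants emitted by :mod:`covtriage.textnorm` (each document token
contributes each of its variants once), and concept identifiers attached by
the annotator, stored under a ``CID:`` prefix so they can never collide with
text tokens.

Scoring is Okapi BM25 with the Lucene-style non-negative IDF

    IDF(t) = ln((N - df + 0.5) / (df + 0.5) + 1)

and optional per-term query weights.  Query weights follow the
rare-word-favouring scheme: weight(t) = max(0, ln(ref_N / (df_ref(t) + 1)))
against a *reference* document-frequency table (e.g. from a broad literature
collection rather than the target corpus), so that common words are damped
and specific ones dominate.  Concept ids found by annotating the query text
are appended to the query and scored against the concept postings with unit
weight.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .annotator import Annotation, Document, annotate_document
from .lexicon_io import Lexicon, normalize_axis
from .textnorm import normalize_terms, tokenize

#: Posting-namespace prefix for concept identifiers.
CONCEPT_PREFIX = "CID:"

DEFAULT_K1 = 1.2
DEFAULT_B = 0.75


@dataclass
class Index:
    """Inverted index over token variants and concept ids."""

    postings: Dict[str, Dict[str, int]] = dc_field(default_factory=dict)
    doc_len: Dict[str, int] = dc_field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.doc_len)

    @property
    def avg_doc_len(self) -> float:
        return sum(self.doc_len.values()) / self.N if self.N else 0.0

    def df(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def tf(self, term: str, doc_id: str) -> int:
        return self.postings.get(term, {}).get(doc_id, 0)

    @property
    def concept_postings(self) -> Dict[str, Dict[str, int]]:
        """Concept-id postings, keyed by bare CURIE."""
        return {
            t[len(CONCEPT_PREFIX):]: p
            for t, p in self.postings.items()
            if t.startswith(CONCEPT_PREFIX)
        }

    def concept_tf(self, concept_id: str, doc_id: str) -> int:
        return self.tf(CONCEPT_PREFIX + concept_id, doc_id)

    def concept_df(self, concept_id: str) -> int:
        return self.df(CONCEPT_PREFIX + concept_id)

    # -- persistence (JSON, one directory) ---------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = {"postings": self.postings, "doc_len": self.doc_len}
        (directory / "index.json").write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, directory) -> "Index":
        payload = json.loads((Path(directory) / "index.json").read_text(encoding="utf-8"))
        return cls(postings=payload["postings"], doc_len=payload["doc_len"])


@dataclass
class WeightedQuery:
    """A weighted bag of normalized terms plus expansion concept ids."""

    terms: List[Tuple[str, float]]
    concept_ids: List[str] = dc_field(default_factory=list)
    focus: Optional[str] = None
    raw_text: str = ""

    def __post_init__(self) -> None:
        for term, w in self.terms:
            if not (w >= 0 and math.isfinite(w)):
                raise ValueError(f"query term {term!r} has invalid weight {w!r}")
        if not self.terms and not self.concept_ids:
            raise ValueError("query must carry at least one term or concept id")
        if self.focus is not None:
            self.focus = normalize_axis(self.focus)


def build_index(
    corpus: Iterable[Document],
    annotations: Optional[Mapping[str, Sequence[Annotation]]] = None,
) -> Index:
    """Index a corpus; optionally attach annotator output as concept postings.

    ``doc_len`` counts variant emissions (a token with two variants adds 2),
    concept postings do not contribute to document length.
    """
    index = Index()
    for doc in corpus:
        if doc.doc_id in index.doc_len:
            raise ValueError(f"duplicate doc_id in corpus: {doc.doc_id}")
        terms = normalize_terms(doc.text)
        index.doc_len[doc.doc_id] = len(terms)
        for t in terms:
            index.postings.setdefault(t, {})
            index.postings[t][doc.doc_id] = index.postings[t].get(doc.doc_id, 0) + 1
    if annotations:
        for doc_id, annots in annotations.items():
            if doc_id not in index.doc_len:
                continue
            for a in annots:
                key = CONCEPT_PREFIX + a.concept_id
                index.postings.setdefault(key, {})
                index.postings[key][doc_id] = index.postings[key].get(doc_id, 0) + 1
    return index


def idf(index: Index, term: str) -> float:
    """Lucene/Elasticsearch BM25 IDF; non-negative for any df <= N."""
    df = index.df(term)
    return math.log((index.N - df + 0.5) / (df + 0.5) + 1.0)


def bm25_score(
    q: WeightedQuery,
    doc_id: str,
    index: Index,
    k1: float = DEFAULT_K1,
    b: float = DEFAULT_B,
) -> float:
    """Okapi BM25 score of one document for a weighted query.

    Terms absent from the document contribute zero; query concept ids are
    scored identically against the concept postings with unit weight.
    """
    if doc_id not in index.doc_len:
        raise KeyError(f"unknown doc_id: {doc_id}")
    if not k1 > 0:
        raise ValueError("k1 must be > 0")
    if not 0 <= b <= 1:
        raise ValueError("b must be in [0, 1]")
    len_norm = 1 - b + b * index.doc_len[doc_id] / index.avg_doc_len if index.avg_doc_len else 1.0
    score = 0.0
    scored: List[Tuple[str, float]] = list(q.terms)
    scored.extend((CONCEPT_PREFIX + cid, 1.0) for cid in q.concept_ids)
    for term, weight in scored:
        tf = index.tf(term, doc_id)
        if tf == 0 or weight == 0:
            continue
        score += weight * idf(index, term) * tf * (k1 + 1) / (tf + k1 * len_norm)
    return score


def weight_query_terms(
    raw: str, ref_df: Mapping[str, int], ref_N: int, focus: Optional[str] = None
) -> WeightedQuery:
    """Tokenize a raw query and weight terms by reference rarity.

    weight(t) = max(0, ln(ref_N / (df_ref(t) + 1))); terms missing from the
    reference table take df 0 (maximal weight); duplicate terms merge by
    summing their weights.
    """
    if ref_N <= 0:
        raise ValueError("ref_N must be positive")
    if ref_df and ref_N < max(ref_df.values()):
        raise ValueError("ref_N smaller than a reference document frequency")
    weights: Dict[str, float] = {}
    for term in normalize_terms(raw):
        w = max(0.0, math.log(ref_N / (ref_df.get(term, 0) + 1)))
        weights[term] = weights.get(term, 0.0) + w
    return WeightedQuery(
        terms=sorted(weights.items()), concept_ids=[], focus=focus, raw_text=raw
    )


def unweighted_query(raw: str, focus: Optional[str] = None) -> WeightedQuery:
    """A query with unit weight per distinct normalized term."""
    terms = sorted({t: 1.0 for t in normalize_terms(raw)}.items())
    return WeightedQuery(terms=list(terms), concept_ids=[], focus=focus, raw_text=raw)


def expand_query(q: WeightedQuery, lexicon: Lexicon) -> WeightedQuery:
    """Append concept ids found by annotating the query text; idempotent."""
    pseudo = Document(doc_id="::query::", fields={"abstract": q.raw_text})
    matched = {a.concept_id for a in annotate_document(pseudo, lexicon)}
    new_ids = sorted(matched - set(q.concept_ids))
    return WeightedQuery(
        terms=list(q.terms),
        concept_ids=list(q.concept_ids) + new_ids,
        focus=q.focus,
        raw_text=q.raw_text,
    )


def search(
    q: WeightedQuery,
    index: Index,
    k: int = 1000,
    k1: float = DEFAULT_K1,
    b: float = DEFAULT_B,
) -> List[Tuple[str, float]]:
    """Rank documents by BM25; positive scores only, ties by doc_id.

    Returns at most ``k`` (doc_id, score) pairs, score-descending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    candidates: set = set()
    for term, w in q.terms:
        if w > 0:
            candidates.update(index.postings.get(term, ()))
    for cid in q.concept_ids:
        candidates.update(index.postings.get(CONCEPT_PREFIX + cid, ()))
    scored = [(doc_id, bm25_score(q, doc_id, index, k1=k1, b=b)) for doc_id in candidates]
    scored = [(d, s) for d, s in scored if s > 0]
    scored.sort(key=lambda ds: (-ds[1], ds[0]))
    return scored[:k]


# ---------------------------------------------------------------------------
# reference DF table I/O: first line "#N=<ref_N>", then "term<TAB>df" rows


def read_ref_df(path) -> Tuple[Dict[str, int], int]:
    """Read a reference document-frequency table; returns (df map, ref_N)."""
    ref_df: Dict[str, int] = {}
    ref_N: Optional[int] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#N="):
                ref_N = int(line[3:])
                continue
            if line.startswith("#") or line == "term\tdf":
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'term<TAB>df', got {line!r}")
            ref_df[cols[0]] = int(cols[1])
    if ref_N is None:
        raise ValueError(f"{path}: missing '#N=<ref_N>' header line")
    return ref_df, ref_N


def write_ref_df(ref_df: Mapping[str, int], ref_N: int, path) -> None:
    lines = [f"#N={ref_N}", "term\tdf"]
    lines.extend(f"{t}\t{df}" for t, df in sorted(ref_df.items()))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
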