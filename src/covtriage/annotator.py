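"""Dictionary annotation of fielded documents and collection statistics.

A document is a set of named text fields (title, abstract, body, keywords).
Annotation slides the compiled lexicon phrase table over the normalized
token-variant stream of each field: a phrase of n normalized tokens matches
n consecutive document tokens when each phrase token is among the variants
of the corresponding document token.  Every match yields an annotation
carrying the matched surface text, the concept id, its preferred label and
axis, the field, and character offsets into the original field text.

Matching is deliberately permissive — concepts from different axes may
overlap freely — but within a single concept, matches starting at the same
token are resolved to the longest phrase, and repeated matches of one
concept at one span (via different variants) are deduplicated.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field as dc_field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .lexicon_io import AXES, Lexicon, normalize_axis
from .textnorm import FIELDS, tokenize

_FIELD_ORDER = {f: i for i, f in enumerate(FIELDS)}


@dataclass(frozen=True)
class Document:
    """A fielded corpus record (MEDLINE/PMC/CORD-19-like)."""

    doc_id: str
    collection: str = ""
    fields: Mapping[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    @property
    def text(self) -> str:
        """All present fields concatenated in canonical order."""
        return " ".join(self.fields[f] for f in FIELDS if self.fields.get(f))

    @classmethod
    def from_record(cls, record: Mapping[str, object]) -> "Document":
        fields = {f: str(record[f]) for f in FIELDS if record.get(f)}
        return cls(
            doc_id=str(record["doc_id"]),
            collection=str(record.get("collection", "")),
            fields=fields,
        )

    def to_record(self) -> Dict[str, object]:
        rec: Dict[str, object] = {"doc_id": self.doc_id, "collection": self.collection}
        for f in FIELDS:
            if self.fields.get(f):
                rec[f] = self.fields[f]
        return rec


@dataclass(frozen=True, order=True)
class Annotation:
    """One matched concept occurrence with positional provenance."""

    concept_id: str
    matched_term: str
    preferred_label: str
    axis: str
    field: str
    start: int
    end: int


@dataclass
class CollectionStats:
    """Per-axis annotation counts for one collection."""

    collection: str
    per_axis: Dict[str, int]
    total: int
    n_docs: int
    avg_per_doc: int

    @classmethod
    def from_axis_counts(
        cls, per_axis: Mapping[str, int], n_docs: int, collection: str = ""
    ) -> "CollectionStats":
        """Build stats from pre-counted per-axis totals.

        The total is the sum over the nine axes; the per-document average is
        the *floor* of total/n_docs (integer truncation, matching how these
        statistics are conventionally reported).
        """
        if n_docs < 0:
            raise ValueError("n_docs must be non-negative")
        counts = {axis: int(per_axis.get(axis, 0)) for axis in AXES}
        unknown = set(per_axis) - set(AXES)
        if unknown:
            raise ValueError(f"unknown axis codes in counts: {sorted(unknown)}")
        total = sum(counts.values())
        return cls(
            collection=collection,
            per_axis=counts,
            total=total,
            n_docs=n_docs,
            avg_per_doc=total // n_docs if n_docs > 0 else 0,
        )


def _resolve_axes(axes: Optional[Iterable[str]]) -> Optional[Set[str]]:
    if axes is None:
        return None
    return {normalize_axis(a) for a in axes}


def annotate_document(
    doc: Document, lexicon: Lexicon, axes: Optional[Iterable[str]] = None
) -> List[Annotation]:
    """Annotate one document against a compiled lexicon.

    Returns annotations sorted by (field order, start, concept id),
    restricted to ``axes`` when given.
    """
    wanted = _resolve_axes(axes)
    table = lexicon.phrase_table
    if not table:
        return []
    max_len = max(len(key) for key in table)
    found: Dict[Tuple[str, str, int], Tuple[int, int]] = {}

    for fname in FIELDS:
        text = doc.fields.get(fname)
        if not text:
            continue
        spans = tokenize(text, field=fname)
        variant_sets = [s.variants for s in spans]
        for i in range(len(spans)):
            if not variant_sets[i]:
                continue
            # longest match per concept at this start token
            best_at_i: Dict[str, int] = {}
            prefix: List[Sequence[str]] = []
            for length in range(1, min(max_len, len(spans) - i) + 1):
                vs = variant_sets[i + length - 1]
                if not vs:
                    break
                prefix.append(sorted(vs))
                for combo in _iter_products(prefix):
                    ids = table.get(combo)
                    if ids:
                        for cid in ids:
                            best_at_i[cid] = length
            for cid, length in best_at_i.items():
                start = spans[i].start
                end = spans[i + length - 1].end
                key = (cid, fname, start)
                prev = found.get(key)
                if prev is None or end > prev[0]:
                    found[key] = (end, i)

    out: List[Annotation] = []
    for (cid, fname, start), (end, _i) in found.items():
        concept = lexicon[cid]
        if wanted is not None and concept.axis not in wanted:
            continue
        out.append(
            Annotation(
                concept_id=cid,
                matched_term=doc.fields[fname][start:end],
                preferred_label=concept.preferred_label,
                axis=concept.axis,
                field=fname,
                start=start,
                end=end,
            )
        )
    out.sort(key=lambda a: (_FIELD_ORDER[a.field], a.start, a.concept_id))
    return out


def _iter_products(variant_lists: Sequence[Sequence[str]]):
    """Cartesian product of per-token variant lists, as tuples."""
    import itertools

    return itertools.product(*variant_lists) if variant_lists else iter(())


def annotate_corpus(
    corpus: Iterable[Document], lexicon: Lexicon, axes: Optional[Iterable[str]] = None
) -> Dict[str, List[Annotation]]:
    """Annotate every document; a once-only pass over the corpus."""
    out: Dict[str, List[Annotation]] = {}
    for doc in corpus:
        if doc.doc_id in out:
            raise ValueError(f"duplicate doc_id in corpus: {doc.doc_id}")
        out[doc.doc_id] = annotate_document(doc, lexicon, axes=axes)
    return out


def aggregate_stats(
    annotations: Mapping[str, Sequence[Annotation]],
    n_docs: int,
    collection: str = "",
) -> CollectionStats:
    """Aggregate per-document annotations into collection statistics.

    ``n_docs`` is the collection size and may exceed the number of annotated
    documents (unannotated documents still count toward the average).
    """
    if n_docs < 0:
        raise ValueError("n_docs must be non-negative")
    if n_docs < len(annotations):
        raise ValueError(
            f"n_docs={n_docs} smaller than number of annotated documents ({len(annotations)})"
        )
    counts: Counter = Counter()
    for annots in annotations.values():
        for a in annots:
            counts[a.axis] += 1
    return CollectionStats.from_axis_counts(counts, n_docs=n_docs, collection=collection)


# ---------------------------------------------------------------------------
# JSONL corpus and SciLite-like annotation exports


def read_corpus_jsonl(path) -> List[Document]:
    """Read a corpus from JSONL, one document object per line."""
    docs = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                docs.append(Document.from_record(json.loads(line)))
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: bad document record: {exc}") from exc
    return docs


def write_corpus_jsonl(docs: Iterable[Document], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_record(), ensure_ascii=False) + "\n")


def annotations_to_json(doc_id: str, annotations: Sequence[Annotation]) -> Dict[str, object]:
    """Serialize one document's annotations in a SciLite-like shape.

    Schema: ``schemas/annotations.schema.json``.
    """
    return {
        "doc_id": doc_id,
        "annotations": [
            {
                "exact": a.matched_term,
                "concept_id": a.concept_id,
                "preferred_label": a.preferred_label,
                "axis": a.axis,
                "field": a.field,
                "start": a.start,
                "end": a.end,
            }
            for a in annotations
        ],
    }


def annotations_from_json(payload: Mapping[str, object]) -> Tuple[str, List[Annotation]]:
    annots = [
        Annotation(
            concept_id=str(rec["concept_id"]),
            matched_term=str(rec["exact"]),
            preferred_label=str(rec["preferred_label"]),
            axis=str(rec["axis"]),
            field=str(rec["field"]),
            start=int(rec["start"]),
            end=int(rec["end"]),
        )
        for rec in payload["annotations"]  # type: ignore[index]
    ]
    return str(payload["doc_id"]), annots


def write_annotations_json(annotations: Mapping[str, Sequence[Annotation]], path) -> None:
    payload = [annotations_to_json(d, a) for d, a in annotations.items()]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, ensure_ascii=False, indent=1)


def read_annotations_json(path) -> Dict[str, List[Annotation]]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return dict(annotations_from_json(rec) for rec in payload)
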