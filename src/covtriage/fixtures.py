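"""Deterministic synthetic fixtures: lexicons, corpora, topics, qrels.

Real inputs to a literature-triage system — an ontology-derived lexicon, a
CORD-19-like document collection, TREC topics and human relevance
judgements — are large and external.  This module generates desk-scale
stand-ins with *known* structure:

* a mini-lexicon spanning all nine axes, with synthetic multi-token,
  dashed and slashed labels (plus the canonical "covid-19" concept) so the
  normalization rules are exercised;
* documents made of filler tokens with concept surface forms planted
  verbatim at recorded offsets, giving gold annotations with recall-1
  semantics;
* one topic per focus axis whose relevance judgements follow a logistic
  link in the number of distinct planted focus-axis concepts, so that
  axis-focused re-ranking has signal to exploit;
* a reference document-frequency table built from a held-out filler
  corpus, so common filler words carry high df (low query weight).

All outputs are byte-identical under the same seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .annotator import (
    Annotation,
    Document,
    write_annotations_json,
    write_corpus_jsonl,
)
from .evaluation import Qrels, write_qrels
from .lexicon_io import AXES, Concept, Lexicon, save_lexicon
from .retrieval import write_ref_df
from .textnorm import normalize_terms

_SYLLABLES = [
    "zor", "bex", "quil", "vam", "tron", "fyx", "gal", "mur", "plek",
    "sarn", "tiv", "wex", "yol", "dru", "hasp", "kyn", "lom", "nid",
]


def _load_filler_words() -> List[str]:
    text = resources.files("covtriage.data").joinpath("filler_words.txt").read_text("utf-8")
    return [w for w in text.split() if w]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    ``plant_rate`` is the expected number of distinct planted concepts per
    document per axis; ``relevance_slope``/``relevance_offset`` parametrize
    the logistic link P(relevant) = sigma(slope * (k - offset)) where k is
    the distinct focus-axis concept count of a document.
    """

    n_concepts_per_axis: int = 2
    n_docs: int = 60
    doc_length: Tuple[int, int] = (40, 80)
    plant_rate: float = 0.6
    relevance_slope: float = 1.2
    relevance_offset: float = 1.0
    n_topics: int = 6
    ref_corpus_docs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_concepts_per_axis, self.n_docs, self.n_topics, self.ref_corpus_docs) < 0:
            raise ValueError("fixture counts must be non-negative")
        if self.plant_rate < 0:
            raise ValueError("plant_rate must be non-negative")


@dataclass(frozen=True)
class Topic:
    topic_id: str
    query: str
    focus: str


@dataclass
class FixtureBundle:
    """Everything one synthetic study produces."""

    lexicon: Lexicon
    documents: List[Document]
    gold: Dict[str, List[Annotation]]
    topics: List[Topic]
    qrels: Qrels
    ref_df: Dict[str, int]
    ref_N: int


def make_lexicon(spec: FixtureSpec) -> Lexicon:
    """Generate a mini-lexicon across all nine axes.

    Every concept gets 1–3 synonyms; some surface forms carry dashes or
    slashes, and the DIS axis always leads with the worked-example concept
    "covid-19" (synonym "coronavirus disease 2019").
    """
    rng = random.Random(spec.seed * 9973 + 1)
    concepts: List[Concept] = []
    serial = 1

    def stem() -> str:
        return "".join(rng.choice(_SYLLABLES) for _ in range(rng.randint(2, 3)))

    for axis in AXES:
        for j in range(spec.n_concepts_per_axis):
            if axis == "DIS" and j == 0:
                concepts.append(
                    Concept(
                        id="COVOC:0000001",
                        axis="DIS",
                        preferred_label="covid-19",
                        synonyms=("coronavirus disease 2019",),
                        xrefs=("MONDO:0100096",),
                    )
                )
                continue
            base = stem()
            style = rng.randrange(3)
            if style == 0:
                label = f"{base}-{rng.randint(10, 99)}"
            elif style == 1:
                label = f"{base}/{stem()}"
            else:
                label = base
            synonyms = []
            for _ in range(rng.randint(1, 3)):
                kind = rng.randrange(3)
                if kind == 0:
                    synonyms.append(f"{stem()} {stem()}")
                elif kind == 1:
                    synonyms.append(f"{stem()}-{stem()}")
                else:
                    synonyms.append(stem())
            concepts.append(
                Concept(
                    id=f"SYN:{serial:07d}",
                    axis=axis,
                    preferred_label=label,
                    synonyms=tuple(dict.fromkeys(synonyms)),
                    xrefs=(),
                )
            )
            serial += 1
    return Lexicon.from_concepts(concepts)


def _assemble_field(tokens: Sequence[str]) -> Tuple[str, List[Tuple[int, int]]]:
    """Join tokens with single spaces, returning the text and token offsets."""
    text_parts: List[str] = []
    offsets: List[Tuple[int, int]] = []
    pos = 0
    for i, tok in enumerate(tokens):
        if i:
            pos += 1
        offsets.append((pos, pos + len(tok)))
        text_parts.append(tok)
        pos += len(tok)
    return " ".join(text_parts), offsets


def make_corpus(spec: FixtureSpec, lexicon: Lexicon) -> FixtureBundle:
    """Generate documents with planted concepts, topics, qrels and ref DF."""
    if not lexicon.concepts:
        raise ValueError("lexicon must be non-empty")
    rng = random.Random(spec.seed * 9973 + 2)
    fillers = _load_filler_words()
    by_axis: Dict[str, List[Concept]] = {axis: [] for axis in AXES}
    for c in sorted(lexicon.concepts.values(), key=lambda c: c.id):
        by_axis[c.axis].append(c)

    p_concept = (
        min(1.0, spec.plant_rate / spec.n_concepts_per_axis)
        if spec.n_concepts_per_axis
        else 0.0
    )

    documents: List[Document] = []
    gold: Dict[str, List[Annotation]] = {}
    planted_distinct: Dict[str, Dict[str, set]] = {}

    for d in range(spec.n_docs):
        doc_id = f"DOC{d:04d}"
        n_tokens = rng.randint(*spec.doc_length)
        tokens: List[str] = [rng.choice(fillers) for _ in range(n_tokens)]
        # choose plants: (concept, surface, occurrences)
        plants: List[Tuple[Concept, str]] = []
        per_axis_distinct: Dict[str, set] = {axis: set() for axis in AXES}
        for axis in AXES:
            for concept in by_axis[axis]:
                if rng.random() < p_concept:
                    per_axis_distinct[axis].add(concept.id)
                    n_occ = 1 + (rng.random() < 0.3)
                    for _ in range(n_occ):
                        surface = rng.choice(concept.surface_forms)
                        plants.append((concept, surface))
        # splice plants at random token positions (as standalone "tokens")
        plant_slots = sorted(rng.sample(range(n_tokens + 1), min(len(plants), n_tokens + 1)))
        rng.shuffle(plants)
        merged: List[Tuple[str, Optional[Tuple[Concept, str]]]] = []
        slot_iter = iter(sorted(zip(plant_slots, plants)))
        next_slot = next(slot_iter, None)
        for i in range(n_tokens + 1):
            while next_slot is not None and next_slot[0] == i:
                merged.append((next_slot[1][1], next_slot[1]))
                next_slot = next(slot_iter, None)
            if i < n_tokens:
                merged.append((tokens[i], None))
        field_tokens = [m[0] for m in merged]
        text, offsets = _assemble_field(field_tokens)
        title_text, _ = _assemble_field([rng.choice(fillers) for _ in range(rng.randint(3, 7))])
        annots: List[Annotation] = []
        for (tok, plant), (start, end) in zip(merged, offsets):
            if plant is None:
                continue
            concept, surface = plant
            annots.append(
                Annotation(
                    concept_id=concept.id,
                    matched_term=surface,
                    preferred_label=concept.preferred_label,
                    axis=concept.axis,
                    field="abstract",
                    start=start,
                    end=end,
                )
            )
        annots.sort(key=lambda a: (a.start, a.concept_id))
        documents.append(
            Document(
                doc_id=doc_id,
                collection="synthetic",
                fields={"title": title_text, "abstract": text},
            )
        )
        gold[doc_id] = annots
        planted_distinct[doc_id] = per_axis_distinct

    # topics: cycle the axes; query = target concept label + common fillers
    topics: List[Topic] = []
    qrels: Qrels = {}
    for t in range(spec.n_topics):
        axis = AXES[t % len(AXES)]
        if not by_axis[axis]:
            continue
        target = by_axis[axis][t // len(AXES) % len(by_axis[axis])]
        query = f"{target.preferred_label} {rng.choice(fillers)} {rng.choice(fillers)}"
        topic_id = str(t + 1)
        topics.append(Topic(topic_id=topic_id, query=query, focus=axis))
        for doc in documents:
            k = len(planted_distinct[doc.doc_id][axis])
            p_rel = 1.0 / (1.0 + math.exp(-spec.relevance_slope * (k - spec.relevance_offset)))
            qrels[(topic_id, doc.doc_id)] = int(rng.random() < p_rel)

    # reference DF from a held-out filler corpus
    ref_rng = random.Random(spec.seed * 9973 + 3)
    ref_df: Dict[str, int] = {}
    for _ in range(spec.ref_corpus_docs):
        n = ref_rng.randint(*spec.doc_length)
        doc_terms = set()
        for _ in range(n):
            doc_terms.update(normalize_terms(ref_rng.choice(fillers)))
        for term in doc_terms:
            ref_df[term] = ref_df.get(term, 0) + 1

    return FixtureBundle(
        lexicon=lexicon,
        documents=documents,
        gold=gold,
        topics=topics,
        qrels=qrels,
        ref_df=ref_df,
        ref_N=max(spec.ref_corpus_docs, 1),
    )


def make_fixtures(spec: FixtureSpec) -> FixtureBundle:
    """Generate a full bundle (lexicon + corpus artifacts) from one spec."""
    return make_corpus(spec, make_lexicon(spec))


def write_fixtures(bundle: FixtureBundle, outdir) -> Dict[str, Path]:
    """Write all five artifacts to a directory; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lexicon": outdir / "lexicon.tsv",
        "corpus": outdir / "corpus.jsonl",
        "gold": outdir / "gold_annotations.json",
        "topics": outdir / "topics.tsv",
        "qrels": outdir / "qrels.txt",
        "ref_df": outdir / "ref_df.tsv",
    }
    save_lexicon(bundle.lexicon, paths["lexicon"])
    write_corpus_jsonl(bundle.documents, paths["corpus"])
    write_annotations_json(bundle.gold, paths["gold"])
    lines = ["topic_id\tquery\tfocus"]
    lines.extend(f"{t.topic_id}\t{t.query}\t{t.focus}" for t in bundle.topics)
    paths["topics"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    write_qrels(bundle.qrels, paths["qrels"])
    write_ref_df(bundle.ref_df, bundle.ref_N, paths["ref_df"])
    return paths


def read_topics(path) -> List[Topic]:
    topics = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            topic_id, query, focus = line.split("\t")
            topics.append(Topic(topic_id=topic_id, query=query, focus=focus))
    return topics
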