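"""End-to-end composition: query → retrieval → expansion → re-ranking.

Ties the modules together the way the triage service operates them: the
corpus is annotated once, indexed with its concept postings, and each topic
is answered by a DF-weighted BM25 query, optionally expanded with concept
ids from the lexicon and re-ranked toward the topic's focus axis.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence

from .annotator import Annotation, Document, annotate_corpus
from .evaluation import Run
from .fixtures import Topic
from .lexicon_io import Lexicon
from .retrieval import (
    Index,
    build_index,
    expand_query,
    search,
    weight_query_terms,
)
from .triage import TriageParams, rerank


def prepare(corpus: Sequence[Document], lexicon: Lexicon):
    """Annotate and index a corpus once; returns (annotations, index)."""
    annotations = annotate_corpus(corpus, lexicon)
    index = build_index(corpus, annotations)
    return annotations, index


def run_topics(
    topics: Sequence[Topic],
    index: Index,
    annotations: Mapping[str, Sequence[Annotation]],
    lexicon: Lexicon,
    ref_df: Mapping[str, int],
    ref_N: int,
    k: int = 1000,
    query_expansion: bool = False,
    triage_params: Optional[TriageParams] = None,
    tag: str = "run",
) -> Run:
    """Answer every topic, producing a TREC-style run.

    ``query_expansion`` toggles concept-id expansion (+QE); passing
    ``triage_params`` re-ranks each retrieved list toward the params' focus
    axis (+RR) — the topic's own focus is used when the params carry none.
    """
    run = Run(tag=tag)
    for topic in topics:
        q = weight_query_terms(topic.query, ref_df, ref_N, focus=topic.focus)
        if query_expansion:
            q = expand_query(q, lexicon)
        results = search(q, index, k=k)
        if triage_params is not None and results:
            params = TriageParams(
                focus=topic.focus,
                w_base=triage_params.w_base,
                w_spec=triage_params.w_spec,
                w_dens=triage_params.w_dens,
                normalize=triage_params.normalize,
            )
            ranked = rerank(results, annotations, index, params)
            results = [(r.doc_id, r.final_score) for r in ranked]
        run.topics[topic.topic_id] = results
    return run
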