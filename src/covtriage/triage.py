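"""Axis-focused prioritization of retrieved literature.

A retrieved list is re-ordered by a learning-free linear combination of
three per-document features:

* the base retrieval score (BM25);
* *specificity* — the number of distinct concepts of the user's focus axis
  annotated in the document;
* *density* — a concept TF-IDF mass: sum over the document's distinct
  annotated concepts of tf · max(0, ln(N / (df + 1))), normalized by
  document length.

Because the three features live on incommensurable scales, each is min-max
scaled to [0, 1] within the result list before combining (a constant
feature scales to 0 everywhere); scaling can be switched off to recover the
raw linear form.  With w_spec = w_dens = 0 and scaling off the re-ranker
reproduces the baseline ordering exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .annotator import Annotation
from .lexicon_io import normalize_axis
from .retrieval import Index

DEFAULT_W_BASE = 1.0
DEFAULT_W_SPEC = 0.5
DEFAULT_W_DENS = 0.5


@dataclass
class TriageParams:
    """Re-ranking weights and the focus axis."""

    focus: str
    w_base: float = DEFAULT_W_BASE
    w_spec: float = DEFAULT_W_SPEC
    w_dens: float = DEFAULT_W_DENS
    normalize: bool = True

    def __post_init__(self) -> None:
        self.focus = normalize_axis(self.focus)
        for name in ("w_base", "w_spec", "w_dens"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.w_base == self.w_spec == self.w_dens == 0:
            raise ValueError("at least one weight must be positive")


@dataclass
class RankedResult:
    """One re-ranked document with its feature breakdown."""

    doc_id: str
    base_score: float
    specificity: int
    density: float
    final_score: float
    rank: int


def specificity(annots: Sequence[Annotation], focus: str) -> int:
    """Number of distinct focus-axis concepts annotated in a document."""
    focus = normalize_axis(focus)
    return len({a.concept_id for a in annots if a.axis == focus})


def density(annots: Sequence[Annotation], doc_id: str, index: Index) -> float:
    """Length-normalized concept TF-IDF mass of a document.

    IDF is clipped at zero, so the measure degenerates gracefully to 0 for
    tiny corpora where every concept is ubiquitous.
    """
    if doc_id not in index.doc_len:
        raise KeyError(f"unknown doc_id: {doc_id}")
    length = index.doc_len[doc_id]
    if not annots or length == 0:
        return 0.0
    total = 0.0
    for cid in {a.concept_id for a in annots}:
        tf = index.concept_tf(cid, doc_id)
        if tf == 0:
            continue
        total += tf * max(0.0, math.log(index.N / (index.concept_df(cid) + 1)))
    return total / length


def _minmax(values: Sequence[float]) -> List[float]:
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.0] * len(values)
    return [(v - lo) / (hi - lo) for v in values]


def rerank(
    results: Sequence[Tuple[str, float]],
    annotations: Mapping[str, Sequence[Annotation]],
    index: Index,
    params: TriageParams,
) -> List[RankedResult]:
    """Re-rank (doc_id, base_score) pairs by the linear triage score.

    Stable and deterministic: ties in the final score fall back to the
    original rank, then doc_id.  The output is always a permutation of the
    input documents.
    """
    if not results:
        raise ValueError("results must be non-empty")
    doc_ids = [d for d, _ in results]
    base = [s for _, s in results]
    spec = [specificity(annotations.get(d, ()), params.focus) for d in doc_ids]
    dens = [density(annotations.get(d, ()), d, index) for d in doc_ids]

    if params.normalize:
        f1, f2, f3 = _minmax(base), _minmax([float(s) for s in spec]), _minmax(dens)
    else:
        f1, f2, f3 = base, [float(s) for s in spec], dens

    final = [
        params.w_base * a + params.w_spec * b + params.w_dens * c
        for a, b, c in zip(f1, f2, f3)
    ]
    order = sorted(range(len(doc_ids)), key=lambda i: (-final[i], i, doc_ids[i]))
    return [
        RankedResult(
            doc_id=doc_ids[i],
            base_score=base[i],
            specificity=spec[i],
            density=dens[i],
            final_score=final[i],
            rank=rank,
        )
        for rank, i in enumerate(order, start=1)
    ]
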