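"""TREC-style ad hoc retrieval evaluation.

Implements the trec_eval conventions: qrels map (topic, document) pairs to
integer relevance grades, binary relevance is grade > 0, unjudged documents
count as non-relevant, average precision divides by the total number of
relevant documents in the qrels, and topics with no relevant documents (or
missing from a run) contribute zero and are included in means.

Also provides the *evolutionary rate*, the signed percentage change of a
metric relative to a baseline run: 100 · (run − baseline) / baseline,
reported with explicit sign and two decimals.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field as dc_field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

logger = logging.getLogger(__name__)

#: Qrels: (topic_id, doc_id) -> relevance grade (>= 0).
Qrels = Dict[Tuple[str, str], int]


@dataclass
class Run:
    """A ranked retrieval run: per-topic ordered (doc_id, score) lists."""

    topics: Dict[str, List[Tuple[str, float]]] = dc_field(default_factory=dict)
    tag: str = "run"


@dataclass
class EvRate:
    """Percentage change of a metric against a baseline."""

    baseline_value: float
    run_value: float
    rate_percent: float

    def __str__(self) -> str:
        return f"{self.rate_percent:+.2f}%"


@dataclass
class MetricsReport:
    """Per-topic and mean P@10 / AP for one run."""

    run_tag: str
    per_topic_p10: Dict[str, float]
    per_topic_ap: Dict[str, float]
    mean_p10: float
    map: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "run_tag": self.run_tag,
                "mean_p10": self.mean_p10,
                "map": self.map,
                "per_topic": {
                    t: {"p10": self.per_topic_p10[t], "ap": self.per_topic_ap[t]}
                    for t in sorted(self.per_topic_p10)
                },
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["topic\tp10\tap"]
        for t in sorted(self.per_topic_p10):
            lines.append(f"{t}\t{self.per_topic_p10[t]:.4f}\t{self.per_topic_ap[t]:.4f}")
        lines.append(f"all\t{self.mean_p10:.4f}\t{self.map:.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# TREC file I/O


def read_qrels(path) -> Qrels:
    """Read TREC qrels: ``topic 0 doc_id grade`` per line."""
    qrels: Qrels = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(cols)}")
            topic, _iter, doc_id, grade = cols
            try:
                g = int(grade)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer grade {grade!r}") from exc
            if g < 0:
                raise ValueError(f"{path}:{lineno}: negative relevance grade {g}")
            qrels[(topic, doc_id)] = g
    return qrels


def write_qrels(qrels: Qrels, path) -> None:
    lines = [f"{t} 0 {d} {g}" for (t, d), g in sorted(qrels.items())]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_run(path) -> Run:
    """Read a TREC run: ``topic Q0 doc_id rank score tag`` per line.

    Within each topic, ranks must form the contiguous sequence 1..n and a
    document may appear only once.
    """
    raw: Dict[str, List[Tuple[int, str, float]]] = {}
    tag = "run"
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
            topic, _q0, doc_id, rank_s, score_s, tag = cols
            try:
                rank, score = int(rank_s), float(score_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad rank/score: {exc}") from exc
            raw.setdefault(topic, []).append((rank, doc_id, score))
    run = Run(tag=tag)
    for topic, rows in raw.items():
        rows.sort()
        seen = set()
        for expected, (rank, doc_id, _s) in enumerate(rows, start=1):
            if rank != expected:
                raise ValueError(
                    f"{path}: topic {topic}: rank gap or duplicate (expected {expected}, got {rank})"
                )
            if doc_id in seen:
                raise ValueError(f"{path}: topic {topic}: duplicate doc_id {doc_id}")
            seen.add(doc_id)
        run.topics[topic] = [(doc_id, score) for _r, doc_id, score in rows]
    return run


def write_run(run: Run, path) -> None:
    """Write a run in the TREC 6-column format, ranks starting at 1."""
    lines = []
    for topic in sorted(run.topics):
        for rank, (doc_id, score) in enumerate(run.topics[topic], start=1):
            lines.append(f"{topic} Q0 {doc_id} {rank} {score:.6f} {run.tag}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# metrics


def _relevant_docs(qrels: Qrels, topic: str) -> set:
    return {d for (t, d), g in qrels.items() if t == topic and g > 0}


def precision_at_k(run: Run, qrels: Qrels, topic: str, k: int = 10) -> float:
    """Fraction of relevant documents in the top k retrieved.

    Fewer than k retrieved: missing slots count as non-relevant.  A topic
    absent from the run scores 0.0 with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = run.topics.get(topic)
    if ranked is None:
        warnings.warn(f"topic {topic!r} missing from run {run.tag!r}; P@{k} = 0")
        return 0.0
    relevant = _relevant_docs(qrels, topic)
    hits = sum(1 for doc_id, _s in ranked[:k] if doc_id in relevant)
    return hits / k


def average_precision(run: Run, qrels: Qrels, topic: str, cutoff: int = 1000) -> float:
    """AP at a rank cutoff, trec_eval convention.

    Sum of P@i over relevant retrieved positions i <= cutoff, divided by the
    total number of relevant documents in the qrels for the topic; zero when
    the topic has no relevant documents.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    relevant = _relevant_docs(qrels, topic)
    if not relevant:
        return 0.0
    ranked = run.topics.get(topic, [])
    hits = 0
    ap_sum = 0.0
    for i, (doc_id, _s) in enumerate(ranked[:cutoff], start=1):
        if doc_id in relevant:
            hits += 1
            ap_sum += hits / i
    return ap_sum / len(relevant)


def mean_average_precision(run: Run, qrels: Qrels, cutoff: int = 1000) -> float:
    """Mean AP over all qrels topics (topics missing from the run score 0)."""
    if not qrels:
        raise ValueError("empty qrels")
    topics = sorted({t for t, _d in qrels})
    return sum(average_precision(run, qrels, t, cutoff) for t in topics) / len(topics)


def evaluate_run(run: Run, qrels: Qrels, cutoff: int = 1000, k: int = 10) -> MetricsReport:
    """Full per-topic and mean P@k / AP report over the qrels topics."""
    if not qrels:
        raise ValueError("empty qrels")
    topics = sorted({t for t, _d in qrels})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p10 = {t: precision_at_k(run, qrels, t, k) for t in topics}
    ap = {t: average_precision(run, qrels, t, cutoff) for t in topics}
    return MetricsReport(
        run_tag=run.tag,
        per_topic_p10=p10,
        per_topic_ap=ap,
        mean_p10=sum(p10.values()) / len(topics),
        map=sum(ap.values()) / len(topics),
    )


def ev_rate(baseline: float, run_value: float) -> EvRate:
    """Signed percentage change of a metric against the baseline.

    Rounded half-up to two decimals, e.g. ``+19.17%`` or ``-2.88%``.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    raw = 100.0 * (run_value - baseline) / baseline
    rate = float(Decimal(repr(raw)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return EvRate(baseline_value=baseline, run_value=run_value, rate_percent=rate)
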