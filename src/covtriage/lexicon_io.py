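"""Axis-partitioned concept lexicon: loading, validation, serialization.

The controlled vocabulary is a flat list of concepts, each carrying a CURIE
identifier, a preferred label, synonyms, cross-references and exactly one
*axis* — one of nine thematic partitions (diseases, chemicals, organisms,
cell lines, ...) used both to filter annotations and to focus ranking.

Two equivalent on-disk dialects are supported:

* TSV — UTF-8, header ``id  axis  preferred_label  synonyms  xrefs``,
  tab-separated, ``|`` as multi-value separator with ``\\|`` escape;
* JSON — an array of objects with the same five keys
  (schema: ``schemas/lexicon.schema.json``).

For matching, the lexicon is compiled into a phrase table: every surface
form (preferred label and synonyms) is tokenized and normalized exactly as
document text is, and every resulting variant token sequence maps back to
the concept id.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .textnorm import tokenize

logger = logging.getLogger(__name__)

#: The nine concept axes.
AXES = ("BMV", "CE", "CL", "CT", "CHEM", "DIS", "GL", "ORG", "PG")

#: Full axis names accepted on input and normalized to the codes.
AXIS_NAMES = {
    "biomedical vocabulary": "BMV",
    "conceptual entities": "CE",
    "cell lines": "CL",
    "clinical trials": "CT",
    "chemicals": "CHEM",
    "diseases and syndromes": "DIS",
    "geographic locations": "GL",
    "organisms": "ORG",
    "proteins and genomes": "PG",
}

PhraseKey = Tuple[str, ...]
PhraseTable = Dict[PhraseKey, Set[str]]


class LexiconError(ValueError):
    """Malformed or invalid lexicon input."""


def normalize_axis(axis: str) -> str:
    """Map an axis code or full name to its canonical code.

    Raises :class:`LexiconError` for unknown axes.
    """
    code = axis.strip()
    if code.upper() in AXES:
        return code.upper()
    full = AXIS_NAMES.get(code.casefold())
    if full is None:
        raise LexiconError(f"unknown axis: {axis!r} (expected one of {', '.join(AXES)})")
    return full


@dataclass(frozen=True)
class Concept:
    """One controlled-vocabulary concept."""

    id: str
    axis: str
    preferred_label: str
    synonyms: Tuple[str, ...] = ()
    xrefs: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise LexiconError("concept id must be non-empty")
        if not self.preferred_label:
            raise LexiconError(f"concept {self.id}: preferred_label must be non-empty")
        object.__setattr__(self, "axis", normalize_axis(self.axis))

    @property
    def surface_forms(self) -> Tuple[str, ...]:
        """Matchable strings: the preferred label plus every synonym."""
        return (self.preferred_label, *self.synonyms)


@dataclass
class Lexicon:
    """A validated concept set plus its compiled phrase table."""

    concepts: Dict[str, Concept]
    phrase_table: PhraseTable = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __getitem__(self, concept_id: str) -> Concept:
        return self.concepts[concept_id]

    @classmethod
    def from_concepts(cls, concepts: Iterable[Concept]) -> "Lexicon":
        by_id: Dict[str, Concept] = {}
        for c in concepts:
            if c.id in by_id:
                raise LexiconError(f"duplicate concept id: {c.id}")
            by_id[c.id] = c
        return cls(concepts=by_id, phrase_table=compile_phrases(by_id.values()))


def compile_phrases(concepts: Iterable[Concept]) -> PhraseTable:
    """Compile surface forms into a normalized-phrase → concept-id table.

    Each surface form is tokenized; an n-token form yields one key per
    element of the cartesian product of the per-token variant sets, so
    "covid-19" contributes both ``("covid",)`` and ``("covid19",)``.  Forms
    in which some token normalizes to nothing (e.g. a bare "19") produce no
    key; a concept none of whose forms survive is logged and left out of the
    table (it stays in the lexicon as metadata).
    """
    table: PhraseTable = {}
    for concept in sorted(concepts, key=lambda c: c.id):
        any_phrase = False
        for form in concept.surface_forms:
            spans = tokenize(form)
            if not spans or any(not s.variants for s in spans):
                continue
            for combo in itertools.product(*(sorted(s.variants) for s in spans)):
                table.setdefault(tuple(combo), set()).add(concept.id)
                any_phrase = True
        if not any_phrase:
            logger.warning(
                "concept %s: no surface form survives normalization; "
                "it will never match",
                concept.id,
            )
    return table


# ---------------------------------------------------------------------------
# serialization

_TSV_HEADER = ["id", "axis", "preferred_label", "synonyms", "xrefs"]


def _split_multi(value: str) -> Tuple[str, ...]:
    """Split a pipe-separated multi-value field honouring the \\| escape."""
    if not value:
        return ()
    parts: List[str] = []
    buf: List[str] = []
    i = 0
    while i < len(value):
        ch = value[i]
        if ch == "\\" and i + 1 < len(value) and value[i + 1] == "|":
            buf.append("|")
            i += 2
        elif ch == "|":
            parts.append("".join(buf))
            buf = []
            i += 1
        else:
            buf.append(ch)
            i += 1
    parts.append("".join(buf))
    return tuple(p for p in parts if p)


def _join_multi(values: Sequence[str]) -> str:
    return "|".join(v.replace("|", "\\|") for v in values)


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "json"):
            raise LexiconError(f"unknown lexicon format: {fmt!r}")
        return fmt
    return "json" if path.suffix.lower() == ".json" else "tsv"


def load_lexicon(path, format: Optional[str] = None) -> Lexicon:
    """Load and validate a lexicon from a TSV or JSON file.

    Format is inferred from the extension unless given.  Malformed rows
    raise :class:`LexiconError` naming the offending line; duplicate ids and
    unknown axis codes are validation errors.
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "json":
        records = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(records, list):
            raise LexiconError(f"{path}: lexicon JSON must be an array of objects")
        concepts = []
        for i, rec in enumerate(records):
            if not isinstance(rec, dict) or "id" not in rec or "axis" not in rec:
                raise LexiconError(f"{path}: record {i} is not a valid concept object")
            concepts.append(
                Concept(
                    id=str(rec["id"]),
                    axis=str(rec["axis"]),
                    preferred_label=str(rec.get("preferred_label", "")),
                    synonyms=tuple(rec.get("synonyms", ()) or ()),
                    xrefs=tuple(rec.get("xrefs", ()) or ()),
                )
            )
        return Lexicon.from_concepts(concepts)

    concepts = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header] != _TSV_HEADER:
            raise LexiconError(
                f"{path}:1: bad header {header!r}, expected {_TSV_HEADER!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise LexiconError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(cols)}"
                )
            try:
                concepts.append(
                    Concept(
                        id=cols[0],
                        axis=cols[1],
                        preferred_label=cols[2],
                        synonyms=_split_multi(cols[3]),
                        xrefs=_split_multi(cols[4]),
                    )
                )
            except LexiconError as exc:
                raise LexiconError(f"{path}:{lineno}: {exc}") from exc
    return Lexicon.from_concepts(concepts)


def save_lexicon(lexicon: Lexicon, path, format: Optional[str] = None) -> None:
    """Write a lexicon back to disk in the TSV or JSON dialect."""
    path = Path(path)
    fmt = _detect_format(path, format)
    concepts = sorted(lexicon.concepts.values(), key=lambda c: c.id)
    if fmt == "json":
        payload = [
            {
                "id": c.id,
                "axis": c.axis,
                "preferred_label": c.preferred_label,
                "synonyms": list(c.synonyms),
                "xrefs": list(c.xrefs),
            }
            for c in concepts
        ]
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8")
        return
    lines = ["\t".join(_TSV_HEADER)]
    for c in concepts:
        lines.append(
            "\t".join(
                [c.id, c.axis, c.preferred_label, _join_multi(c.synonyms), _join_multi(c.xrefs)]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def obo_to_concepts(path, axis_property: str = "property_value: axis") -> List[Concept]:
    """Convert an OBO graph into flat concepts (convenience, not core).

    Each OBO term becomes one concept; synonyms are taken from the OBO
    ``synonym`` clauses and xrefs from ``xref``.  The axis is read from a
    ``property_value`` of the form ``axis "<CODE>"`` when present, else
    defaults to BMV.
    """
    import obonet

    graph = obonet.read_obo(path)
    concepts = []
    for node_id, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            continue
        synonyms = []
        for syn in data.get("synonym", ()):
            # OBO synonym clause: "label" SCOPE [refs]
            if syn.startswith('"'):
                endq = syn.find('"', 1)
                if endq > 0:
                    synonyms.append(syn[1:endq])
        axis = "BMV"
        for pv in data.get("property_value", ()):
            parts = pv.split()
            if parts and parts[0].rstrip(":").lower().endswith("axis") and len(parts) > 1:
                axis = parts[1].strip('"')
        concepts.append(
            Concept(
                id=node_id,
                axis=axis,
                preferred_label=name,
                synonyms=tuple(synonyms),
                xrefs=tuple(data.get("xref", ())),
            )
        )
    return concepts
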