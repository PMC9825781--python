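"""String pre-processing and tokenization for dictionary annotation.

Biomedical text is rife with spelling variation around dashes and slashes
("covid-19" vs "COVID19" vs "covid 19").  To make dictionary matching robust
to these variants, every token is expanded into a set of normalized surface
variants: the token is lowercased, split on dashes and slashes, each fragment
of at least three characters is kept as a variant, and the fusion of all
fragments (separators deleted) is added as a further variant.  The same
expansion is applied to lexicon entries and to document text, so a concept
spelled either way in the lexicon matches either spelling in text.

Character offsets always refer to the original, unmodified field text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from typing import FrozenSet, List

#: Fields a document may carry, in canonical order.
FIELDS = ("title", "abstract", "body", "keywords")

#: Minimum length (in characters) a normalized variant must have to be kept.
MIN_VARIANT_LEN = 3

# Dash-like codepoints normalized to an ASCII hyphen before splitting:
# hyphen, non-breaking hyphen, figure dash, en dash, em dash, horizontal bar,
# minus sign.
_DASHES = "‐‑‒–—―−"
_DASH_TABLE = str.maketrans({c: "-" for c in _DASHES})

# A token is a maximal run of Unicode letters/digits, possibly containing
# internal dashes or slashes.  [^\W_] = word character minus underscore.
_TOKEN_RE = re.compile(r"[^\W_]+(?:[-/]+[^\W_]+)*", re.UNICODE)
_SEP_RE = re.compile(r"[-/]+")


@dataclass(frozen=True)
class TokenSpan:
    """One token of a document field with its normalized variants.

    ``start``/``end`` are 0-based half-open character offsets into the
    original field text; ``variants`` may be empty when every fragment of the
    token is shorter than :data:`MIN_VARIANT_LEN`.
    """

    surface: str
    variants: FrozenSet[str]
    start: int
    end: int
    field: str = "abstract"


def expand_token(surface: str) -> FrozenSet[str]:
    """Return the normalized variant set of a single token.

    The surface is lowercased and split on ``-`` and ``/`` (typographic
    dashes included); each fragment of length >= 3 is a variant, and the
    fusion of all fragments is a variant if itself of length >= 3.  A
    separator-free token yields itself (if long enough) or nothing.

    >>> sorted(expand_token("covid-19"))
    ['covid', 'covid19']
    >>> sorted(expand_token("SARS-CoV-2"))
    ['cov', 'sars', 'sarscov2']
    >>> expand_token("19")
    frozenset()
    """
    lowered = surface.casefold().translate(_DASH_TABLE)
    fragments = [f for f in _SEP_RE.split(lowered) if f]
    variants = {f for f in fragments if len(f) >= MIN_VARIANT_LEN}
    fusion = "".join(fragments)
    if len(fusion) >= MIN_VARIANT_LEN:
        variants.add(fusion)
    return frozenset(variants)


def tokenize(text: str, field: str = "abstract") -> List[TokenSpan]:
    """Split field text into token spans with normalized variants.

    Tokens are maximal runs of letters/digits possibly containing internal
    dashes/slashes; all other punctuation and whitespace delimits.  Spans are
    non-overlapping, ordered by start offset, and index into ``text`` itself.
    """
    mapped = text.translate(_DASH_TABLE)
    spans = []
    for m in _TOKEN_RE.finditer(mapped):
        surface = text[m.start() : m.end()]
        spans.append(
            TokenSpan(
                surface=surface,
                variants=expand_token(surface),
                start=m.start(),
                end=m.end(),
                field=field,
            )
        )
    return spans


def normalize_terms(text: str) -> List[str]:
    """Flatten ``tokenize`` output into the list of emitted variants.

    Each token contributes each of its variants once, in token order; used
    for indexing and query processing.
    """
    out: List[str] = []
    for span in tokenize(text):
        out.extend(sorted(span.variants))
    return out
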