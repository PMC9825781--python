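# Methods

## Normalization and tokenization

Tokens are maximal runs of Unicode letters/digits possibly containing
internal `-` or `/`; all other punctuation delimits. Typographic dash
codepoints (en/em dash, minus sign, non-breaking hyphen, ...) are mapped to
`-` before splitting because real abstracts contain them. Each token is
lowercased (casefold) and split on the separators; every fragment of length
≥ 3 is kept as a matchable variant and the fusion of *all* fragments is
added when itself ≥ 3 characters. Choices made where the rule is open:

* **Multi-separator tokens** (`SARS-CoV-2`): fragments are all kept
  individually (subject to the length filter) and one fusion of all
  fragments is added (`sarscov2`), not pairwise fusions — the simplest
  generalization consistent with the single-dash behaviour.
* **The ≥ 3-character filter applies to every variant**, including
  separator-free tokens, for uniformity; so a bare `19` or `ab` never
  matches. Digits count toward length (`covid19` has length 7).
* Offsets are 0-based half-open character offsets into the *original*
  field text; normalization never moves them.

No stemming, lemmatization, stop lists or sentence splitting: the engine's
recall robustness comes from synonym lists and variant expansion alone.

## Lexicon and annotation

The lexicon is a flat table (TSV or JSON) of concepts: CURIE id, one of
nine axis codes (full axis names are accepted on input and normalized),
preferred label, synonyms, cross-references. Cross-references are metadata
only; they do not participate in matching. For matching, every surface form
is tokenized with the same rules as document text and compiled into a
phrase table mapping each variant token sequence (cartesian product of
per-token variant sets) to its concept id. Concepts whose every surface
form is filtered away stay in the lexicon but never match; a warning is
logged.

Annotation slides the phrase table over each field's token stream; phrase
tokens must match *consecutive* document tokens (no gaps — no gap policy is
otherwise defensible without training data). Matching is deliberately
permissive: concepts from different axes may overlap freely. Within one
concept, matches starting at the same character are resolved to the longest
phrase, and repeated matches of one concept at one span via different
variants are deduplicated. Per-field provenance is kept so positional
exports remain possible.

Collection statistics count every annotation once per axis; the
per-document average is the **floor** of total/n_docs (integer truncation).
This matters: 724 978 858 annotations over 4 722 601 documents average 153
under truncation but 154 under half-up rounding, and the truncated value is
the conventionally reported one.

## Retrieval

One index holds token-variant postings and concept-id postings (`CID:`
prefix avoids namespace collisions). Each document token contributes each
of its variants once, and document length counts variant emissions — so
variant expansion slightly inflates lengths uniformly across the corpus.
Fields are concatenated without per-field boosts.

BM25 uses k1 = 1.2, b = 0.75 (the defaults of the search engine this
design mirrors) and the Lucene IDF `ln((N − df + 0.5)/(df + 0.5) + 1)`,
which is non-negative for any df ≤ N. Query-term weights enter the sum
multiplicatively; the weighting function `max(0, ln(ref_N/(df_ref + 1)))`
against a reference DF table is the simplest smoothed inverse-DF scheme
that favours rare, informative words, with terms unknown to the reference
taking the maximal weight. Both the constants and the weighting scheme are
exposed as configuration; no claim is made that they are optimal.

Query expansion annotates the raw query text with the same annotator used
on documents and appends the distinct matched concept ids (unit weight,
scored against concept postings). The operation is idempotent.

## Triage re-ranking

`final = w_base·f1 + w_spec·f2 + w_dens·f3` over three features: base BM25
score; specificity = number of *distinct* focus-axis concepts in the
document; density = Σ over distinct annotated concepts of
`tf·max(0, ln(N/(df+1)))`, divided by document length. Decisions:

* **Min-max scaling per result list** (default on) because the three
  features live on incommensurable scales; a constant feature scales to 0
  for the whole list. With scaling off and w_spec = w_dens = 0 the
  re-ranker reproduces the baseline ordering exactly — a tested reduction
  law.
* Density is defined over distinct concepts with clipped IDF, so it
  degenerates gracefully to 0 at N = 1.
* Default weights w_base = 1.0, w_spec = 0.5, w_dens = 0.5: no empirical
  weights are published for this kind of system, so the defaults are
  chosen to keep the base ranking dominant while letting focus evidence
  break near-ties; all three are exposed in the library and CLI.
* Ties in the final score fall back to the original rank, then doc_id;
  all retrieved documents are re-ranked (not a prefix), and the output is
  always a permutation of the input.

## Evaluation

trec_eval conventions throughout: binary relevance is grade > 0, unjudged
documents are non-relevant, AP divides by the total number of relevant
documents in the qrels (retrieved or not), topics with no relevant
documents or missing from a run contribute zero and are included in means.
Run files must have contiguous ranks 1..n per topic and no duplicate
documents. The evolutionary rate `100·(run − baseline)/baseline` is
rounded half-up to two decimals and always printed with an explicit sign.
Statistical significance testing between runs is out of scope.

## Synthetic studies

The fixture generator emulates the *structure* of a triage evaluation, not
its content: a mini-lexicon with 2 concepts per axis (1–3 synonyms each,
dashed/slashed/multi-token labels to exercise normalization, and the
canonical "covid-19" concept), 60 documents of 40–80 filler tokens with
concept surface forms planted verbatim at recorded offsets, one topic per
focus axis whose query is a planted concept label plus common filler words,
and relevance judgements drawn from a logistic link
`P(rel) = σ(1.2·(k − 1))` in the number k of distinct planted focus-axis
concepts. The reference DF table comes from a held-out 200-document filler
corpus, so filler words carry high df and planted labels maximal query
weight. Everything is byte-identical under a fixed seed; the filler
vocabulary ships with the package.

These sizes keep a 20-seed study under a few seconds while leaving enough
per-topic variation for the direction of the re-ranking effect to emerge;
the acceptance script uses 20 studies × 60 documents × 6 topics.

What passing tests show — and what they do not: planted-recall 1.0 shows
the matcher finds exactly what the normalization rules make findable; it
says nothing about lexical coverage of real vocabularies. The re-ranking
improvement on these fixtures shows the linear combination exploits a
focus-relevance correlation *when one exists by construction*; on real
collections the strength of that correlation, and hence the gain, is an
empirical question. Real MEDLINE XML / JATS full text, field boosts, and
residual-collection evaluation rounds are not emulated.

## Known limitations

* Whether a production engine applies the ≥ 3-character filter to
  unhyphenated tokens is unknowable from the outside; it is a documented
  decision here and short acronyms (2 characters) therefore never match.
* The DF-weighting function and whether weights enter BM25 multiplicatively
  are design choices, configurable but unvalidated against any service.
* The OBO converter reads term/synonym/xref clauses only and expects the
  axis as a `property_value`; it does not reason over imports or the class
  hierarchy.
* Clinical-trial identifier recognition (NCT ids) is not implemented; the
  CT axis only matches whatever surface forms the lexicon carries.
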