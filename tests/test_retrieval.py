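"""Inverted index, BM25 scoring, DF weighting, query expansion, search."""

import math
import random

import pytest

from covtriage import (
    Document,
    WeightedQuery,
    bm25_score,
    build_index,
    expand_query,
    search,
    weight_query_terms,
)
from covtriage.retrieval import Index, read_ref_df, write_ref_df


# --- independent oracle: BM25 computed term-by-term from the formula -------


def oracle_bm25(query_terms, doc_tokens_by_id, doc_id, k1=1.2, b=0.75):
    """Brute-force BM25 over plain token lists (no index machinery)."""
    N = len(doc_tokens_by_id)
    avglen = sum(len(v) for v in doc_tokens_by_id.values()) / N
    tokens = doc_tokens_by_id[doc_id]
    score = 0.0
    for term, weight in query_terms:
        tf = tokens.count(term)
        if tf == 0:
            continue
        df = sum(1 for toks in doc_tokens_by_id.values() if term in toks)
        idf = math.log((N - df + 0.5) / (df + 0.5) + 1.0)
        norm = 1 - b + b * len(tokens) / avglen
        score += weight * idf * tf * (k1 + 1) / (tf + k1 * norm)
    return score


def _word_doc(rng, vocab, n):
    return " ".join(rng.choice(vocab) for _ in range(n))


VOCAB = ["alpha", "bravo", "charlie", "delta", "echo", "foxtrot", "golf", "hotel"]


def test_build_index_variant_emission():
    idx = build_index([Document(doc_id="d", fields={"abstract": "covid-19 covid-19"})])
    assert idx.postings["covid"]["d"] == 2
    assert idx.postings["covid19"]["d"] == 2
    assert idx.doc_len["d"] == 4
    assert idx.N == 1


def test_build_index_empty_and_df():
    assert build_index([]).N == 0
    idx = build_index(
        [
            Document(doc_id="a", fields={"abstract": "remdesivir works"}),
            Document(doc_id="b", fields={"abstract": "nothing here"}),
        ]
    )
    assert idx.df("remdesivir") == 1
    with pytest.raises(ValueError, match="duplicate"):
        build_index([Document(doc_id="a", fields={}), Document(doc_id="a", fields={})])


def test_bm25_no_shared_terms_is_zero():
    idx = build_index([Document(doc_id="d", fields={"abstract": "alpha bravo"})])
    q = WeightedQuery(terms=[("zulu", 1.0)], raw_text="zulu")
    assert bm25_score(q, "d", idx) == 0.0
    with pytest.raises(KeyError):
        bm25_score(q, "missing", idx)


def test_bm25_closed_form_single_doc():
    """N=1, one term with tf=2, len=4: the closed form is checkable by hand."""
    idx = build_index([Document(doc_id="d", fields={"abstract": "alpha alpha bravo bravo"})])
    q = WeightedQuery(terms=[("alpha", 1.0)], raw_text="alpha")
    k1, b = 1.2, 0.75
    idf = math.log((1 - 1 + 0.5) / (1 + 0.5) + 1.0)
    expected = idf * 2 * (k1 + 1) / (2 + k1 * 1.0)  # len == avglen
    assert bm25_score(q, "d", idx, k1=k1, b=b) == pytest.approx(expected, abs=1e-12)


def test_bm25_matches_oracle_on_random_corpora():
    """Exact rank order agreement with the brute-force scorer, 50 corpora."""
    rng = random.Random(1234)
    for _ in range(50):
        docs, tokens = [], {}
        for i in range(20):
            text = _word_doc(rng, VOCAB, rng.randint(3, 25))
            doc_id = f"d{i:02d}"
            docs.append(Document(doc_id=doc_id, fields={"abstract": text}))
            tokens[doc_id] = text.split()
        idx = build_index(docs)
        q_terms = [(rng.choice(VOCAB), rng.uniform(0.1, 3.0)) for _ in range(rng.randint(1, 4))]
        q = WeightedQuery(terms=q_terms, raw_text=" ".join(t for t, _ in q_terms))
        ours = search(q, idx, k=1000)
        oracle = [(d, oracle_bm25(q_terms, tokens, d)) for d in tokens]
        oracle = sorted(((d, s) for d, s in oracle if s > 0), key=lambda x: (-x[1], x[0]))
        assert [d for d, _ in ours] == [d for d, _ in oracle]
        for (d1, s1), (d2, s2) in zip(ours, oracle):
            assert s1 == pytest.approx(s2, abs=1e-9)


def test_bm25_tf_monotonicity():
    """More occurrences of a query term never lower the score."""
    prev = -1.0
    for tf in range(1, 6):
        text = " ".join(["alpha"] * tf + ["bravo"] * (6 - tf))
        idx = build_index(
            [
                Document(doc_id="d", fields={"abstract": text}),
                Document(doc_id="pad", fields={"abstract": "charlie delta echo"}),
            ]
        )
        q = WeightedQuery(terms=[("alpha", 1.0)], raw_text="alpha")
        s = bm25_score(q, "d", idx)
        assert s >= prev
        prev = s


def test_idf_decreases_with_df():
    from covtriage.retrieval import idf

    docs = [Document(doc_id=f"d{i}", fields={"abstract": "alpha" if i < 3 else "bravo"}) for i in range(10)]
    idx = build_index(docs)
    assert idf(idx, "alpha") > idf(idx, "bravo")
    assert idf(idx, "alpha") >= 0 and idf(idx, "bravo") >= 0


def test_weight_query_terms_formula():
    wq = weight_query_terms("the spreaders", {"the": 999, "spreaders": 2}, ref_N=1000)
    weights = dict(wq.terms)
    assert weights["spreaders"] == pytest.approx(math.log(1000 / 3))
    assert weights["the"] == pytest.approx(0.0)
    assert weights["spreaders"] > weights["the"] >= 0


def test_weight_query_terms_missing_term_and_duplicates():
    wq = weight_query_terms("rare rare", {}, ref_N=100)
    assert dict(wq.terms)["rare"] == pytest.approx(2 * math.log(100))
    with pytest.raises(ValueError):
        weight_query_terms("word", {}, ref_N=0)
    with pytest.raises(ValueError):
        weight_query_terms("", {}, ref_N=10)


def test_query_invariants():
    with pytest.raises(ValueError):
        WeightedQuery(terms=[("abc", float("nan"))], raw_text="abc")
    with pytest.raises(ValueError):
        WeightedQuery(terms=[("abc", -1.0)], raw_text="abc")
    q = WeightedQuery(terms=[], concept_ids=["X:1"], raw_text="")
    assert q.concept_ids == ["X:1"]


def test_expand_query(demo_lexicon):
    q = WeightedQuery(terms=[("remdesivir", 1.0), ("treatment", 1.0)], raw_text="remdesivir treatment")
    expanded = expand_query(q, demo_lexicon)
    assert expanded.concept_ids == ["CHEBI:145994"]
    assert expanded.terms == q.terms
    # no lexicon phrase in the query: unchanged
    q2 = WeightedQuery(terms=[("nothing", 1.0)], raw_text="nothing")
    assert expand_query(q2, demo_lexicon).concept_ids == []
    # idempotence
    twice = expand_query(expand_query(q, demo_lexicon), demo_lexicon)
    assert twice == expanded


def test_concept_scoring_adds_to_bm25(demo_lexicon):
    docs = [
        Document(doc_id="a", fields={"abstract": "remdesivir trial outcome"}),
        Document(doc_id="b", fields={"abstract": "placebo trial outcome"}),
    ]
    from covtriage import annotate_corpus

    annotations = annotate_corpus(docs, demo_lexicon)
    idx = build_index(docs, annotations)
    q = WeightedQuery(terms=[("trial", 1.0)], raw_text="remdesivir trial")
    base_a = bm25_score(q, "a", idx)
    q_exp = expand_query(q, demo_lexicon)
    assert q_exp.concept_ids == ["CHEBI:145994"]
    assert bm25_score(q_exp, "a", idx) > base_a
    assert bm25_score(q_exp, "b", idx) == pytest.approx(bm25_score(q, "b", idx))


def test_search_truncation_ties_and_positive_only():
    docs = [Document(doc_id=f"d{i}", fields={"abstract": "alpha bravo"}) for i in range(5)]
    docs.append(Document(doc_id="zz", fields={"abstract": "charlie"}))
    idx = build_index(docs)
    q = WeightedQuery(terms=[("alpha", 1.0)], raw_text="alpha")
    results = search(q, idx, k=1000)
    assert len(results) == 5  # "zz" has score 0 and is excluded
    assert [d for d, _ in results] == sorted(d for d, _ in results)  # tie-break by doc_id
    assert len(search(q, idx, k=3)) == 3
    with pytest.raises(ValueError):
        search(q, idx, k=0)


def test_index_save_load_roundtrip(tmp_path, demo_lexicon, demo_doc):
    from covtriage import annotate_corpus

    annotations = annotate_corpus([demo_doc], demo_lexicon)
    idx = build_index([demo_doc], annotations)
    idx.save(tmp_path / "idx")
    again = Index.load(tmp_path / "idx")
    assert again.postings == idx.postings and again.doc_len == idx.doc_len
    assert again.concept_tf("CHEBI:145994", "d1") == 1


def test_ref_df_roundtrip(tmp_path):
    path = tmp_path / "ref.tsv"
    write_ref_df({"alpha": 10, "bravo": 2}, 100, path)
    ref_df, ref_N = read_ref_df(path)
    assert ref_df == {"alpha": 10, "bravo": 2} and ref_N == 100
    with pytest.raises(ValueError, match="#N="):
        (tmp_path / "bad.tsv").write_text("alpha\t3\n")
        read_ref_df(tmp_path / "bad.tsv")
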