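"""TREC qrels/run I/O, P@10, average precision, MAP, evolutionary rates."""

import random

import pytest

from covtriage.evaluation import (
    Run,
    average_precision,
    ev_rate,
    evaluate_run,
    mean_average_precision,
    precision_at_k,
    read_qrels,
    read_run,
    write_qrels,
    write_run,
)


# --- independent oracle: AP and P@k by direct enumeration ------------------


def oracle_ap(ranked_ids, relevant, cutoff=1000):
    if not relevant:
        return 0.0
    total = 0.0
    hits = 0
    for i, doc_id in enumerate(ranked_ids[:cutoff], start=1):
        if doc_id in relevant:
            hits += 1
            precision_here = hits / i
            total += precision_here
    return total / len(relevant)


def oracle_p_at_k(ranked_ids, relevant, k):
    return sum(1 for d in ranked_ids[:k] if d in relevant) / k


def _run(topic_docs, tag="t"):
    return Run(topics={t: [(d, 1.0 / (i + 1)) for i, d in enumerate(docs)] for t, docs in topic_docs.items()}, tag=tag)


def test_qrels_io_roundtrip(tmp_path):
    path = tmp_path / "qrels.txt"
    path.write_text("1 0 docA 1\n1 0 docB 0\n2 0 docC 2\n")
    qrels = read_qrels(path)
    assert qrels == {("1", "docA"): 1, ("1", "docB"): 0, ("2", "docC"): 2}
    out = tmp_path / "out.txt"
    write_qrels(qrels, out)
    assert read_qrels(out) == qrels


def test_qrels_errors(tmp_path):
    bad = tmp_path / "bad.txt"
    bad.write_text("1 0 docA\n")
    with pytest.raises(ValueError, match=":1:"):
        read_qrels(bad)
    bad.write_text("1 0 docA -2\n")
    with pytest.raises(ValueError, match="negative"):
        read_qrels(bad)


def test_run_io_roundtrip(tmp_path):
    run = _run({"1": ["a", "b"], "2": ["c"]}, tag="demo")
    path = tmp_path / "run.txt"
    write_run(run, path)
    again = read_run(path)
    assert again.tag == "demo"
    assert [d for d, _ in again.topics["1"]] == ["a", "b"]


def test_run_rank_gap_and_duplicate_rejected(tmp_path):
    path = tmp_path / "run.txt"
    path.write_text("1 Q0 a 1 2.0 t\n1 Q0 b 3 1.0 t\n")
    with pytest.raises(ValueError, match="rank gap"):
        read_run(path)
    path.write_text("1 Q0 a 1 2.0 t\n1 Q0 a 2 1.0 t\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_run(path)


def test_precision_at_k_cases():
    qrels = {("1", f"d{i}"): 1 for i in range(10)}
    run = _run({"1": [f"d{i}" for i in range(10)]})
    assert precision_at_k(run, qrels, "1") == 1.0
    run_bad = _run({"1": ["x", "y"]})
    assert precision_at_k(run_bad, qrels, "1") == 0.0
    seven = _run({"1": [f"d{i}" for i in range(7)] + ["x", "y", "z"]})
    assert precision_at_k(seven, qrels, "1") == pytest.approx(0.7)
    # short list: missing slots are non-relevant
    short = _run({"1": ["d0", "d1"]})
    assert precision_at_k(short, qrels, "1") == pytest.approx(0.2)
    with pytest.warns(UserWarning):
        assert precision_at_k(run, qrels, "99") == 0.0


def test_map_simple_cases():
    qrels = {("1", "a"): 1}
    assert mean_average_precision(_run({"1": ["a", "b"]}), qrels) == 1.0
    assert mean_average_precision(_run({"1": ["b", "a"]}), qrels) == 0.5
    with pytest.raises(ValueError):
        mean_average_precision(_run({"1": ["a"]}), {})


def test_ap_denominator_counts_unretrieved_relevant():
    qrels = {("1", "a"): 1, ("1", "b"): 1}
    # only "a" retrieved, at rank 1: AP = (1/1) / 2
    assert average_precision(_run({"1": ["a", "x"]}), qrels, "1") == 0.5


def test_topic_with_no_relevant_contributes_zero():
    qrels = {("1", "a"): 1, ("2", "x"): 0}
    run = _run({"1": ["a"], "2": ["x"]})
    assert mean_average_precision(run, qrels) == 0.5


def test_metrics_match_oracle_on_random_runs():
    """Equality within 1e-9 against the enumeration oracle, 30 random runs."""
    rng = random.Random(42)
    doc_pool = [f"doc{i}" for i in range(30)]
    for _ in range(30):
        topics = [str(t) for t in range(1, rng.randint(2, 5))]
        qrels = {}
        run = Run(topics={}, tag="r")
        for t in topics:
            judged = rng.sample(doc_pool, rng.randint(5, 20))
            for d in judged:
                qrels[(t, d)] = rng.randint(0, 1)
            retrieved = rng.sample(doc_pool, rng.randint(0, 25))
            run.topics[t] = [(d, 1.0 / (i + 1)) for i, d in enumerate(retrieved)]
        report = evaluate_run(run, qrels, cutoff=1000, k=10)
        ap_values, p10_values = [], []
        for t in topics:
            relevant = {d for (tt, d), g in qrels.items() if tt == t and g > 0}
            ranked = [d for d, _ in run.topics[t]]
            ap_values.append(oracle_ap(ranked, relevant))
            p10_values.append(oracle_p_at_k(ranked, relevant, 10))
            assert report.per_topic_ap[t] == pytest.approx(ap_values[-1], abs=1e-9)
            assert report.per_topic_p10[t] == pytest.approx(p10_values[-1], abs=1e-9)
        assert report.map == pytest.approx(sum(ap_values) / len(topics), abs=1e-9)
        assert report.mean_p10 == pytest.approx(sum(p10_values) / len(topics), abs=1e-9)
        assert 0 <= report.map <= 1 and 0 <= report.mean_p10 <= 1


def test_moving_relevant_doc_up_never_decreases_ap():
    rng = random.Random(7)
    for _ in range(20):
        ranked = [f"d{i}" for i in range(15)]
        relevant = set(rng.sample(ranked, 4))
        rel_positions = [i for i, d in enumerate(ranked) if d in relevant and i > 0]
        if not rel_positions:
            continue
        i = rng.choice(rel_positions)
        swapped = list(ranked)
        swapped[i - 1], swapped[i] = swapped[i], swapped[i - 1]
        assert oracle_ap(swapped, relevant) >= oracle_ap(ranked, relevant)
        run_a = _run({"1": ranked})
        run_b = _run({"1": swapped})
        qrels = {("1", d): int(d in relevant) for d in ranked}
        assert average_precision(run_b, qrels, "1") >= average_precision(run_a, qrels, "1")


@pytest.mark.parametrize(
    "baseline, value, expected",
    [
        (0.4825, 0.575, 19.17),
        (0.1561, 0.1623, 3.97),
        (0.6178, 0.6, -2.88),
        (0.1006, 0.1557, 54.77),
        (0.5, 0.5, 0.0),
    ],
)
def test_ev_rate_values(baseline, value, expected):
    r = ev_rate(baseline, value)
    assert r.rate_percent == pytest.approx(expected, abs=1e-12)


def test_ev_rate_formatting_and_errors():
    assert str(ev_rate(0.4825, 0.575)) == "+19.17%"
    assert str(ev_rate(0.6178, 0.6)) == "-2.88%"
    assert str(ev_rate(0.5, 0.5)) == "+0.00%"
    with pytest.raises(ValueError):
        ev_rate(0.0, 0.5)


def test_report_serialization():
    qrels = {("1", "a"): 1}
    report = evaluate_run(_run({"1": ["a"]}, tag="demo"), qrels)
    assert "demo" in report.to_json()
    tsv = report.to_tsv()
    assert tsv.splitlines()[0] == "topic\tp10\tap"
    assert tsv.splitlines()[-1].startswith("all\t")
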