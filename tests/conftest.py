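import pytest

from covtriage import Concept, Document, Lexicon
from covtriage.fixtures import FixtureSpec, make_fixtures


@pytest.fixture
def demo_lexicon() -> Lexicon:
    """Two-concept lexicon used throughout the worked examples."""
    return Lexicon.from_concepts(
        [
            Concept(
                id="COVOC:0000001",
                axis="DIS",
                preferred_label="covid-19",
                synonyms=("coronavirus disease 2019",),
                xrefs=("MONDO:0100096",),
            ),
            Concept(id="CHEBI:145994", axis="CHEM", preferred_label="remdesivir"),
        ]
    )


@pytest.fixture
def demo_doc() -> Document:
    return Document(
        doc_id="d1",
        collection="demo",
        fields={"abstract": "Remdesivir blocks covid-19 replication."},
    )


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic synthetic study, shared across tests."""
    return make_fixtures(FixtureSpec(seed=3))
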