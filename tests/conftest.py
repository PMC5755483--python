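import pytest

from litrdf import BiblioGraphConfig, LexiconEntry
from litrdf.fixtures import make_jats, tables_lexicon
from litrdf.jats import parse_jats

FIXED_TIME = "2018-01-02T00:00:00+00:00"

WORKED_IDS = {
    "pmcid": "3879346",
    "pmid": "24392157",
    "doi": "10.1371/journal.pone.0084792",
}


@pytest.fixture
def fixed_cfg():
    return BiblioGraphConfig(creation_time=FIXED_TIME)


@pytest.fixture
def worked_doc():
    """Article carrying the worked-example identifier set, two sections."""
    xml = make_jats(
        {
            **WORKED_IDS,
            "issn": "1234-5678",
            "abstract": "A synthetic abstract about zorvex.",
            "n_authors": 3,
            "sections": [("Introduction", 3), ("Materials and Methods", 2)],
            "refs": ["journal", "book", "webpage"],
        },
        seed=42,
    )
    return parse_jats(xml)


@pytest.fixture(scope="session")
def snomed_lexicon():
    return tables_lexicon()


@pytest.fixture(scope="session")
def extended_lexicon():
    """SNOMED CT lexicon plus two NCIT terms used in content queries."""
    return tables_lexicon() + [
        LexiconEntry(
            "Chloroplast DNA", "http://purl.bioontology.org/ontology/NCIT/C000001", "NCIT"
        ),
        LexiconEntry(
            "Isolation", "http://purl.bioontology.org/ontology/NCIT/C000002", "NCIT"
        ),
    ]
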