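import pytest

from chemtagger import synthetic
from chemtagger.corpus_io import EntityAnnotation, PatentDocument


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic 40-document synthetic corpus shared across tests."""
    return synthetic.generate_corpus(synthetic.GrammarConfig(n_documents=40, seed=7))


@pytest.fixture
def toy_doc():
    return PatentDocument(
        "US1",
        "Chiral tricyclic compounds",
        "The agent aspirin was tested. Later aspirin was tested again.",
    )


def make_ann(doc, section, start, end, etype="TRIVIAL", conf=1.0):
    text = doc.section_text(section)[start:end]
    return EntityAnnotation(doc.doc_id, section, start, end, text, etype, conf)
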