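import pytest

from entsearch import (
    Dictionary,
    DocumentRecord,
    SourceRecord,
    build_index,
    merge_records,
)


@pytest.fixture(scope="session")
def cml_dictionary() -> Dictionary:
    """Tiny hand-built dictionary around the chronic myeloid leukemia
    worked example: one drug concept (imatinib/Gleevec) and one disease."""
    records = [
        SourceRecord("drugbank", "imatinib", "drug", frozenset({"DB00619"})),
        SourceRecord("fda", "Gleevec", "drug", frozenset({"DB00619"})),
        SourceRecord("mesh", "chronic myeloid leukemia", "disease",
                     frozenset({"D015464"})),
        SourceRecord("mesh", "leukemia", "disease", frozenset({"D007938"})),
        SourceRecord("entrez", "BCR-ABL", "gene/protein", frozenset({"G25"})),
        SourceRecord("entrez", "TP53", "gene/protein", frozenset({"G7157"})),
    ]
    return merge_records(records)


PMID_24524212 = (
    "Consistent use of imatinib is critical for treatment success in "
    "chronic myeloid leukemia."
)


@pytest.fixture(scope="session")
def cml_corpus(cml_dictionary):
    docs = [
        DocumentRecord("24524212", PMID_24524212, journal="Blood",
                       impact_factor=13.2, pub_year=2014, pub_month=2),
        DocumentRecord("d2", "imatinib resistant cases with BCR-ABL kinase",
                       journal="PLOS", impact_factor=3.5,
                       pub_year=2013, pub_month=6),
        DocumentRecord("d3", "resistant leukemia without known drivers",
                       journal="", impact_factor=None,
                       pub_year=2010, pub_month=1),
        DocumentRecord("d4", "no entities in this abstract at all",
                       journal="", impact_factor=None,
                       pub_year=2014, pub_month=1),
    ]
    return docs


@pytest.fixture(scope="session")
def cml_index(cml_dictionary, cml_corpus):
    return build_index(cml_corpus, cml_dictionary)
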