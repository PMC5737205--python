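import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bioquery.corpus import DatasetRecord
from bioquery.index import build_index
from bioquery.query_formulation import Lexicon, LexiconEntry
from bioquery.synthetic import GeneratorConfig, generate_collection


@pytest.fixture
def micro_records():
    """Three one-field records with known statistics: df('protein', title)=2."""
    return [
        DatasetRecord("d1", "repoA", "Protein structure",
                      {"title": "chemotaxis protein"}),
        DatasetRecord("d2", "repoA", "Unspecified",
                      {"title": "protein structure"}),
        DatasetRecord("d3", "repoB", "Gene expression",
                      {"title": "gene expression"}),
    ]


@pytest.fixture
def micro_index(micro_records):
    return build_index(micro_records)


@pytest.fixture
def tiny_lexicon():
    return Lexicon(
        [
            LexiconEntry("G:1", "gene", "TP53", ("p53", "tumor protein p53")),
            LexiconEntry("G:2", "gene", "CheY", ("chey protein",)),
            LexiconEntry("O:1", "organism", "Homo sapiens", ("human",)),
            LexiconEntry("O:2", "organism", "Escherichia coli", ("e coli",)),
            LexiconEntry("D:1", "disease", "melanoma", ()),
        ]
    )


@pytest.fixture(scope="session")
def small_collection():
    """A down-scaled synthetic collection shared across tests (fast)."""
    config = GeneratorConfig(
        seed=7,
        n_queries=6,
        repositories=tuple(
            r.__class__(r.name, r.category, r.fields, 80)
            for r in GeneratorConfig().repositories
        ),
    )
    return generate_collection(config)


@pytest.fixture(scope="session")
def small_index(small_collection):
    return build_index(small_collection.records)
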