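import pytest

from traitlink import (
    FixtureSpec,
    TermFrequencyTable,
    generate_annotation,
    generate_genes,
    generate_ontology,
    generate_trait_dictionary,
)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def ontology(spec):
    return generate_ontology(spec)


@pytest.fixture(scope="session")
def genes(spec):
    return generate_genes(spec)


@pytest.fixture(scope="session")
def trait_dict(spec, ontology):
    return generate_trait_dictionary(spec, ontology)


@pytest.fixture(scope="session")
def trait_terms(spec, trait_dict):
    return {
        f"trait {i + 1}": trait_dict.lookup(f"trait {i + 1}")[0]
        for i in range(spec.n_traits)
    }


@pytest.fixture(scope="session")
def toy_annotation():
    """100-gene background, 10 terms of 8 genes each."""
    return generate_annotation(n_genes=100, n_terms=10, genes_per_term=8, seed=7)


@pytest.fixture
def small_freq():
    """Hand-built IC table: total 100; counts chosen for easy closed forms."""
    return TermFrequencyTable({"a": 10, "b": 5, "c": 50, "d": 100}, total=100)
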