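import pytest

from parity.fixtures import build_corpus


@pytest.fixture(scope="session")
def corpus():
    """Toy corpus with 21 extra seeded random molecules for oracle tests."""
    return build_corpus(seed=1, n_extra=21)


@pytest.fixture(scope="session")
def table(corpus):
    return corpus.compound_table


@pytest.fixture(scope="session")
def mol(table):
    """Getter for a corpus molecule by component ID."""
    return lambda cid: table[cid]


@pytest.fixture(scope="session")
def random_pairs(corpus):
    """All pairs of the seeded random molecules (210 for 21 molecules)."""
    import itertools

    mols = [corpus.compound_table[r] for r in corpus.random_ids]
    return list(itertools.combinations(mols, 2))


@pytest.fixture()
def corpus_dir(tmp_path):
    """A freshly written corpus directory (no random extras)."""
    from parity.fixtures import write_corpus

    write_corpus(build_corpus(seed=1), tmp_path / "corpus")
    return tmp_path / "corpus"
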