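import pytest

from lactopept import (
    ParentProtein,
    PeptideRecord,
    PeptideTable,
    load_bioactive_reference,
    load_example_differential_peptides,
    load_parent_proteins,
)


@pytest.fixture(scope="session")
def bioactive_db():
    return load_bioactive_reference()


@pytest.fixture(scope="session")
def example_queries():
    return load_example_differential_peptides()


@pytest.fixture(scope="session")
def parents():
    return {p.id: p for p in load_parent_proteins()}


@pytest.fixture
def toy_parent():
    return ParentProtein("toy", "toy protein", "MKPEPTIDE")


@pytest.fixture
def two_group_table():
    """Six samples, two groups, three peptides with assorted missingness."""
    records = [
        PeptideRecord("PEPTIDEA", {"A1": 2.0, "A2": 4.0, "A3": 3.0,
                                   "B1": 8.0, "B2": 9.0, "B3": 10.0}),
        PeptideRecord("PEPTIDEC", {"A1": 2.0, "A2": 4.0,
                                   "B1": 1.0, "B2": 2.0, "B3": 2.0}),
        PeptideRecord("SEQTW", {"A1": 5.0, "A2": 5.5, "A3": 4.5}),
    ]
    samples = ["A1", "A2", "A3", "B1", "B2", "B3"]
    groups = {s: s[0] for s in samples}
    return PeptideTable(records, samples, groups)
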