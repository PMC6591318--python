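import pytest

from glycoladder import (
    candidate_glycopeptides,
    digest,
    find_sequons,
    gen_fixture_proteome,
    load_default_table,
)

#: The six experimentally characterized archaellin glycopeptides and the
#: in-peptide 1-based position of their glycosylated Asn.
CHARACTERIZED_PEPTIDES = {
    "TASGTDTVDYANLTVR": 12,
    "QAAGADNINLSK": 9,
    "FNTTSIK": 2,
    "VDYVNLTVR": 5,
    "QAAGADNINLTK": 9,
    "VVNYANLTVR": 6,
}


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def fixture_proteome():
    return gen_fixture_proteome(seed=1)


@pytest.fixture(scope="session")
def candidates(fixture_proteome):
    out = []
    for prot in fixture_proteome:
        peps = digest(prot)
        out.extend(candidate_glycopeptides(peps, find_sequons(prot)))
    return out


@pytest.fixture(scope="session")
def vvny_candidate(candidates):
    """The single VVNYANLTVR candidate used in single-spectrum searches."""
    return [
        (pep, seq) for pep, seq in candidates if pep.sequence == "VVNYANLTVR"
    ]
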